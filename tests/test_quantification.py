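"""Sample measurement, baseline handling, calibration, LOD and kinetics fits."""

import math

import numpy as np
import pytest
from scipy import stats as scistats

from goredox import (
    GompertzParams,
    InvalidPointError,
    PointSet,
    ReductionSeries,
    Roi,
    baseline_subtract,
    fit_calibration,
    fit_gompertz,
    fit_rate_through_origin,
    gompertz,
    lod_normalized,
    measure_sample,
)


def twelve_points():
    return PointSet("s", tuple((16 + 32 * i, 16 + 32 * j) for i in range(3) for j in range(4)))


class TestMeasureSample:
    def test_uniform_image(self, uniform_image):
        img = uniform_image(128, 128, 160)
        m = measure_sample(img, twelve_points())
        assert m.mean_value == 128 / 255
        assert m.sd_value == 0.0
        assert m.n_points == 12

    def test_black_and_white_boxes(self):
        img = np.zeros((32, 64, 3), dtype=np.uint8)
        img[:, 32:] = 255
        m = measure_sample(img, PointSet("s", ((16, 16), (16, 48))))
        assert m.mean_value == pytest.approx(0.5)
        assert m.sd_value == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_order_invariance(self, rng):
        img = rng.integers(0, 256, (128, 160, 3), dtype=np.uint8)
        pts = twelve_points()
        rev = PointSet("s", pts.points[::-1])
        a, b = measure_sample(img, pts), measure_sample(img, rev)
        assert a.mean_value == pytest.approx(b.mean_value, abs=1e-15)
        assert a.sd_value == pytest.approx(b.sd_value, abs=1e-15)

    def test_mean_bounded_by_box_means(self, rng):
        from goredox import PixelBox, box_stats

        img = rng.integers(0, 256, (128, 160, 3), dtype=np.uint8)
        pts = twelve_points()
        m = measure_sample(img, pts)
        box_means = [box_stats(img, PixelBox(r, c, 32)).mean_v for r, c in pts.points]
        assert min(box_means) <= m.mean_value <= max(box_means)

    def test_invalid_point_aborts_with_reason(self, uniform_image):
        img = uniform_image(128, 64, 64)
        roi = Roi(0, 0, 64, 64)
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 32] = True
        with pytest.raises(InvalidPointError, match="glare"):
            measure_sample(img, PointSet("s", ((32, 32),)), roi=roi, mask=mask)


class TestBaselineSubtract:
    def test_basic(self):
        s = ReductionSeries("a", (0.0, 1.0, 2.0), (0.30, 0.35, 0.40), (0, 0, 0))
        out = baseline_subtract(s)
        assert out.mean_value == (0.0, pytest.approx(0.05), pytest.approx(0.10))
        assert out.baseline_value == 0.30

    def test_single_point(self):
        out = baseline_subtract(ReductionSeries("a", (0.0,), (0.42,), (0.0,)))
        assert out.mean_value == (0.0,)

    def test_negatives_preserved(self):
        out = baseline_subtract(ReductionSeries("a", (0.0, 1.0), (0.30, 0.28), (0, 0)))
        assert out.mean_value[1] == pytest.approx(-0.02)

    def test_applying_twice_equals_once(self):
        s = ReductionSeries("a", (0.0, 1.0, 3.0), (0.3, 0.32, 0.41), (0, 0, 0))
        once = baseline_subtract(s)
        twice = baseline_subtract(once)
        assert twice.mean_value == once.mean_value
        assert twice.baseline_value == once.baseline_value

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ReductionSeries("a", (), (), ())


class TestCalibration:
    def test_exact_line(self):
        concs = [0.02, 0.04, 0.06, 0.08, 0.10, 0.12]
        values = [0.8 - 2 * c for c in concs]
        fit = fit_calibration(concs, values, (0.0, 0.2))
        assert fit.slope == pytest.approx(-2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.8, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_all_points_outside_range(self):
        with pytest.raises(ValueError):
            fit_calibration([0.5, 0.6, 0.7], [0.1, 0.1, 0.1], (0.0, 0.2))

    def test_plateau_data_linear_region_recovery(self):
        """Linear-below / flat-above-0.40 g/L response: the fit restricted
        to the 0.06–0.12 g/L window recovers the generating slope."""
        concs = np.linspace(0.01, 1.0, 50)
        slope_true, v0, plateau_start = -1.25, 0.85, 0.40
        values = np.where(
            concs < plateau_start,
            v0 + slope_true * concs,
            v0 + slope_true * plateau_start,
        )
        fit = fit_calibration(concs, values, (0.06, 0.12))
        assert fit.slope == pytest.approx(slope_true, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)


class TestLod:
    @pytest.mark.parametrize(
        "control,maxd,expected",
        [
            ([0.10, 0.10, 0.10], 0.5, 0.20),
            ([0.1, 0.2, 0.3], 1.0, 0.50),
            ([0.0, 0.0, 0.0], 1.0, 0.0),
        ],
    )
    def test_closed_form(self, control, maxd, expected):
        assert lod_normalized(control, maxd) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            lod_normalized([0.1], 1.0)
        with pytest.raises(ValueError):
            lod_normalized([0.1, 0.2], 0.0)


class TestRateThroughOrigin:
    def test_exact_proportionality(self):
        fit = fit_rate_through_origin([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0, abs=1e-14)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_two_points(self):
        fit = fit_rate_through_origin([1, 2], [3, 2])
        assert fit.slope == pytest.approx(1.4, abs=1e-14)

    def test_scaling_linearity(self, rng):
        t = rng.uniform(0.5, 8.0, 10)
        y = rng.normal(0.1 * t, 0.02)
        k = 3.7
        assert fit_rate_through_origin(t, k * y).slope == pytest.approx(
            k * fit_rate_through_origin(t, y).slope, rel=1e-12
        )

    def test_equals_ols_when_intercept_zero(self):
        """Data whose unrestricted OLS intercept is exactly 0 (with nonzero
        residuals) gives the same slope through the origin."""
        t = np.array([1.0, 2.0, 3.0])
        y = np.array([1.9, 4.2, 5.9])
        ols = scistats.linregress(t, y)
        assert ols.intercept == pytest.approx(0.0, abs=1e-12)
        fit = fit_rate_through_origin(t, y)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-12)

    def test_all_zero_times_rejected(self):
        with pytest.raises(ValueError):
            fit_rate_through_origin([0, 0], [1, 2])


class TestGompertz:
    TRUE = GompertzParams(A=0.15, mu=0.05, lam=1.5)

    def test_noiseless_recovery(self):
        t = np.linspace(0, 10, 15)
        params, rnorm = fit_gompertz(t, gompertz(t, self.TRUE))
        assert params.A == pytest.approx(self.TRUE.A, abs=1e-6)
        assert params.mu == pytest.approx(self.TRUE.mu, abs=1e-6)
        assert params.lam == pytest.approx(self.TRUE.lam, abs=1e-6)
        assert rnorm < 1e-9

    def test_asymptote(self):
        t_far = self.TRUE.lam + 1000 / self.TRUE.mu
        assert gompertz(t_far, self.TRUE) == pytest.approx(self.TRUE.A, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gompertz([0, 1, 2], [0, 0.1, 0.2])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(A=0.0, mu=0.05, lam=1.0)

    def test_noisy_recovery_of_asymptote(self):
        """With Gaussian noise SD 0.005, A is recovered within 10% in each
        of 50 seeded replicates."""
        t = np.linspace(0, 12, 16)
        clean = gompertz(t, self.TRUE)
        for seed in range(50):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.005, t.size)
            params, _ = fit_gompertz(t, noisy)
            assert abs(params.A - self.TRUE.A) / self.TRUE.A < 0.10, f"seed {seed}"
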