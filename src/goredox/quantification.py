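"""Sample- and series-level quantification of graphene oxide reduction.

A sample measurement is the mean of per-box mean V values (with the sample
SD across boxes); a reduction series is the per-timepoint sequence of such
measurements for one sample, normalized by subtracting the earliest
(baseline) value so samples with different starting amounts can be compared.
On top of these sit three fits:

* a linear calibration of mean V against graphene oxide concentration over a
  stated range (the V-vs-concentration response is linear at low
  concentrations and plateaus near 0.40 g/L);
* a through-origin regression of signal against time, giving a reduction
  rate (the signal is zero at t = 0 by construction after baseline
  subtraction);
* the modified (Zwietering) Gompertz curve
  ``y(t) = A * exp(-exp(mu*e/A * (lam - t) + 1))``
  with asymptote ``A`` (value units), maximum rate ``mu`` (value units/h)
  and lag time ``lam`` (h), the standard shape for microbially driven
  analyte conversion.

The normalized limit of detection is (control mean + 3 control SD) divided
by the assay's highest detected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats as _scistats

from .errors import FitFailureError, InvalidPointError
from .image_core import DEFAULT_BOX_SIDE, PixelBox, box_stats, validate_rgb_image
from .sampling import PointSet, Roi, validate_points


@dataclass(frozen=True)
class SampleMeasurement:
    """Per-sample, per-timepoint mean HSV value over all sampled boxes.

    ``sd_value`` is the sample SD (n - 1) across box means — the spread of
    the measurement over the sample, not the pixel-level spread.
    """

    sample_id: str
    time_h: float
    mean_value: float
    sd_value: float
    n_points: int


@dataclass(frozen=True)
class ReductionSeries:
    """Ordered (time_h, mean_value, sd_value) triples for one sample."""

    sample_id: str
    time_h: tuple[float, ...]
    mean_value: tuple[float, ...]
    sd_value: tuple[float, ...]
    baseline_value: float | None = None  # set after baseline subtraction

    def __post_init__(self) -> None:
        t = self.time_h
        if len(t) == 0:
            raise ValueError("series must have at least one time point")
        if not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError("time_h must be strictly increasing")
        if not (len(t) == len(self.mean_value) == len(self.sd_value)):
            raise ValueError("time/value/sd lengths differ")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line of mean V against concentration over ``fit_range`` (g/L)."""

    slope: float
    intercept: float
    fit_range: tuple[float, float]
    r2: float
    n: int

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class RateFit:
    """Through-origin regression slope (value units per hour) and its SE."""

    slope: float
    slope_se: float
    n: int


@dataclass(frozen=True)
class GompertzParams:
    """Modified Gompertz parameters: asymptote A, max rate mu, lag lam."""

    A: float
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.mu > 0):
            raise ValueError("Gompertz requires A > 0 and mu > 0")


def gompertz(t: np.ndarray | float, params: GompertzParams) -> np.ndarray | float:
    """Evaluate the modified Gompertz curve at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    # inner exp may overflow far before the lag; the outer exp(-inf) -> 0
    # is exactly the curve's limit there
    with np.errstate(over="ignore"):
        y = params.A * np.exp(
            -np.exp(params.mu * math.e / params.A * (params.lam - t) + 1.0)
        )
    return y if y.ndim else float(y)


def measure_sample(
    image: np.ndarray,
    points: PointSet,
    side: int = DEFAULT_BOX_SIDE,
    time_h: float = 0.0,
    roi: Roi | None = None,
    mask: np.ndarray | None = None,
) -> SampleMeasurement:
    """Average the per-box mean V over all points of one sample image.

    If ``roi`` and ``mask`` are given, every point is first validated
    against them (bounds + glare) and any failure aborts with the per-point
    reason; otherwise only image bounds are enforced by box extraction.
    """
    arr = validate_rgb_image(image)
    if roi is not None and mask is not None:
        bad = [v for v in validate_points(points, roi, mask, side) if not v.ok]
        if bad:
            detail = "; ".join(f"{v.point}: {v.reason}" for v in bad)
            raise InvalidPointError(f"invalid points — {detail}")
    box_means = [
        box_stats(arr, PixelBox(r, c, side)).mean_v for r, c in points.points
    ]
    vals = np.array(box_means)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return SampleMeasurement(
        sample_id=points.sample_id,
        time_h=time_h,
        mean_value=float(vals.mean()),
        sd_value=sd,
        n_points=len(vals),
    )


def baseline_subtract(series: ReductionSeries) -> ReductionSeries:
    """Subtract the earliest-time value from every value in the series.

    The first entry becomes exactly 0; negative later values are retained
    (they reflect random fluctuation, not signal).  Applying the operation
    twice equals applying it once.
    """
    baseline = series.mean_value[0]
    return replace(
        series,
        mean_value=tuple(v - baseline for v in series.mean_value),
        baseline_value=baseline
        if series.baseline_value is None
        else series.baseline_value,
    )


def fit_calibration(
    concs: "np.ndarray | list[float]",
    values: "np.ndarray | list[float]",
    fit_range: tuple[float, float],
) -> CalibrationFit:
    """OLS line of value against concentration, restricted to ``fit_range``.

    Only points with fit_range[0] <= conc <= fit_range[1] enter the fit;
    at least 3 in-range points are required.  The slope is expected to be
    negative for darkening samples but this is not enforced.
    """
    concs = np.asarray(concs, dtype=float)
    values = np.asarray(values, dtype=float)
    if concs.shape != values.shape:
        raise ValueError("concs and values must have equal length")
    lo, hi = fit_range
    keep = (concs >= lo) & (concs <= hi)
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 points inside fit_range {fit_range}, got {int(keep.sum())}"
        )
    res = _scistats.linregress(concs[keep], values[keep])
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_range=(float(lo), float(hi)),
        r2=float(res.rvalue**2),
        n=int(keep.sum()),
    )


def lod_normalized(
    control_values: "np.ndarray | list[float]", max_detected: float
) -> float:
    """Normalized limit of detection: (mean + 3 SD of control) / max signal.

    The control SD uses n - 1 (the replicates are a sample).  Requires at
    least 2 control values and a positive ``max_detected``.
    """
    cv = np.asarray(control_values, dtype=float)
    if cv.size < 2:
        raise ValueError("need >= 2 control values")
    if max_detected <= 0:
        raise ValueError("max_detected must be > 0")
    return float((cv.mean() + 3.0 * cv.std(ddof=1)) / max_detected)


def fit_rate_through_origin(
    times_h: "np.ndarray | list[float]", values: "np.ndarray | list[float]"
) -> RateFit:
    """Least-squares slope of ``values`` on ``times_h`` through the origin.

    slope = sum(t*y) / sum(t^2);
    SE = sqrt( sum((y - slope*t)^2) / ((n - 1) * sum(t^2)) ).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 (time, value) pairs of equal length")
    st2 = float(np.sum(t * t))
    if st2 == 0.0:
        raise ValueError("all times are zero; slope undefined")
    slope = float(np.sum(t * y)) / st2
    resid = y - slope * t
    se = math.sqrt(float(np.sum(resid**2)) / ((t.size - 1) * st2))
    return RateFit(slope=slope, slope_se=se, n=int(t.size))


def _default_gompertz_init(t: np.ndarray, y: np.ndarray) -> GompertzParams:
    a0 = float(y.max())
    if a0 <= 0:
        a0 = 1e-3
    dy = np.diff(y) / np.diff(t)
    mu0 = float(dy.max()) if dy.size and dy.max() > 0 else a0 / max(t.max(), 1.0)
    above = t[y > 0.1 * a0]
    lam0 = float(above[0]) if above.size else float(t[0])
    return GompertzParams(A=a0, mu=mu0, lam=lam0)


def fit_gompertz(
    times_h: "np.ndarray | list[float]",
    values: "np.ndarray | list[float]",
    init: GompertzParams | None = None,
) -> tuple[GompertzParams, float]:
    """Nonlinear least squares of the modified Gompertz curve.

    Returns the fitted parameters and the residual 2-norm.  Deterministic
    given ``init``; the default initialisation takes A from the data
    maximum, mu from the steepest finite-difference slope and lam from the
    first time the signal exceeds 10% of A.  Raises
    :class:`FitFailureError` with solver diagnostics on non-convergence.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need >= 4 (time, value) pairs of equal length")
    p0 = init if init is not None else _default_gompertz_init(t, y)

    def resid(p: np.ndarray) -> np.ndarray:
        return gompertz(t, GompertzParams(p[0], p[1], p[2])) - y

    sol = optimize.least_squares(
        resid,
        x0=[p0.A, p0.mu, p0.lam],
        bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        max_nfev=5000,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise FitFailureError(
            f"Gompertz fit did not converge: {sol.message}",
            diagnostics={"status": sol.status, "nfev": sol.nfev, "cost": sol.cost},
        )
    params = GompertzParams(A=float(sol.x[0]), mu=float(sol.x[1]), lam=float(sol.x[2]))
    return params, float(np.linalg.norm(sol.fun))
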