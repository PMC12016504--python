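"""Synthetic assay-image generator with known ground truth.

Renders images that look like photographs of graphene oxide suspensions:
a brown background whose HSV value encodes the reduction state, corrupted
by the artifacts real photographs carry — specular glare ellipses (bright,
desaturated), dark flocculate speckle, a smooth horizontal illumination
ramp, and per-channel pixel noise.  Every render returns its ground truth
(the true value and the exact glare footprint) so downstream tests never
re-derive truth from pixels.

``simulate_reduction_images`` chains the generator over a Gompertz
reduction time course: the true darkening magnitude follows
``y(t) = A·exp(−exp(mu·e/A·(lam − t) + 1))`` and the rendered sample value
is ``v0 − y(t)`` (darkening) plus seeded between-replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import color as _skcolor
from skimage.draw import ellipse as _sk_ellipse

from .quantification import GompertzParams, gompertz

# light-brown graphene oxide suspension
DEFAULT_BASE_HUE = 0.08
DEFAULT_BASE_SAT = 0.45


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth darkness plus artifact parameters for one render.

    ``glare_ellipses`` entries are (center_row, center_col, (semi_r, semi_c));
    ``gradient_amplitude`` is the peak-to-peak smooth illumination variation
    and ``noise_sd`` the per-channel Gaussian SD, both in value units.
    """

    height: int = 240
    width: int = 320
    true_v: float = 0.5
    base_hue: float = DEFAULT_BASE_HUE
    base_sat: float = DEFAULT_BASE_SAT
    glare_ellipses: tuple[tuple[int, int, tuple[int, int]], ...] = ()
    speckle_density: float = 0.0
    speckle_v: float = 0.05
    gradient_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be >= 1")
        if not 0.0 <= self.speckle_density < 1.0:
            raise ValueError("speckle_density must lie in [0, 1)")
        lo = self.true_v - self.gradient_amplitude / 2 - 3 * self.noise_sd
        hi = self.true_v + self.gradient_amplitude / 2 + 3 * self.noise_sd
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                "true_v ± gradient/2 ± 3·noise_sd must stay within [0, 1]"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the renderer painted: the true value and the glare footprint."""

    true_v: float
    glare_mask: np.ndarray  # (H, W) bool, True where glare was painted
    speckle_mask: np.ndarray  # (H, W) bool, True where speckle was painted

    @property
    def clean_mask(self) -> np.ndarray:
        """Pixels carrying the background signal (no glare, no speckle)."""
        return ~(self.glare_mask | self.speckle_mask)


@dataclass(frozen=True)
class ReductionSimSpec:
    """Gompertz reduction time course for rendered replicate series.

    ``direction`` is ``"darkening"`` (rendered value = v0 − y(t), the
    photographed reality) or ``"signal"`` (rendered value = y(t), already in
    the baseline-subtracted frame).
    """

    gompertz: GompertzParams = field(
        default_factory=lambda: GompertzParams(A=0.15, mu=0.05, lam=1.5)
    )
    v0: float = 0.55
    direction: str = "darkening"
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
    replicate_noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("darkening", "signal"):
            raise ValueError("direction must be 'darkening' or 'signal'")
        if self.direction == "darkening" and self.v0 - self.gompertz.A < 0:
            raise ValueError("v0 − A must be >= 0 for darkening direction")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def render_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic assay image; returns (uint8 RGB, ground truth).

    Layer order: uniform background at (base_hue, base_sat, true_v); cosine
    illumination ramp added to V; speckle pixels forced to ``speckle_v``;
    glare ellipses painted last (V = 1, S ≈ 0); per-channel Gaussian noise
    added in RGB and channels clipped before 8-bit quantisation.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    hsv = np.empty((h, w, 3), dtype=float)
    hsv[..., 0] = spec.base_hue
    hsv[..., 1] = spec.base_sat
    hsv[..., 2] = spec.true_v
    if spec.gradient_amplitude > 0 and w > 1:
        ramp = (spec.gradient_amplitude / 2.0) * np.cos(
            np.pi * np.arange(w) / (w - 1)
        )
        hsv[..., 2] += ramp[None, :]

    speckle_mask = np.zeros((h, w), dtype=bool)
    if spec.speckle_density > 0:
        speckle_mask = rng.random((h, w)) < spec.speckle_density
        hsv[..., 2][speckle_mask] = spec.speckle_v

    glare_mask = np.zeros((h, w), dtype=bool)
    for cr, cc, (sr, sc) in spec.glare_ellipses:
        rr, cc_idx = _sk_ellipse(cr, cc, sr, sc, shape=(h, w))
        glare_mask[rr, cc_idx] = True
    hsv[..., 1][glare_mask] = 0.02
    hsv[..., 2][glare_mask] = 1.0

    rgb = _skcolor.hsv2rgb(np.clip(hsv, 0.0, 1.0))
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    img = np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)
    truth = GroundTruth(
        true_v=spec.true_v, glare_mask=glare_mask, speckle_mask=speckle_mask
    )
    return img, truth


@dataclass(frozen=True)
class SimulatedFrame:
    """One rendered replicate at one timepoint of a reduction simulation."""

    time_h: float
    replicate: int
    image: np.ndarray
    truth: GroundTruth
    true_value: float  # rendered sample value (v0 − y or y)
    true_signal: float  # noiseless Gompertz magnitude y(t)


def simulate_reduction_images(
    spec: ReductionSimSpec, image_spec: SyntheticSpec
) -> list[SimulatedFrame]:
    """Render a Gompertz reduction time course as replicate image series.

    Per (timepoint, replicate): the true rendered value is the Gompertz
    trajectory in the requested direction plus seeded replicate noise,
    clipped only by the render spec's own invariants.  The noiseless
    baseline-subtracted signal y(t) is monotone non-decreasing in time.
    """
    frames: list[SimulatedFrame] = []
    rng = np.random.default_rng(spec.seed)
    for t in spec.timepoints:
        y = float(gompertz(t, spec.gompertz))
        base = spec.v0 - y if spec.direction == "darkening" else y
        for rep in range(spec.n_replicates):
            v = base
            if spec.replicate_noise_sd > 0:
                v += float(rng.normal(0.0, spec.replicate_noise_sd))
            render_seed = int(
                np.random.SeedSequence(
                    [spec.seed, int(round(t * 1000)), rep]
                ).generate_state(1)[0]
                % (2**31)
            )
            frame_spec = replace(image_spec, true_v=v, seed=render_seed)
            img, truth = render_image(frame_spec)
            frames.append(
                SimulatedFrame(
                    time_h=float(t),
                    replicate=rep,
                    image=img,
                    truth=truth,
                    true_value=v,
                    true_signal=y,
                )
            )
    return frames
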