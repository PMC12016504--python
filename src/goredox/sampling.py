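"""Region-of-interest handling, glare masking and point selection.

Assay photographs contain specular reflections from tube walls and the
lightbox; boxes must avoid them because glare pixels saturate V and bias the
sample mean upward.  In the manual workflow an operator crops a clean region
and clicks glare-free points; here the region is an explicit :class:`Roi`,
the glare criterion is made operational (bright AND desaturated pixels), and
point selection can be automated by seeded rejection sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientAreaError, OutOfBoundsError
from .image_core import (
    DEFAULT_BOX_SIDE,
    rgb_array_to_hsv,
    validate_rgb_image,
)

logger = logging.getLogger(__name__)

# Specular highlights are near-white: very bright and nearly colorless.
DEFAULT_V_THRESHOLD = 0.95
DEFAULT_S_THRESHOLD = 0.20
# The manual protocol avoids reflections entirely, so by default no glare
# pixel is tolerated inside a box.
DEFAULT_MAX_GLARE_FRACTION = 0.0
DEFAULT_MIN_POINTS = 12
RECOMMENDED_MIN_POINTS = 15  # lowers the standard error of the sample mean
_ATTEMPTS_PER_POINT = 1000


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest, in full-image pixel coordinates."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI top/left must be >= 0")

    def check_within(self, image: np.ndarray) -> None:
        h, w = np.asarray(image).shape[:2]
        if self.top + self.height > h or self.left + self.width > w:
            raise OutOfBoundsError(
                f"ROI {self} exceeds image {h}x{w}"
            )


@dataclass(frozen=True)
class PointSet:
    """Named set of (row, col) box centres in full-image coordinates."""

    sample_id: str
    points: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pts = tuple((int(r), int(c)) for r, c in self.points)
        if len(set(pts)) != len(pts):
            raise ValueError("duplicate points in PointSet")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PointVerdict:
    """Pass/fail outcome of validating one point."""

    point: tuple[int, int]
    ok: bool
    reason: str = ""  # "", "bounds" or "glare"
    glare_fraction: float = 0.0


def build_glare_mask(
    image: np.ndarray,
    roi: Roi,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    s_threshold: float = DEFAULT_S_THRESHOLD,
) -> np.ndarray:
    """Boolean raster congruent with ``roi``; True flags glare pixels.

    A pixel is flagged iff V >= v_threshold and S <= s_threshold.
    """
    if not (0 <= v_threshold <= 1 and 0 <= s_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    arr = validate_rgb_image(image)
    roi.check_within(arr)
    crop = arr[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width]
    hsv = rgb_array_to_hsv(crop)
    return (hsv[..., 2] >= v_threshold) & (hsv[..., 1] <= s_threshold)


def validate_points(
    points: PointSet,
    roi: Roi,
    mask: np.ndarray,
    side: int = DEFAULT_BOX_SIDE,
    max_glare_fraction: float = DEFAULT_MAX_GLARE_FRACTION,
) -> list[PointVerdict]:
    """Per-point verdicts: box inside the ROI and glare fraction tolerated.

    Returns verdicts rather than raising; callers decide what failure means.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (roi.height, roi.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match ROI {roi.height}x{roi.width}"
        )
    half = side // 2
    verdicts: list[PointVerdict] = []
    for r, c in points.points:
        r0, c0 = r - half, c - half
        r1, c1 = r + half, c + half
        if (
            r0 < roi.top
            or c0 < roi.left
            or r1 > roi.top + roi.height
            or c1 > roi.left + roi.width
        ):
            verdicts.append(PointVerdict((r, c), False, "bounds"))
            continue
        sub = mask[r0 - roi.top : r1 - roi.top, c0 - roi.left : c1 - roi.left]
        frac = float(sub.mean())
        if frac > max_glare_fraction:
            verdicts.append(PointVerdict((r, c), False, "glare", frac))
        else:
            verdicts.append(PointVerdict((r, c), True, "", frac))
    return verdicts


def auto_select_points(
    image: np.ndarray,
    roi: Roi,
    n: int,
    side: int = DEFAULT_BOX_SIDE,
    seed: int = 0,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    s_threshold: float = DEFAULT_S_THRESHOLD,
    max_glare_fraction: float = DEFAULT_MAX_GLARE_FRACTION,
    sample_id: str = "auto",
) -> PointSet:
    """Draw ``n`` glare-free box centres uniformly at random (seeded).

    Rejection sampling over the valid centre rectangle; candidates whose box
    overlaps glare (per :func:`validate_points`) or duplicates an accepted
    point are rejected.  Deterministic for a fixed seed.  Raises
    :class:`InsufficientAreaError` after ``n * 1000`` failed attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arr = validate_rgb_image(image)
    roi.check_within(arr)
    half = side // 2
    r_lo, r_hi = roi.top + half, roi.top + roi.height - half
    c_lo, c_hi = roi.left + half, roi.left + roi.width - half
    if r_lo >= r_hi + 1 or c_lo >= c_hi + 1:
        raise InsufficientAreaError(f"ROI smaller than one {side}x{side} box")
    mask = build_glare_mask(arr, roi, v_threshold, s_threshold)
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    attempts = 0
    cap = n * _ATTEMPTS_PER_POINT
    while len(chosen) < n:
        if attempts >= cap:
            raise InsufficientAreaError(
                f"could not place {n} glare-free boxes after {cap} attempts "
                f"({len(chosen)} placed)"
            )
        attempts += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        c = int(rng.integers(c_lo, c_hi + 1))
        if (r, c) in chosen:
            continue
        verdict = validate_points(
            PointSet(sample_id, ((r, c),)), roi, mask, side, max_glare_fraction
        )[0]
        if verdict.ok:
            chosen.append((r, c))
        else:
            logger.debug("rejected point (%d, %d): %s", r, c, verdict.reason)
    return PointSet(sample_id, tuple(chosen))
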