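"""Pixel-level color decomposition and box statistics.

Assay photographs are 8-bit RGB rasters; the quantity of interest is the HSV
*value* channel (V = max(R,G,B)/255, 0 = darkest, 1 = lightest), which tracks
sample darkening as graphene oxide is reduced.  Measurements are taken as
per-channel means over fixed-size square pixel boxes centred on user- or
auto-selected points.

Coordinates are 0-based, row-major.  A box of side ``s`` centred on
``(r, c)`` spans the half-open ranges ``[r - s/2, r + s/2)`` and
``[c - s/2, c + s/2)``; boxes that cross the image boundary are an error,
never clamped, because clamping would bias means near tube edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as _skcolor

from .errors import InvalidPixelError, OutOfBoundsError

logger = logging.getLogger(__name__)

DEFAULT_BOX_SIDE = 32


@dataclass(frozen=True)
class HsvTriple:
    """Hue, saturation and value, each on [0, 1] (hue wraps on [0, 1)).

    Multiply ``h`` by 360 for degrees.
    """

    h: float
    s: float
    v: float


@dataclass(frozen=True)
class PixelBox:
    """Square pixel box centred on ``(center_row, center_col)``.

    ``side`` must be a positive even integer so the half-open span
    ``[center - side/2, center + side/2)`` has integer endpoints.
    """

    center_row: int
    center_col: int
    side: int = DEFAULT_BOX_SIDE

    def __post_init__(self) -> None:
        if self.side <= 0 or self.side % 2 != 0:
            raise ValueError(f"box side must be a positive even integer, got {self.side}")

    @property
    def row_range(self) -> tuple[int, int]:
        half = self.side // 2
        return (self.center_row - half, self.center_row + half)

    @property
    def col_range(self) -> tuple[int, int]:
        half = self.side // 2
        return (self.center_col - half, self.center_col + half)


@dataclass(frozen=True)
class BoxStats:
    """Per-channel HSV means over one box plus the V spread.

    ``sd_v`` is the sample standard deviation (n - 1): a box is treated as a
    sample of a larger homogeneous region.
    """

    mean_h: float
    mean_s: float
    mean_v: float
    sd_v: float
    n_pixels: int


def validate_rgb_image(image: np.ndarray) -> np.ndarray:
    """Check an array is a valid 8-bit RGB raster and return it as uint8.

    Accepts (H, W, 3) integer arrays with every channel in 0..255.
    An (H, W, 4) RGBA raster has its alpha channel discarded with a warning.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise InvalidPixelError(
            f"expected an (H, W, 3) RGB raster, got shape {arr.shape}"
        )
    if arr.shape[2] == 4:
        logger.warning("alpha channel discarded from RGBA image")
        arr = arr[:, :, :3]
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidPixelError("image must be at least 1x1")
    if not np.issubdtype(arr.dtype, np.integer):
        raise InvalidPixelError(f"expected integer channels, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidPixelError("channel values must lie in [0, 255]")
    return arr.astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        if im.mode == "RGBA":
            logger.warning("alpha channel discarded from %s", path)
        if im.mode not in ("RGB", "RGBA"):
            im = im.convert("RGB")
        arr = np.asarray(im)
    return validate_rgb_image(arr)


def rgb_array_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an (..., 3) uint8 RGB array to float HSV on [0, 1].

    Standard hexcone model: V = max/255 exactly; S = (max - min)/max (0 when
    max = 0); H per the piecewise formula, wrapped to [0, 1).
    """
    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        raise InvalidPixelError(f"expected integer channels, got dtype {arr.dtype}")
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 255:
        raise InvalidPixelError("channel values must lie in [0, 255]")
    # divide to float64 ourselves: V must equal max/255 to the last bit
    hsv = _skcolor.rgb2hsv(arr.astype(np.float64) / 255.0)
    # rgb2hsv may return h == 1.0 at the wrap point; fold onto [0, 1)
    h = hsv[..., 0]
    h[h >= 1.0] -= 1.0
    return hsv


def rgb_to_hsv(pixel: tuple[int, int, int]) -> HsvTriple:
    """Convert a single (R, G, B) integer triple to an :class:`HsvTriple`.

    Raises :class:`InvalidPixelError` for channels outside 0..255.
    """
    r, g, b = pixel
    for ch in (r, g, b):
        if not float(ch).is_integer() or not 0 <= ch <= 255:
            raise InvalidPixelError(f"channel value {ch!r} outside 0..255")
    hsv = rgb_array_to_hsv(np.array([[[r, g, b]]], dtype=np.uint8))[0, 0]
    return HsvTriple(h=float(hsv[0]), s=float(hsv[1]), v=float(hsv[2]))


def extract_box(image: np.ndarray, box: PixelBox) -> np.ndarray:
    """Crop the ``side``x``side`` pixel block of ``box`` from ``image``.

    Raises :class:`OutOfBoundsError` if the box crosses the image boundary;
    there is no silent clamping.
    """
    arr = validate_rgb_image(image)
    r0, r1 = box.row_range
    c0, c1 = box.col_range
    h, w = arr.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise OutOfBoundsError(
            f"box rows [{r0}, {r1}) cols [{c0}, {c1}) exceed image {h}x{w}"
        )
    return arr[r0:r1, c0:c1]


def box_stats(image: np.ndarray, box: PixelBox) -> BoxStats:
    """Mean H, S and V (plus the V sample SD) over all pixels of a box."""
    block = extract_box(image, box)
    hsv = rgb_array_to_hsv(block)
    v = hsv[..., 2]
    return BoxStats(
        mean_h=float(hsv[..., 0].mean()),
        mean_s=float(hsv[..., 1].mean()),
        mean_v=float(v.mean()),
        sd_v=float(v.std(ddof=1)),
        n_pixels=int(v.size),
    )
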