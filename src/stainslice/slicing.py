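"""Grey-level intensity slicing.

A slice keeps the pixels of one narrow grey-level range and turns everything
else white (255), reproducing the two-step thresholding macro used on the
source images: for a range ``lo``..``hi`` the commands whiten ``v <= lo`` and
``v >= hi``, so *both* shared boundary levels are excluded from adjacent
ranges.  The sole exception is ``lo = 0``, where only the upper command
applies and level 0 itself is kept ("macro" boundary mode).  The alternative
"inclusive-lower" mode keeps ``lo <= v < hi`` instead.

Because fill pixels are indistinguishable from native white pixels in the
sliced raster, the boolean ``kept_mask`` is the authoritative record of the
slice and is carried alongside the image everywhere.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .imgio import GreyImage

__all__ = [
    "IntensityRange",
    "SlicedImage",
    "DEFAULT_NARROW_RANGES",
    "FULL_RANGE",
    "SPECIFIC_RANGE",
    "NONSPECIFIC_RANGE",
    "DEFAULT_ANALYSIS_RANGES",
    "kept_mask",
    "slice_image",
    "slice_all",
    "range_share",
    "binary_mask",
    "overlay",
]

WHITE = 255


@dataclasses.dataclass(frozen=True)
class IntensityRange:
    """Half-open-ish grey-level interval ``lo``-``hi`` (see module docstring)."""

    lo: int
    hi: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 255):
            raise ValueError(f"invalid intensity range {self.lo}-{self.hi}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.lo}-{self.hi}")


#: The seven discrete narrow ranges used throughout the analysis.  The two
#: darkest ranges are wider because intense staining is rare.
DEFAULT_NARROW_RANGES = tuple(
    IntensityRange(lo, hi)
    for lo, hi in [(0, 130), (130, 160), (160, 180), (180, 200), (200, 220), (220, 240), (240, 255)]
)
FULL_RANGE = IntensityRange(0, 255)
#: 220 is the cutoff between specific (epithelial) and non-specific (stromal)
#: pan cytokeratin staining.
SPECIFIC_RANGE = IntensityRange(0, 220)
NONSPECIFIC_RANGE = IntensityRange(220, 255)
#: Default extraction set: original image plus seven narrow plus the
#: specific/non-specific split (10 ranges).
DEFAULT_ANALYSIS_RANGES = (FULL_RANGE,) + DEFAULT_NARROW_RANGES + (SPECIFIC_RANGE, NONSPECIFIC_RANGE)


def kept_mask(pixels: np.ndarray, rng: IntensityRange, boundary: str = "macro") -> np.ndarray:
    """Boolean mask of pixels kept by ``rng`` under the given boundary mode."""
    v = np.asarray(pixels)
    if boundary == "macro":
        lower = (v >= 0) if rng.lo == 0 else (v > rng.lo)
        return lower & (v < rng.hi)
    if boundary == "inclusive-lower":
        return (v >= rng.lo) & (v < rng.hi)
    raise ValueError(f"unknown boundary mode {boundary!r}")


@dataclasses.dataclass(frozen=True)
class SlicedImage:
    """A grey image restricted to one intensity range, with white fill."""

    image: GreyImage
    kept_mask: np.ndarray
    range: IntensityRange


def slice_image(img: GreyImage, rng: IntensityRange, boundary: str = "macro") -> SlicedImage:
    """Whiten every pixel outside ``rng`` and record the kept-pixel mask."""
    mask = kept_mask(img.pixels, rng, boundary)
    out = np.where(mask, img.pixels, np.uint8(WHITE)).astype(np.uint8)
    return SlicedImage(GreyImage(out, img.pixel_size), mask, rng)


def slice_all(
    img: GreyImage,
    ranges: tuple[IntensityRange, ...] = DEFAULT_NARROW_RANGES,
    boundary: str = "macro",
) -> list[SlicedImage]:
    """Slice an image by each range in turn (default: the seven narrow ranges).

    Ranges are expected to share boundaries; properly overlapping ranges are
    allowed but provoke a warning since pixels would then be counted twice.
    """
    ordered = sorted(ranges, key=lambda r: (r.lo, r.hi))
    for a, b in zip(ordered, ordered[1:]):
        if b.lo < a.hi and not (b.lo == a.lo and b.hi == a.hi):
            warnings.warn(
                f"ranges {a.label} and {b.label} overlap beyond a shared boundary",
                stacklevel=2,
            )
    return [slice_image(img, r, boundary) for r in ranges]


def range_share(
    img: GreyImage,
    ranges: tuple[IntensityRange, ...] = DEFAULT_NARROW_RANGES,
    boundary: str = "macro",
) -> dict[str, float]:
    """Fraction of image pixels kept by each range (relative to all pixels)."""
    total = img.pixels.size
    return {
        r.label: float(kept_mask(img.pixels, r, boundary).sum()) / total for r in ranges
    }


def binary_mask(sliced: SlicedImage) -> np.ndarray:
    """Kept pixels as a 0/255 ``uint8`` raster (white = kept)."""
    return np.where(sliced.kept_mask, np.uint8(255), np.uint8(0))


def overlay(img: GreyImage, sliced: SlicedImage) -> np.ndarray:
    """Original grey image as RGB with the slice's kept pixels in pure red."""
    rgb = np.repeat(img.pixels[:, :, None], 3, axis=2).astype(np.uint8)
    rgb[sliced.kept_mask] = (255, 0, 0)
    return rgb
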