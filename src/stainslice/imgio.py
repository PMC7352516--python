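"""Raster image I/O, stain separation and intensity histograms.

Images are 8-bit greyscale rasters where 0 is black (maximal stain uptake)
and 255 is white (no stain).  Brightfield RGB input is reduced to per-stain
greyscale channels by optical-density colour deconvolution; all downstream
analysis runs on the blue (pan cytokeratin) channel.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb_from_hdx

__all__ = [
    "GreyImage",
    "FormatError",
    "ParameterError",
    "read_image",
    "write_image",
    "decompose_stains",
    "intensity_histogram",
    "histogram_to_csv",
]


class FormatError(ValueError):
    """Raised for unreadable files or unsupported pixel depths."""


class ParameterError(ValueError):
    """Raised for invalid analysis parameters (e.g. degenerate stain vectors)."""


@dataclasses.dataclass(frozen=True)
class GreyImage:
    """8-bit greyscale raster; 0 = black (strong stain), 255 = white.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array.
    pixel_size
        Optional physical pixel edge length in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("GreyImage requires a 2-D raster of at least 1x1 pixels")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise FormatError("GreyImage pixels must be 8-bit integers in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def read_image(path: str | Path):
    """Read an 8-bit PNG/TIFF.

    Returns a :class:`GreyImage` for single-channel input, or an
    ``(H, W, 3) uint8`` RGB array (flagged for stain decomposition) for
    colour input.  Higher bit depths are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: only 8-bit images are supported, got dtype {arr.dtype} "
            "(convert 16-bit scans to 8-bit before analysis)"
        )
    if arr.ndim == 2:
        return GreyImage(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return np.ascontiguousarray(arr[:, :, :3])
    raise FormatError(f"{path}: unsupported image layout with shape {arr.shape}")


def write_image(img: GreyImage | np.ndarray, path: str | Path) -> None:
    """Write an image as 8-bit PNG or TIFF, chosen by file extension."""
    arr = img.pixels if isinstance(img, GreyImage) else np.asarray(img, dtype=np.uint8)
    iio.imwrite(Path(path), arr)


#: Optical-density vectors (rows: stain 1, stain 2) for a hematoxylin-like
#: blue stain and a DAB-like brown stain, taken from the standard H-DAB
#: deconvolution matrix.
DEFAULT_STAIN_VECTORS = np.array(rgb_from_hdx[:2], dtype=float)


def decompose_stains(
    rgb: np.ndarray,
    stain_vectors: np.ndarray | None = None,
) -> tuple[GreyImage, GreyImage]:
    """Separate an RGB brightfield image into two per-stain greyscale channels.

    The Beer-Lambert model is inverted: per-pixel optical density
    ``od = -log10(I / 255)`` is projected onto the two stain vectors (plus an
    orthogonal residual).  Each output channel re-exponentiates its stain
    density, so 255 means "no stain" and darker values mean denser stain.

    Returns ``(channel_1, channel_2)`` in the order of ``stain_vectors``;
    with the defaults that is (blue/hematoxylin-like, brown/DAB-like).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError("decompose_stains expects an (H, W, 3) RGB raster")
    # float input (same 0-255 scale) is accepted for unquantised mixtures
    vec = np.array(DEFAULT_STAIN_VECTORS if stain_vectors is None else stain_vectors, float)
    if vec.shape != (2, 3):
        raise ParameterError("stain_vectors must be a 2x3 array of OD vectors")
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms == 0):
        raise ParameterError("stain vectors must be non-zero")
    vec = vec / norms[:, None]
    residual = np.cross(vec[0], vec[1])
    if np.linalg.norm(residual) < 1e-6:
        raise ParameterError("stain vectors are collinear; deconvolution is degenerate")
    basis = np.vstack([vec, residual / np.linalg.norm(residual)])

    intensity = np.clip(rgb.astype(float), 1.0, 255.0)
    od = -np.log10(intensity / 255.0)
    conc = od.reshape(-1, 3) @ np.linalg.inv(basis)
    channels = []
    for i in range(2):
        c = np.clip(conc[:, i], 0.0, None)
        grey = np.clip(np.round(255.0 * np.power(10.0, -c)), 0, 255).astype(np.uint8)
        channels.append(GreyImage(grey.reshape(rgb.shape[:2])))
    return channels[0], channels[1]


def intensity_histogram(img: GreyImage) -> np.ndarray:
    """256-bin pixel count vector over grey levels 0..255."""
    return np.bincount(img.pixels.ravel(), minlength=256)


def histogram_to_csv(hist: np.ndarray, path: str | Path) -> None:
    """Export a 256-bin histogram as a two-column ``level,count`` CSV."""
    with open(path, "w") as fh:
        fh.write("level,count\n")
        for level, count in enumerate(np.asarray(hist)):
            fh.write(f"{level},{int(count)}\n")
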