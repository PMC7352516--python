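"""Grey-level co-occurrence matrix (GLCM) texture features.

The co-occurrence matrix is built over the full 256 grey levels without
quantisation (distance 1, angle 0, symmetric by default) and the five
classic Haralick features are computed from it:

* angular second moment  ``ASM = sum p^2``
* contrast               ``sum (i - j)^2 p``
* correlation            ``sum (i - mu_x)(j - mu_y) p / (sigma_x sigma_y)``
* inverse difference moment ``IDM = sum p / (1 + (i - j)^2)``
* entropy                ``-sum p ln p``  (natural log)

On sliced images the white fill pixels take part in the matrix like any
other grey level, so texture features of a slice describe the spatial
arrangement of the kept pattern against its white background.

Correlation is undefined when either marginal is degenerate (e.g. a
constant image); it is reported as NaN with ``correlation_defined=False``
rather than raising.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.feature import graycomatrix

from .imgio import GreyImage

__all__ = ["GlcmFeatureSet", "GLCM_FEATURE_NAMES", "glcm", "glcm_features"]

GLCM_FEATURE_NAMES = ("asm", "contrast", "correlation", "idm", "entropy")


@dataclasses.dataclass(frozen=True)
class GlcmFeatureSet:
    asm: float
    contrast: float
    correlation: float
    idm: float
    entropy: float
    correlation_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLCM_FEATURE_NAMES}


def glcm(
    img: GreyImage,
    distance: int = 1,
    angle: float = 0.0,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalised 256x256 co-occurrence probability matrix.

    ``angle`` is in degrees following the usual convention (0 = horizontal
    neighbour, 90 = vertical).  The image must hold at least one pixel pair
    along the offset direction.
    """
    px = img.pixels
    rad = math.radians(angle)
    dr = round(distance * math.sin(rad))
    dc = round(distance * math.cos(rad))
    if px.shape[0] <= abs(dr) or px.shape[1] <= abs(dc):
        raise ValueError(
            f"image of shape {px.shape} is too small for offset distance={distance}, angle={angle}"
        )
    p = graycomatrix(px, [distance], [rad], levels=256, symmetric=symmetric, normed=True)
    return p[:, :, 0, 0]


def glcm_features(p: np.ndarray) -> GlcmFeatureSet:
    """The five texture features of a normalised co-occurrence matrix."""
    p = np.asarray(p, dtype=float)
    if p.shape[0] != p.shape[1] or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("glcm_features expects a square, normalised probability matrix")
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    diff2 = (i[:, None] - i[None, :]) ** 2

    asm = float((p * p).sum())
    contrast = float((diff2 * p).sum())
    idm = float((p / (1.0 + diff2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    px_marg = p.sum(axis=1)
    py_marg = p.sum(axis=0)
    mu_x = float((i * px_marg).sum())
    mu_y = float((i * py_marg).sum())
    var_x = float(((i - mu_x) ** 2 * px_marg).sum())
    var_y = float(((i - mu_y) ** 2 * py_marg).sum())
    if var_x <= 0 or var_y <= 0:
        corr, defined = float("nan"), False
    else:
        cov = float(((i[:, None] - mu_x) * (i[None, :] - mu_y) * p).sum())
        corr, defined = cov / math.sqrt(var_x * var_y), True
    return GlcmFeatureSet(asm, contrast, corr, idm, entropy, defined)
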