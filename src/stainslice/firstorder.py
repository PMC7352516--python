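"""Threshold-limited first-order statistics.

Unlike the texture and fractal families, these are computed strictly on the
pixels kept by a grey-level range — the white fill pixels of a slice are
excluded.  The canonical five features are area, skewness, kurtosis,
integrated density (mean x area) and raw integrated density (sum of kept
values); the mean is emitted as a derived auxiliary value.

Moment conventions follow common image-measurement tools: population
(biased) estimators, kurtosis in the excess convention (4th standardised
moment minus 3, so a Gaussian scores 0).  Sample-corrected estimators are
available via ``sample_corrected=True``.  Skewness and kurtosis are
undefined (NaN) when the kept set has zero spread or fewer than 4 pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .imgio import GreyImage
from .slicing import IntensityRange, kept_mask

__all__ = ["FirstOrderFeatureSet", "FIRSTORDER_FEATURE_NAMES", "first_order"]

#: Canonical five first-order features (mean is auxiliary).
FIRSTORDER_FEATURE_NAMES = ("area", "skewness", "kurtosis", "int_den", "raw_int_den")


@dataclasses.dataclass(frozen=True)
class FirstOrderFeatureSet:
    area: float
    skewness: float
    kurtosis: float
    int_den: float
    raw_int_den: float
    mean: float
    area_um2: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in FIRSTORDER_FEATURE_NAMES}
        d["mean"] = self.mean
        return d


def first_order(
    img: GreyImage,
    rng: IntensityRange,
    boundary: str = "macro",
    sample_corrected: bool = False,
) -> FirstOrderFeatureSet:
    """First-order statistics of the pixels kept by ``rng``.

    An empty kept set yields area 0, zero densities and NaN shape moments
    rather than an exception.
    """
    mask = kept_mask(img.pixels, rng, boundary)
    values = img.pixels[mask].astype(np.float64)
    area = float(values.size)
    area_um2 = area * img.pixel_size**2 if img.pixel_size is not None else None
    if area == 0:
        nan = float("nan")
        return FirstOrderFeatureSet(0.0, nan, nan, 0.0, 0.0, nan, area_um2)
    mean = float(values.mean())
    raw_int_den = float(values.sum())
    int_den = mean * area
    if area < 4 or values.std() == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(values, bias=not sample_corrected))
        kurt = float(stats.kurtosis(values, fisher=True, bias=not sample_corrected))
    return FirstOrderFeatureSet(area, skew, kurt, int_den, raw_int_den, mean, area_um2)
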