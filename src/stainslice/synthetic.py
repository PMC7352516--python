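"""Synthetic pan cytokeratin-like images and simulated patient cohorts.

The generator emulates the structure of a pan cytokeratin-stained breast
tumour section: dark-staining epithelial *tumour nests* — unions of
randomly placed, randomly oriented ellipses that merge where they overlap —
scattered over a light stroma background.  Pixel values inside nests are
drawn from a weighted mixture of the five "specific" grey-level ranges
(0-220) and stroma pixels from the two "non-specific" ranges (220-255);
the default weights reproduce the reported average share of image pixels in
the seven narrow ranges, 6/9/10/8/8/29/30 %, which corresponds to about
41 % of the frame covered by nests.  Additive Gaussian noise (clipped to
[0, 255]) roughens the per-range plateaus.

Simulated cohorts attach a binary metastasis outcome to a latent image
property (by default the per-patient nest area fraction) by a binormal
construction: the latent mean is shifted between outcome classes by
``delta = sqrt(2) * Phi^-1(effect_auc)`` standard deviations, which makes
the population AUC of the latent feature exactly ``effect_auc``.  Following
the source cohort, metastasis-positive patients have the *lower* staining
area.  Tumour size is simulated with its own mild association (AUC 0.65)
while age and ER status are outcome-neutral.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from skimage.draw import ellipse as draw_ellipse

from .imgio import GreyImage, ParameterError, write_image
from .slicing import IntensityRange

__all__ = [
    "NestImageSpec",
    "CohortSpec",
    "PatientRecord",
    "generate_image",
    "generate_cohort",
    "write_cohort",
    "nests_for_coverage",
]

log = logging.getLogger(__name__)

#: Default nest mixture: the five specific ranges weighted 6:9:10:8:8.
DEFAULT_NEST_MIX = (
    ((0, 130), 6 / 41), ((130, 160), 9 / 41), ((160, 180), 10 / 41),
    ((180, 200), 8 / 41), ((200, 220), 8 / 41),
)
#: Default stroma mixture: the two non-specific ranges weighted 29:30.
DEFAULT_STROMA_MIX = (((220, 240), 29 / 59), ((240, 255), 30 / 59))

#: Fraction of the frame covered by nests implied by the range shares
#: (specific staining = 6+9+10+8+8 = 41 %).
DEFAULT_NEST_AREA_FRACTION = 0.41

#: Empirical ratio of realised mean ellipse area to the analytic
#: pi * (r_mean^2 + r_sd^2), accounting for nests clipped at the frame
#: border (calibrated once on the default spec).
_EDGE_AREA_FACTOR = 0.889

#: Values are drawn this many levels inside a range's kept interval so that
#: the default additive noise rarely carries them across a range boundary.
_NOISE_GUARD = 2


def _validate_mix(mix, name: str) -> tuple[tuple[tuple[int, int], float], ...]:
    out = []
    total = 0.0
    for entry, weight in mix:
        if weight < 0:
            raise ParameterError(f"{name}: negative weight {weight}")
        if isinstance(entry, (int, np.integer)):
            lo, hi = int(entry), int(entry)
        else:
            lo, hi = int(entry[0]), int(entry[1])
        if not (0 <= lo <= hi <= 255):
            raise ParameterError(f"{name}: grey levels {entry} outside [0, 255]")
        out.append(((lo, hi), float(weight)))
        total += weight
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"{name}: weights sum to {total}, expected 1")
    return tuple(out)


@dataclasses.dataclass(frozen=True)
class NestImageSpec:
    """Parameters of one synthetic nest image.

    Mixture entries are ``((lo, hi), weight)`` pairs; values are drawn
    uniformly from the levels *kept* by the macro slicing rule for that
    range (``lo < v < hi``, or ``0 <= v < hi`` when ``lo = 0``), so a
    noise-free image has exactly the requested range shares.  A bare
    integer entry denotes a single grey level.
    """

    width: int = 256
    height: int = 256
    nest_count: int = 46
    nest_radius_mean: float = 16.0
    nest_radius_sd: float = 4.0
    nest_intensity_mix: tuple = DEFAULT_NEST_MIX
    stroma_intensity_mix: tuple = DEFAULT_STROMA_MIX
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ParameterError("image dimensions must be at least 64x64")
        if self.nest_count < 0 or self.nest_radius_mean <= 0 or self.noise_sd < 0:
            raise ParameterError("nest_count, nest_radius_mean and noise_sd must be non-negative")
        object.__setattr__(
            self, "nest_intensity_mix", _validate_mix(self.nest_intensity_mix, "nest_intensity_mix")
        )
        object.__setattr__(
            self, "stroma_intensity_mix",
            _validate_mix(self.stroma_intensity_mix, "stroma_intensity_mix"),
        )


def _kept_levels(lo: int, hi: int) -> np.ndarray:
    """Grey levels sampled for a (lo, hi) mixture range.

    These are the levels kept by the macro slicing rule, shrunk by a small
    guard band when the range is wide enough, so that additive noise rarely
    pushes a pixel across a range boundary.
    """
    if lo == hi:  # degenerate single-level entry
        return np.array([lo])
    start = lo if lo == 0 else lo + 1
    levels = np.arange(start, hi)
    if levels.size == 0:
        raise ParameterError(f"range {lo}-{hi} keeps no grey levels under the macro rule")
    if levels.size > 2 * _NOISE_GUARD + 2:
        levels = levels[_NOISE_GUARD : levels.size - _NOISE_GUARD]
    return levels


def _draw_mixture(rng: np.random.Generator, mix, n: int) -> np.ndarray:
    weights = np.array([w for _, w in mix])
    comp = rng.choice(len(mix), size=n, p=weights / weights.sum())
    values = np.empty(n, dtype=np.int64)
    for k, ((lo, hi), _) in enumerate(mix):
        levels = _kept_levels(lo, hi)
        sel = comp == k
        values[sel] = rng.choice(levels, size=int(sel.sum()))
    return values


def nest_mask(spec: NestImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of randomly placed, randomly oriented ellipses."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for _ in range(spec.nest_count):
        r = rng.uniform(0, spec.height)
        c = rng.uniform(0, spec.width)
        a = max(2.0, rng.normal(spec.nest_radius_mean, spec.nest_radius_sd))
        b = max(2.0, rng.normal(spec.nest_radius_mean, spec.nest_radius_sd))
        theta = rng.uniform(0, math.pi)
        rr, cc = draw_ellipse(r, c, a, b, shape=mask.shape, rotation=theta)
        mask[rr, cc] = True
    return mask


def generate_image(spec: NestImageSpec) -> GreyImage:
    """Deterministically render one synthetic nest image from its spec."""
    rng = np.random.default_rng(spec.seed)
    mask = nest_mask(spec, rng)
    img = np.empty((spec.height, spec.width), dtype=np.int64)
    n_nest = int(mask.sum())
    img[mask] = _draw_mixture(rng, spec.nest_intensity_mix, n_nest)
    img[~mask] = _draw_mixture(rng, spec.stroma_intensity_mix, img.size - n_nest)
    if spec.noise_sd > 0:
        noisy = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        clipped = (noisy < 0) | (noisy > 255)
        if clipped.mean() > 0.01:
            log.warning("%.1f%% of pixels clipped by noise", 100 * clipped.mean())
        img = np.clip(np.round(noisy), 0, 255).astype(np.int64)
    return GreyImage(img.astype(np.uint8))


def nests_for_coverage(coverage: float, spec: NestImageSpec) -> int:
    """Nest count whose random-ellipse union covers ~``coverage`` of the frame.

    Uses the Poisson-union approximation ``coverage = 1 - exp(-n*A/WH)``
    with the mean ellipse area corrected for border clipping.
    """
    coverage = float(np.clip(coverage, 0.02, 0.95))
    mean_area = _EDGE_AREA_FACTOR * math.pi * (spec.nest_radius_mean**2 + spec.nest_radius_sd**2)
    n = -math.log(1.0 - coverage) * spec.width * spec.height / mean_area
    return max(1, round(n))


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Shape and effect-size parameters of a simulated patient cohort."""

    n_patients: int = 102
    images_per_patient: int = 5
    prevalence: float = 0.2
    effect_feature: str = "nest_area_fraction"
    effect_auc: float = 0.8
    seed: int = 0
    #: "exact": round(prevalence * n) positives at random positions;
    #: "binomial": independent Bernoulli outcomes.
    positives: str = "exact"
    #: Between-patient SD of the latent feature (area-fraction units).
    latent_sd: float = 0.07

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ParameterError("prevalence must be in (0, 1)")
        if not (0.5 <= self.effect_auc <= 1.0):
            raise ParameterError("effect_auc must be in [0.5, 1.0]")
        if self.effect_feature not in ("nest_area_fraction", "intensity_heterogeneity"):
            raise ParameterError(f"unknown effect_feature {self.effect_feature!r}")
        if self.positives not in ("exact", "binomial"):
            raise ParameterError("positives must be 'exact' or 'binomial'")


@dataclasses.dataclass
class PatientRecord:
    patient_id: str
    outcome: int
    latent: float
    images: list[GreyImage]
    image_specs: list[NestImageSpec]
    age: int
    tumor_size: float
    er_status: int


def generate_cohort(
    spec: CohortSpec,
    image_spec: NestImageSpec | None = None,
) -> list[PatientRecord]:
    """Simulate a cohort of patients with per-patient image sets.

    The latent effect feature discriminates outcome classes with population
    AUC ``spec.effect_auc`` (binormal construction; positives shifted to
    lower values).  Each patient's images are rendered from ``image_spec``
    with the latent property substituted and per-image seeds derived from
    ``spec.seed``.
    """
    base = NestImageSpec() if image_spec is None else image_spec
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if spec.positives == "exact":
        n_pos = round(spec.prevalence * n)
        outcome = np.zeros(n, dtype=int)
        outcome[rng.choice(n, size=n_pos, replace=False)] = 1
    else:
        outcome = (rng.uniform(size=n) < spec.prevalence).astype(int)

    delta = math.sqrt(2.0) * norm.ppf(spec.effect_auc)
    if spec.effect_feature == "nest_area_fraction":
        mu0, sd = DEFAULT_NEST_AREA_FRACTION, spec.latent_sd
    else:
        mu0, sd = max(base.noise_sd, 1.0), 0.25 * max(base.noise_sd, 1.0)
    latent = rng.normal(mu0, sd, size=n) - delta * sd * outcome

    # tumour size carries its own mild prognostic signal (AUC 0.65)
    ts_delta = math.sqrt(2.0) * norm.ppf(0.65) * 6.0
    tumor_size = np.round(rng.normal(22.0, 6.0, size=n) + ts_delta * outcome, 1)
    age = np.clip(np.round(rng.normal(57.0, 9.0, size=n)), 37, 80).astype(int)
    er = (rng.uniform(size=n) < 0.69).astype(int)

    records = []
    seed_stream = rng.integers(0, 2**31 - 1, size=n * spec.images_per_patient)
    for i in range(n):
        fields: dict = {}
        if spec.effect_feature == "nest_area_fraction":
            fields["nest_count"] = nests_for_coverage(latent[i], base)
        else:
            fields["noise_sd"] = float(np.clip(latent[i], 0.0, 40.0))
        specs, images = [], []
        for j in range(spec.images_per_patient):
            s = dataclasses.replace(
                base, seed=int(seed_stream[i * spec.images_per_patient + j]), **fields
            )
            specs.append(s)
            images.append(generate_image(s))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                outcome=int(outcome[i]),
                latent=float(latent[i]),
                images=images,
                image_specs=specs,
                age=int(age[i]),
                tumor_size=float(tumor_size[i]),
                er_status=int(er[i]),
            )
        )
    return records


def write_cohort(records: list[PatientRecord], outdir: str | Path) -> pd.DataFrame:
    """Write cohort images as PNGs plus a manifest CSV; returns the manifest.

    The manifest has one row per image: patient_id, image_path, outcome and
    the clinicopathological covariates.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for j, img in enumerate(rec.images):
            rel = Path("images") / f"{rec.patient_id}_{j + 1}.png"
            write_image(img, outdir / rel)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "image_path": str(rel),
                    "outcome": rec.outcome,
                    "age": rec.age,
                    "tumor_size": rec.tumor_size,
                    "er_status": rec.er_status,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# re-exported for convenience in tests and analysis scripts
SEVEN_RANGE_SHARES = {
    IntensityRange(lo, hi).label: share
    for (lo, hi), share in [
        ((0, 130), 0.06), ((130, 160), 0.09), ((160, 180), 0.10), ((180, 200), 0.08),
        ((200, 220), 0.08), ((220, 240), 0.29), ((240, 255), 0.30),
    ]
}
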