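"""Per-image feature extraction and per-patient aggregation.

For every image and every analysis range (by default the original 0-255
image, the seven narrow ranges and the specific/non-specific 0-220 /
220-255 split) a row of 33 canonical features is produced: the five GLCM
texture features and the 23 monofractal features computed on the
white-filled sliced image, and the five first-order statistics computed on
the kept pixels only.  The derived mean intensity is carried as an
auxiliary column.

Undefined values (correlation of a degenerate matrix, shape moments of an
empty slice, ...) propagate as NaN — never as silent zeros — and are
excluded pairwise when image rows are averaged into the per-patient cohort
table.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .firstorder import FIRSTORDER_FEATURE_NAMES, first_order
from .fractal import FRACTAL_FEATURE_NAMES, default_box_sizes, fractal_features
from .glcm import GLCM_FEATURE_NAMES, glcm as glcm_matrix, glcm_features
from .imgio import GreyImage, read_image
from .slicing import DEFAULT_ANALYSIS_RANGES, IntensityRange, slice_image

__all__ = [
    "ExtractionConfig",
    "CANONICAL_FEATURES",
    "AUXILIARY_FEATURES",
    "FEATURE_FAMILIES",
    "extract_features",
    "aggregate_patients",
]

log = logging.getLogger(__name__)

#: The 33 canonical features per image x range (5 GLCM + 23 fractal +
#: 5 first-order).
CANONICAL_FEATURES = tuple(GLCM_FEATURE_NAMES) + tuple(FRACTAL_FEATURE_NAMES) + tuple(
    FIRSTORDER_FEATURE_NAMES
)
AUXILIARY_FEATURES = ("mean",)

FEATURE_FAMILIES = {
    **{name: "glcm" for name in GLCM_FEATURE_NAMES},
    **{name: "fractal" for name in FRACTAL_FEATURE_NAMES},
    **{name: "first_order" for name in FIRSTORDER_FEATURE_NAMES},
    "mean": "first_order",
}


@dataclasses.dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the per-image extraction stage."""

    ranges: tuple[IntensityRange, ...] = DEFAULT_ANALYSIS_RANGES
    boundary: str = "macro"
    glcm_distance: int = 1
    glcm_angle: float = 0.0
    glcm_symmetric: bool = True
    fractal_grids: int = 12
    fractal_box_sizes: tuple[int, int, int] = (5, 575, 3)
    fractal_seed: int = 0
    fractal_counting: str = "differential"

    def box_sizes(self) -> np.ndarray:
        lo, hi, step = self.fractal_box_sizes
        return default_box_sizes(lo, hi, step)


def _image_range_row(
    img: GreyImage, rng: IntensityRange, config: ExtractionConfig
) -> dict[str, float]:
    sliced = slice_image(img, rng, config.boundary)
    row: dict[str, float] = {}
    p = glcm_matrix(
        sliced.image, config.glcm_distance, config.glcm_angle, config.glcm_symmetric
    )
    row.update(glcm_features(p).as_dict())
    row.update(
        fractal_features(
            sliced.image,
            n_grids=config.fractal_grids,
            box_sizes=config.box_sizes(),
            seed=config.fractal_seed,
            counting=config.fractal_counting,
        ).as_dict()
    )
    row.update(first_order(img, rng, config.boundary).as_dict())
    return row


def extract_features(
    images: dict[str, GreyImage | str | Path],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Long-format feature table: one row per image x range.

    ``images`` maps an image id to a :class:`GreyImage` or a readable path.
    Unreadable images are skipped with a logged reason; the run continues.
    """
    config = config or ExtractionConfig()
    rows = []
    for image_id, source in images.items():
        if not isinstance(source, GreyImage):
            try:
                loaded = read_image(source)
            except Exception as exc:
                log.warning("skipping image %s: %s", image_id, exc)
                continue
            if not isinstance(loaded, GreyImage):
                log.warning("skipping image %s: RGB input requires stain decomposition", image_id)
                continue
            source = loaded
        for rng in config.ranges:
            row = {"image_id": image_id, "range_label": rng.label}
            row.update(_image_range_row(source, rng, config))
            rows.append(row)
    columns = ["image_id", "range_label", *CANONICAL_FEATURES, *AUXILIARY_FEATURES]
    return pd.DataFrame(rows, columns=columns)


def aggregate_patients(rows: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Average image rows into one wide row per patient.

    ``manifest`` maps image ids to patients and carries ``outcome`` plus any
    covariate columns (one row per image, as written by
    :func:`stainslice.synthetic.write_cohort`; an ``image_id`` column is
    derived from ``image_path`` when absent).  Feature columns are named
    ``"<range>|<feature>"``.  NaN feature values are excluded from the mean
    (logged); patients without a single valid image are dropped with a
    warning.
    """
    manifest = manifest.copy()
    if "image_id" not in manifest.columns:
        if "image_path" not in manifest.columns:
            raise ValueError("manifest must have an image_id or image_path column")
        manifest["image_id"] = manifest["image_path"].map(lambda p: Path(p).stem)
    if "outcome" not in manifest.columns:
        raise ValueError("manifest is missing the required column 'outcome'")
    if "patient_id" not in manifest.columns:
        raise ValueError("manifest is missing the required column 'patient_id'")

    merged = rows.merge(
        manifest[["image_id", "patient_id"]], on="image_id", how="left", validate="many_to_one"
    )
    unmapped = merged["patient_id"].isna()
    if unmapped.any():
        raise ValueError(
            f"{sorted(merged.loc[unmapped, 'image_id'].unique())} not present in the manifest"
        )

    feature_cols = [*CANONICAL_FEATURES, *AUXILIARY_FEATURES]
    n_undefined = int(merged[feature_cols].isna().sum().sum())
    if n_undefined:
        log.info("excluding %d undefined feature values from patient means", n_undefined)

    wide_blocks = []
    for rng_label, block in merged.groupby("range_label", sort=False):
        per_patient = block.groupby("patient_id")[feature_cols].mean()  # skipna by default
        per_patient.columns = [f"{rng_label}|{c}" for c in feature_cols]
        wide_blocks.append(per_patient)
    wide = pd.concat(wide_blocks, axis=1)

    covar_cols = [
        c for c in manifest.columns if c not in ("image_id", "image_path", "patient_id")
    ]
    per_patient_meta = manifest.groupby("patient_id")[covar_cols].first()
    out = per_patient_meta.join(wide, how="inner").reset_index()

    missing = set(manifest["patient_id"]) - set(out["patient_id"])
    if missing:
        log.warning("patients without any valid image excluded: %s", sorted(missing))
    bad = ~out["outcome"].isin((0, 1))
    if bad.any():
        raise ValueError("outcome column must be binary 0/1")
    return out
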