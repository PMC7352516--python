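"""End-to-end orchestration: manifest -> features -> cohort -> evaluation.

A run is fully described by a JSON-serialisable :class:`RunConfig`; its
hash is embedded in the run metadata so outputs can be traced to the exact
configuration.  Given identical inputs, configuration and seeds, every
data output (CSV, PNG) is byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import prognostics as prog
from .imgio import GreyImage, histogram_to_csv, intensity_histogram, read_image, write_image
from .pipeline import (
    AUXILIARY_FEATURES,
    CANONICAL_FEATURES,
    FEATURE_FAMILIES,
    ExtractionConfig,
    aggregate_patients,
    extract_features,
)
from .slicing import DEFAULT_NARROW_RANGES, binary_mask, overlay, slice_all

__all__ = ["RunConfig", "evaluate_cohort", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "tumor_size", "er_status")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    extraction: ExtractionConfig = dataclasses.field(default_factory=ExtractionConfig)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    bootstrap_resamples: int = 1000
    seed: int = 7
    alpha: float = 0.05
    figures: bool = True

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True, indent=2)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        ext = raw.pop("extraction", {})
        ranges = ext.pop("ranges", None)
        from .slicing import IntensityRange

        kwargs = {}
        if ranges is not None:
            kwargs["ranges"] = tuple(IntensityRange(**r) for r in ranges)
        if "fractal_box_sizes" in ext:
            ext["fractal_box_sizes"] = tuple(ext["fractal_box_sizes"])
        extraction = ExtractionConfig(**kwargs, **ext)
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(extraction=extraction, **raw)


def evaluate_cohort(
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
    covariates: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Prognostic evaluation of a wide per-patient feature table.

    Returns three result tables: ``per_feature`` (AUC, CI, p and, for
    significant features, the bootstrap optimism-corrected AUC, one row per
    feature x range), ``per_range`` (mean folded AUC and significant
    improvement sums per feature family) and ``stepwise`` (the multivariate
    stepwise logistic model over univariately significant features plus
    covariates).
    """
    config = config or RunConfig()
    covariates = config.covariates if covariates is None else covariates
    y = cohort["outcome"].to_numpy(int)

    feature_cols = [
        c for c in cohort.columns
        if "|" in c and c.split("|", 1)[1] in CANONICAL_FEATURES + AUXILIARY_FEATURES
    ]
    rows = []
    for col in feature_cols:
        rng_label, feat = col.split("|", 1)
        s = cohort[col].to_numpy(float)
        if not np.isfinite(s).any() or np.nanstd(s) == 0:
            rows.append({"range": rng_label, "feature": feat, "auc": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "p": np.nan, "auc_corrected": np.nan})
            continue
        r = prog.roc(s, y)
        corrected = np.nan
        if r.p <= config.alpha and config.bootstrap_resamples > 0:
            corrected = prog.bootstrap_validate(
                s[np.isfinite(s)], y[np.isfinite(s)],
                n_resamples=config.bootstrap_resamples, seed=config.seed,
            ).corrected
        rows.append({"range": rng_label, "feature": feat, "auc": r.auc, "ci_lo": r.ci_lo,
                     "ci_hi": r.ci_hi, "p": r.p, "auc_corrected": corrected})
    per_feature = pd.DataFrame(rows)

    auc_tab = per_feature.pivot(index="feature", columns="range", values="auc")
    p_tab = per_feature.pivot(index="feature", columns="range", values="p")
    original = "0-255" if "0-255" in auc_tab.columns else auc_tab.columns[0]
    per_range = prog.range_summary(auc_tab, p_tab, FEATURE_FAMILIES, original=original,
                                   alpha=config.alpha)

    significant = per_feature.loc[per_feature["p"] <= config.alpha]
    candidates = [f"{r}|{f}" for r, f in zip(significant["range"], significant["feature"])]
    candidates += [c for c in covariates if c in cohort.columns]
    if candidates:
        model = prog.stepwise_logistic(cohort, candidates, entry=config.alpha,
                                       remain=config.alpha)
        stepwise = model.table.reset_index(names="term")
    else:
        stepwise = pd.DataFrame(columns=["term", "coef", "hr", "ci_lo", "ci_hi", "p"])
    return {"per_feature": per_feature, "per_range": per_range.reset_index(names="range"),
            "stepwise": stepwise}


def _write_figures(images: dict[str, GreyImage], outdir: Path) -> None:
    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    image_id, img = next(iter(images.items()))
    histogram_to_csv(intensity_histogram(img), figdir / f"{image_id}_histogram.csv")
    for sliced in slice_all(img, DEFAULT_NARROW_RANGES):
        stem = f"{image_id}_{sliced.range.label}"
        write_image(sliced.image, figdir / f"{stem}.png")
        write_image(GreyImage(binary_mask(sliced)), figdir / f"{stem}_mask.png")
        write_image(overlay(img, sliced), figdir / f"{stem}_overlay.png")


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    outdir: str | Path,
    config: RunConfig | None = None,
    image_root: str | Path | None = None,
) -> dict[str, Path]:
    """Run extraction, aggregation and evaluation; write the output bundle.

    ``manifest`` is a CSV (or frame) with columns patient_id, image_path,
    outcome and optional covariates.  Outputs: features_long.csv,
    per_patient.csv, per_feature_auc.csv, per_range_summary.csv,
    stepwise_model.csv, run_config.json, run_metadata.json, figures/ and
    run.log.  Any stage failure aborts with a stage-labelled message.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("stainslice")
    root.addHandler(handler)
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}
    try:
        stage = "validate-manifest"
        t0 = time.perf_counter()
        mf = pd.read_csv(manifest) if not isinstance(manifest, pd.DataFrame) else manifest.copy()
        for col in ("patient_id", "image_path", "outcome"):
            if col not in mf.columns:
                raise ValueError(f"[{stage}] manifest is missing the required column '{col}'")
        root_dir = Path(image_root) if image_root is not None else (
            Path(manifest).parent if not isinstance(manifest, pd.DataFrame) else Path(".")
        )
        timings[stage] = time.perf_counter() - t0

        stage = "extract"
        t0 = time.perf_counter()
        mf["image_id"] = mf["image_path"].map(lambda p: Path(p).stem)
        images: dict[str, object] = {
            row.image_id: root_dir / row.image_path for row in mf.itertuples()
        }
        features = extract_features(images, config.extraction)
        outputs["features_long"] = outdir / "features_long.csv"
        features.to_csv(outputs["features_long"], index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "aggregate"
        t0 = time.perf_counter()
        cohort = aggregate_patients(features, mf)
        outputs["per_patient"] = outdir / "per_patient.csv"
        cohort.to_csv(outputs["per_patient"], index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        tables = evaluate_cohort(cohort, config)
        for name, frame in tables.items():
            key = {"per_feature": "per_feature_auc", "per_range": "per_range_summary",
                   "stepwise": "stepwise_model"}[name]
            outputs[key] = outdir / f"{key}.csv"
            frame.to_csv(outputs[key], index=False)
        timings[stage] = time.perf_counter() - t0

        if config.figures:
            stage = "figures"
            t0 = time.perf_counter()
            loaded = {}
            first = mf.iloc[0]
            img = read_image(root_dir / first.image_path)
            if isinstance(img, GreyImage):
                loaded[first.image_id] = img
                _write_figures(loaded, outdir)
            timings[stage] = time.perf_counter() - t0

        stage = "metadata"
        (outdir / "run_config.json").write_text(config.to_json())
        meta = {
            "config_hash": config.config_hash,
            "n_patients": int(cohort.shape[0]),
            "n_images": int(mf.shape[0]),
            "outputs": {k: str(v) for k, v in outputs.items()},
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        outputs["run_config"] = outdir / "run_config.json"
        outputs["run_metadata"] = outdir / "run_metadata.json"
        return outputs
    except ValueError as exc:
        if str(exc).startswith("["):
            raise
        raise ValueError(f"[{stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
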