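"""Prognostic evaluation of image features against a binary endpoint.

The toolbox mirrors a classic biomarker workflow with metastasis
occurrence as the endpoint:

* per-feature ROC analysis — the Mann-Whitney AUC (half credit for ties)
  with DeLong standard error, 95 % CI and a two-sided p-value against the
  chance value 0.5;
* AUC *folding*, ``max(a, 1 - a)``: an AUC below 0.5 marks an association
  with the opposite class, so its distance from 0.5 is what carries
  prognostic information when AUCs are averaged;
* bootstrap internal validation (default 1000 patient-level resamples):
  the optimism of the direction-chosen AUC is estimated and subtracted;
* optimal-cutoff dichotomisation by exhaustive chi-square maximisation
  over candidate cutoffs within the 10th-90th percentile window (the
  published principle of the X-tile cutpoint selector);
* Spearman rank correlation between dichotomised classifiers (redundancy
  screen);
* stepwise multivariate binary logistic regression (forward selection with
  backward elimination, likelihood-ratio p-values, entry/remain p <= 0.05)
  on continuous feature values;
* per-range AUC summaries: the mean folded AUC of every feature in a range
  and the summed significant AUC improvements over the original images;
* a Hanley-McNeil ROC sample-size computation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "RocResult",
    "BootstrapResult",
    "CutoffResult",
    "StepwiseModel",
    "SampleSizeResult",
    "roc",
    "auc_mann_whitney",
    "fold_auc",
    "bootstrap_validate",
    "optimal_cutoff",
    "spearman_matrix",
    "stepwise_logistic",
    "range_summary",
    "roc_sample_size",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# ROC / AUC
# --------------------------------------------------------------------------- #

def _clean(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    return s, y.astype(int)


def auc_mann_whitney(scores, outcomes) -> float:
    """Mann-Whitney AUC estimate with half credit for ties."""
    s, y = _clean(scores, outcomes)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


@dataclasses.dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lo: float
    ci_hi: float
    p: float
    se: float
    n_pos: int
    n_neg: int
    auc_boot_corrected: float | None = None


def roc(scores, outcomes) -> RocResult:
    """ROC analysis of a continuous score: AUC, DeLong 95 % CI and p vs 0.5.

    Missing scores are dropped pairwise.  Raises when only one outcome
    class is present.
    """
    s, y = _clean(scores, outcomes)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    v_pos = (tz[:m] - tx) / n          # placements of positives among negatives
    v_neg = 1.0 - (tz[m:] - ty) / m    # placements of negatives among positives
    var = (np.var(v_pos, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v_neg, ddof=1) / n if n > 1 else 0.0
    )
    se = math.sqrt(max(var, 0.0))
    if se == 0:
        p = 1.0 if auc == 0.5 else 0.0
        ci_lo = ci_hi = auc
    else:
        z = abs(auc - 0.5) / se
        p = 2 * (1 - stats.norm.cdf(z))
        ci_lo = max(0.0, auc - 1.959963984540054 * se)
        ci_hi = min(1.0, auc + 1.959963984540054 * se)
    return RocResult(auc, ci_lo, ci_hi, float(p), se, m, n)


def fold_auc(a: float) -> float:
    """Fold an AUC into the 0.5-1.0 band: ``max(a, 1 - a)``."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"AUC {a} outside [0, 1]")
    return max(a, 1.0 - a)


# --------------------------------------------------------------------------- #
# Bootstrap internal validation
# --------------------------------------------------------------------------- #

@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    apparent: float
    optimism: float
    corrected: float
    ci_lo: float
    ci_hi: float
    n_resamples: int
    n_redrawn: int


def bootstrap_validate(
    scores, outcomes, n_resamples: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Optimism-corrected AUC by patient-level bootstrap resampling.

    The data-driven part of a univariate AUC readout is the choice of
    direction (which side of the score marks high risk); folding the AUC to
    ``max(a, 1-a)`` performs that choice.  Each resample re-chooses the
    direction, its folded AUC is compared with that direction applied to
    the original sample, and the mean difference (the optimism) is
    subtracted from the apparent folded AUC.  The CI is the percentile
    interval of the folded resample AUCs.  Degenerate single-class
    resamples are redrawn (counted).
    """
    s, y = _clean(scores, outcomes)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("bootstrap_validate requires both outcome classes")
    rng = np.random.default_rng(seed)
    auc0 = auc_mann_whitney(s, y)
    apparent = fold_auc(auc0)
    n = s.size
    optimisms = np.empty(n_resamples)
    boot_aucs = np.empty(n_resamples)
    redrawn = 0
    for b in range(n_resamples):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            redrawn += 1
        auc_b = auc_mann_whitney(s[idx], yb)
        direction = 1.0 if auc_b >= 0.5 else -1.0
        on_original = auc0 if direction > 0 else 1.0 - auc0
        boot_aucs[b] = fold_auc(auc_b)
        optimisms[b] = fold_auc(auc_b) - on_original
    optimism = float(optimisms.mean())
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    return BootstrapResult(
        apparent, optimism, apparent - optimism, float(lo), float(hi), n_resamples, redrawn
    )


# --------------------------------------------------------------------------- #
# Optimal cutoff (X-tile principle)
# --------------------------------------------------------------------------- #

@dataclasses.dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    chi2: float
    n_low: int
    n_high: int
    high_risk: str  # "above" or "below"


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]] (no correction)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def optimal_cutoff(scores, outcomes, percentile_window: tuple[float, float] = (10, 90)) -> CutoffResult:
    """Best dichotomising cutoff by exhaustive chi-square maximisation.

    Candidates are midpoints between consecutive sorted unique scores,
    restricted to the given percentile window of the score distribution.
    Ties in chi-square resolve to the smaller cutoff.
    """
    s, y = _clean(scores, outcomes)
    if s.size < 8:
        raise ValueError("optimal_cutoff requires at least 8 patients")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; no cutoff exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo, hi = np.percentile(s, percentile_window)
    window = mids[(mids >= lo) & (mids <= hi)]
    if window.size == 0:
        log.warning("no cutoff candidate inside the percentile window; using all midpoints")
        window = mids
    best_cut, best_chi2 = None, -1.0
    for cut in window:  # increasing order; strict > keeps the smaller tie
        high = s > cut
        a = int((high & (y == 1)).sum())
        b = int((high & (y == 0)).sum())
        c = int((~high & (y == 1)).sum())
        d = int((~high & (y == 0)).sum())
        chi2 = _chi2_2x2(a, b, c, d)
        if chi2 > best_chi2:
            best_cut, best_chi2 = float(cut), float(chi2)
    high = s > best_cut
    rate_high = y[high].mean() if high.any() else 0.0
    rate_low = y[~high].mean() if (~high).any() else 0.0
    return CutoffResult(
        best_cut, best_chi2, int((~high).sum()), int(high.sum()),
        "above" if rate_high >= rate_low else "below",
    )


def spearman_matrix(classifiers: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p between (dichotomised) classifiers.

    Zero-variance classifiers yield NaN against everything; the diagonal
    is exactly 1.
    """
    if len(classifiers) < 3:
        raise ValueError("spearman_matrix requires at least 3 patients")
    cols = list(classifiers.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            x, yv = classifiers[a].to_numpy(float), classifiers[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                r = p = float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.spearmanr(x, yv)
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


# --------------------------------------------------------------------------- #
# Stepwise logistic regression
# --------------------------------------------------------------------------- #

@dataclasses.dataclass(frozen=True)
class StepwiseModel:
    """Retained terms with coefficient, HR = exp(coef), Wald 95 % CI and
    likelihood-ratio p-value."""

    table: pd.DataFrame  # index: term; columns: coef, hr, ci_lo, ci_hi, p
    excluded: tuple[str, ...] = ()

    @property
    def terms(self) -> list[str]:
        return list(self.table.index)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        res = model.fit(disp=0, maxiter=200)
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 1e3:
        raise np.linalg.LinAlgError("separation or non-identified fit")
    return res


def _lr_pvalue(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    lr = max(0.0, 2.0 * (llf_full - llf_reduced))
    return float(stats.chi2.sf(lr, df))


def stepwise_logistic(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome: str = "outcome",
    entry: float = 0.05,
    remain: float = 0.05,
) -> StepwiseModel:
    """Forward selection with backward elimination on continuous candidates.

    At each forward step the candidate with the smallest likelihood-ratio
    p-value enters if p <= ``entry``; backward steps drop any included term
    whose drop-one likelihood-ratio p-value exceeds ``remain``.  Candidates
    that cannot be fit (perfect separation, collinearity) are excluded with
    a warning.  Rows with missing values in any candidate are dropped.
    """
    data = cohort[[outcome, *candidates]].dropna()
    y = data[outcome].to_numpy(int)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    included: list[str] = []
    excluded: list[str] = []

    def llf(terms: list[str]) -> float:
        if terms:
            return _fit_logit(y, data[terms]).llf
        return _fit_logit(y, data[[]]).llf

    changed = True
    while changed:
        changed = False
        # forward
        best_p, best_term = None, None
        ll0 = llf(included)
        for term in candidates:
            if term in included or term in excluded:
                continue
            try:
                ll1 = llf(included + [term])
            except Exception as exc:
                log.warning("candidate %s excluded: %s", term, exc)
                excluded.append(term)
                continue
            p = _lr_pvalue(ll1, ll0)
            if best_p is None or p < best_p:
                best_p, best_term = p, term
        if best_term is not None and best_p <= entry:
            included.append(best_term)
            changed = True
        # backward
        while len(included) > 0:
            ll_full = llf(included)
            drop_p = {
                t: _lr_pvalue(ll_full, llf([u for u in included if u != t])) for t in included
            }
            worst = max(drop_p, key=drop_p.get)
            if drop_p[worst] > remain:
                included.remove(worst)
                changed = True
            else:
                break

    if not included:
        empty = pd.DataFrame(columns=["coef", "hr", "ci_lo", "ci_hi", "p"])
        return StepwiseModel(empty, tuple(excluded))
    res = _fit_logit(y, data[included])
    ll_full = res.llf
    rows = {}
    conf = res.conf_int()
    old = np.seterr(over="ignore")
    for t in included:
        beta = float(res.params[t])
        lo, hi = float(conf.loc[t, 0]), float(conf.loc[t, 1])
        rows[t] = {
            "coef": beta,
            "hr": float(np.exp(beta)),
            "ci_lo": float(np.exp(lo)),
            "ci_hi": float(np.exp(hi)),
            "p": _lr_pvalue(ll_full, llf([u for u in included if u != t])),
        }
    np.seterr(**old)
    return StepwiseModel(pd.DataFrame(rows).T[["coef", "hr", "ci_lo", "ci_hi", "p"]],
                         tuple(excluded))


# --------------------------------------------------------------------------- #
# Range-level summaries
# --------------------------------------------------------------------------- #

def range_summary(
    auc_table: pd.DataFrame,
    p_table: pd.DataFrame,
    families: dict[str, str],
    original: str = "0-255",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-range mean folded AUC and summed significant AUC improvements.

    ``auc_table`` and ``p_table`` are feature x range frames.  The mean
    folded AUC averages ``max(a, 1-a)`` over the features available in each
    range.  A feature's improvement in a narrow range is
    ``max(0, |AUC_range - 0.5| - |AUC_original - 0.5|)`` and is counted
    only when the feature is significant (p <= alpha) in that range;
    improvements are summed per feature family and in total.  The original
    column gets NaN improvements (it is the baseline).
    """
    if original not in auc_table.columns:
        raise ValueError(f"AUC table lacks the original-image column {original!r}")
    fams = sorted(set(families.get(f, "other") for f in auc_table.index))
    rows = {}
    for rng in auc_table.columns:
        aucs = auc_table[rng].dropna()
        row = {"mean_folded_auc": float(np.mean([fold_auc(a) for a in aucs])) if len(aucs) else np.nan}
        if rng == original:
            for fam in fams:
                row[f"improvement_{fam}"] = np.nan
            row["improvement_total"] = np.nan
        else:
            fam_sums = dict.fromkeys(fams, 0.0)
            for feat in auc_table.index:
                a_r = auc_table.loc[feat, rng]
                a_o = auc_table.loc[feat, original]
                p_r = p_table.loc[feat, rng]
                if np.isnan(a_r) or np.isnan(a_o) or np.isnan(p_r) or p_r > alpha:
                    continue
                gain = max(0.0, abs(a_r - 0.5) - abs(a_o - 0.5))
                fam_sums[families.get(feat, "other")] += gain
            for fam, val in fam_sums.items():
                row[f"improvement_{fam}"] = val
            row["improvement_total"] = sum(fam_sums.values())
        rows[rng] = row
    return pd.DataFrame(rows).T


# --------------------------------------------------------------------------- #
# ROC sample size (Hanley-McNeil)
# --------------------------------------------------------------------------- #

@dataclasses.dataclass(frozen=True)
class SampleSizeResult:
    n_pos: int
    n_neg: int

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg


def hanley_mcneil_variance(theta: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil variance of the Mann-Whitney AUC estimator."""
    q1 = theta / (2.0 - theta)
    q2 = 2.0 * theta**2 / (1.0 + theta)
    return (
        theta * (1 - theta) + (n_pos - 1) * (q1 - theta**2) + (n_neg - 1) * (q2 - theta**2)
    ) / (n_pos * n_neg)


def roc_sample_size(
    auc_alt: float = 0.67,
    auc_null: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.80,
    neg_pos_ratio: float = 1.0,
    sided: int = 2,
    variance_at: str = "alternative",
    max_n: int = 100_000,
) -> SampleSizeResult:
    """Minimal group sizes for a test of AUC = ``auc_null`` vs ``auc_alt``.

    Iterates over the positive-group size (negatives =
    ``ceil(neg_pos_ratio * n_pos)``) until
    ``z_alpha * sqrt(V0) + z_beta * sqrt(V1) <= auc_alt - auc_null`` with
    the Hanley-McNeil variances ``V0``/``V1``.  ``variance_at`` selects
    whether the null-hypothesis variance is evaluated at ``auc_null``
    ("null") or, like the common clinical calculators, at the alternative
    AUC ("alternative", default).  With the defaults — equal allocation,
    two-sided alpha 0.05, power 0.80 — detecting AUC 0.67 against chance
    requires 40 + 40 = 80 patients.
    """
    if not auc_null < auc_alt <= 1.0:
        raise ValueError("auc_alt must exceed auc_null (an AUC of 0.5 is undetectable)")
    if neg_pos_ratio <= 0:
        raise ValueError("neg_pos_ratio must be positive")
    if sided not in (1, 2):
        raise ValueError("sided must be 1 or 2")
    if variance_at not in ("alternative", "null"):
        raise ValueError("variance_at must be 'alternative' or 'null'")
    za = stats.norm.ppf(1 - alpha / sided)
    zb = stats.norm.ppf(power)
    delta = auc_alt - auc_null
    for n_pos in range(2, max_n):
        n_neg = math.ceil(neg_pos_ratio * n_pos)
        v1 = hanley_mcneil_variance(auc_alt, n_pos, n_neg)
        v0 = v1 if variance_at == "alternative" else hanley_mcneil_variance(auc_null, n_pos, n_neg)
        if za * math.sqrt(v0) + zb * math.sqrt(v1) <= delta:
            return SampleSizeResult(n_pos, n_neg)
    raise RuntimeError("sample size search did not converge")
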