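"""Greyscale box-counting fractal analysis with repositioned grids.

For each box size ``eps`` the image is tiled (from a grid offset) into
``eps x eps`` boxes and three per-box summaries are accumulated:

* a *differential box count*: the number of grey-level boxes of height
  ``h = eps * 256 / min(W, H)`` needed to span the box's intensity range,
  ``n_b = floor(I_max / h) - floor(I_min / h) + 1`` (Sarkar-Chaudhuri
  counting).  ``N(eps) = sum n_b`` scales as ``eps**-D_B``.
* the box *mass* ``m_b = sum(255 - v)``: inverted intensity, so stain-dense
  (dark) boxes are heavy.  The mean mass ``mu(eps)`` scales as
  ``eps**D_M`` and the mass dispersion yields the lacunarity
  ``lambda(eps) = (sigma(eps) / mu(eps))**2``.
* for binary masks, a classic *binary box count* (``counting="binary"``):
  a box counts 1 when it holds any non-white pixel.  This is the right
  estimator for the set dimension of a 0/255 image; differential counting
  applied to a binary image measures its intensity *surface* instead
  (roughly the boundary dimension plus one).

Two numerical safeguards keep the log-log regression honest on finite
rasters: only complete boxes are tiled, box sizes are capped at 45 % of the
short image side (larger boxes quantise the count so coarsely that they
bias the slope), and every count is rescaled by (image area)/(tiled area)
so that truncated tilings are extrapolated to the full frame.  With this
convention a constant image yields exactly D = 2.

Grids are repositioned ``n_grids`` times (default 12): the reference grid
at offset (0, 0) plus seeded pseudo-random offsets within ``[0, eps_min)``
in each axis.  The 23 monofractal summary features aggregate the per-grid
regressions; SD-type features measure dispersion across grids while
SE-type features are the slope standard error of the grid-averaged
regression.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .imgio import GreyImage

__all__ = [
    "GridScan",
    "FractalFeatureSet",
    "FRACTAL_FEATURE_NAMES",
    "MAX_BOX_FRACTION",
    "default_box_sizes",
    "usable_box_sizes",
    "scan_grid",
    "fractal_features",
]

log = logging.getLogger(__name__)

#: Largest box edge used in a scan, as a fraction of the short image side.
MAX_BOX_FRACTION = 0.45


def default_box_sizes(lo: int = 5, hi: int = 575, step: int = 3) -> np.ndarray:
    """The default linear box-size series 5, 8, ..., 575 (191 sizes)."""
    return np.arange(lo, hi + 1, step)


def usable_box_sizes(img_shape: tuple[int, int], box_sizes: np.ndarray) -> np.ndarray:
    """Subset of ``box_sizes`` applicable to an image, largest sizes dropped."""
    cap = int(MAX_BOX_FRACTION * min(img_shape))
    sizes = np.asarray(box_sizes)
    usable = sizes[sizes <= cap]
    if usable.size < sizes.size:
        log.debug(
            "dropping %d box sizes above %d px for image of shape %s",
            sizes.size - usable.size, cap, img_shape,
        )
    return usable


def _ols_loglog(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit returning (slope, intercept, r2, slope standard error)."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / sxx) if n > 2 else float("nan")
    return slope, float(intercept), float(min(max(r2, 0.0), 1.0)), float(se)


@dataclasses.dataclass
class GridScan:
    """Box-count scan of one grid position.

    ``counts`` are edge-corrected box counts N(eps); ``mass_mean`` and
    ``mass_sd`` summarise per-box inverted-intensity masses; ``d`` is the
    slope of log N vs log(1/eps) with intercept ``y_int``, fit quality
    ``r2`` and slope standard error ``slope_se``.
    """

    grid_offset: tuple[int, int]
    box_sizes: np.ndarray
    counts: np.ndarray
    mass_mean: np.ndarray
    mass_sd: np.ndarray
    lacunarity: np.ndarray
    d: float
    y_int: float
    r2: float
    slope_se: float


def scan_grid(
    img: GreyImage,
    offset: tuple[int, int] = (0, 0),
    box_sizes: np.ndarray | None = None,
    counting: str = "differential",
) -> GridScan:
    """Scan one grid position over all usable box sizes.

    ``counting`` selects differential (greyscale) or binary box counting;
    see the module docstring.
    """
    if counting not in ("differential", "binary"):
        raise ValueError(f"unknown counting mode {counting!r}")
    px = img.pixels
    H, W = px.shape
    dx, dy = int(offset[0]), int(offset[1])
    sizes = usable_box_sizes((H, W), default_box_sizes() if box_sizes is None else box_sizes)
    if sizes.size == 0:
        raise ValueError(f"image of shape {(H, W)} is smaller than the smallest box size")
    if sizes.size < 3:
        raise ValueError("fewer than 3 usable box sizes; regression is underdetermined")

    G, M = 256.0, float(min(H, W))
    area = float(W * H)
    counts = np.empty(sizes.size)
    mass_mean = np.empty(sizes.size)
    mass_sd = np.empty(sizes.size)
    inv = (255.0 - px).astype(np.float64)
    for k, e in enumerate(sizes):
        e = int(e)
        nby, nbx = (H - dy) // e, (W - dx) // e
        if nby < 1 or nbx < 1:
            counts[k] = np.nan
            mass_mean[k] = mass_sd[k] = np.nan
            continue
        boxes = px[dy : dy + nby * e, dx : dx + nbx * e].reshape(nby, e, nbx, e)
        mn = boxes.min(axis=(1, 3))
        if counting == "differential":
            mx = boxes.max(axis=(1, 3))
            h = e * G / M
            nb = np.floor(mx / h) - np.floor(mn / h) + 1.0
            n = float(nb.sum())
        else:
            n = float((mn < 255).sum())
        counts[k] = n * area / (nbx * nby * e * e)
        m = inv[dy : dy + nby * e, dx : dx + nbx * e].reshape(nby, e, nbx, e).sum(axis=(1, 3))
        mass_mean[k] = m.mean()
        mass_sd[k] = m.std()

    with np.errstate(divide="ignore", invalid="ignore"):
        lac = np.where(mass_mean > 0, (mass_sd / np.where(mass_mean > 0, mass_mean, 1.0)) ** 2, 0.0)

    pos = np.isfinite(counts) & (counts > 0)
    if pos.sum() < 3:
        d = y_int = r2 = se = float("nan")
    else:
        d, y_int, r2, se = _ols_loglog(np.log(1.0 / sizes[pos]), np.log(counts[pos]))
    return GridScan((dx, dy), sizes, counts, mass_mean, mass_sd, lac, d, y_int, r2, se)


#: Canonical order of the 23 monofractal features.
FRACTAL_FEATURE_NAMES = (
    "d_b", "sd_d_b", "d_b_min", "d_b_max", "d_b_best_r2", "se_d_b", "yint_d_b",
    "d_m", "sd_d_m", "d_m_min", "d_m_max", "d_m_best_r2", "se_d_m", "yint_d_m",
    "d_x_best_r2", "se_d_x", "yint_d_x",
    "lam", "lam_prime", "lam_min", "lam_max", "cv_lam_g", "cv_lam_prime_g",
)


@dataclasses.dataclass(frozen=True)
class FractalFeatureSet:
    """The 23 monofractal features (box dimension, mass dimension, optimal
    cover and lacunarity families)."""

    d_b: float
    sd_d_b: float
    d_b_min: float
    d_b_max: float
    d_b_best_r2: float
    se_d_b: float
    yint_d_b: float
    d_m: float
    sd_d_m: float
    d_m_min: float
    d_m_max: float
    d_m_best_r2: float
    se_d_m: float
    yint_d_m: float
    d_x_best_r2: float
    se_d_x: float
    yint_d_x: float
    lam: float
    lam_prime: float
    lam_min: float
    lam_max: float
    cv_lam_g: float
    cv_lam_prime_g: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FRACTAL_FEATURE_NAMES}


def _mass_fit(scan: GridScan) -> tuple[float, float, float, float]:
    """Mass-dimension regression log mu(eps) vs log eps for one grid."""
    pos = np.isfinite(scan.mass_mean) & (scan.mass_mean > 0)
    if pos.sum() < 3:
        return (float("nan"),) * 4
    return _ols_loglog(np.log(scan.box_sizes[pos].astype(float)), np.log(scan.mass_mean[pos]))


def _cv(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    m = values.mean()
    if m == 0:
        return 0.0
    return float(values.std(ddof=1) / m) if values.size > 1 else 0.0


def fractal_features(
    img: GreyImage,
    n_grids: int = 12,
    box_sizes: np.ndarray | None = None,
    seed: int = 0,
    counting: str = "differential",
) -> FractalFeatureSet:
    """The 23 monofractal features aggregated over ``n_grids`` grid positions."""
    sizes = usable_box_sizes(
        img.pixels.shape, default_box_sizes() if box_sizes is None else box_sizes
    )
    if sizes.size < 3:
        raise ValueError("fewer than 3 usable box sizes; regression is underdetermined")
    rng = np.random.default_rng(seed)
    eps_min = int(sizes.min())
    offsets = [(0, 0)] + [
        (int(rng.integers(0, eps_min)), int(rng.integers(0, eps_min))) for _ in range(n_grids - 1)
    ]
    scans = [scan_grid(img, off, sizes, counting) for off in offsets]

    # --- box dimension family -------------------------------------------------
    d = np.array([s.d for s in scans])
    r2 = np.array([s.r2 for s in scans])
    ok = np.isfinite(d)
    if ok.any():
        d_b = float(d[ok].mean())
        sd_d_b = float(d[ok].std(ddof=1)) if ok.sum() > 1 else 0.0
        d_b_min, d_b_max = float(d[ok].min()), float(d[ok].max())
        d_b_best = float(d[ok][np.nanargmax(r2[ok])])
    else:
        d_b = sd_d_b = d_b_min = d_b_max = d_b_best = float("nan")
    # grid-averaged count regression (mean log N per box size)
    logN = np.full((len(scans), sizes.size), np.nan)
    for g, s in enumerate(scans):
        pos = np.isfinite(s.counts) & (s.counts > 0)
        logN[g, pos] = np.log(s.counts[pos])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_logN = np.nanmean(logN, axis=0)
    pos = np.isfinite(mean_logN)
    if pos.sum() >= 3:
        _, yint_d_b, _, se_d_b = _ols_loglog(np.log(1.0 / sizes[pos]), mean_logN[pos])
    else:
        yint_d_b = se_d_b = float("nan")

    # --- mass dimension family ------------------------------------------------
    mfits = [_mass_fit(s) for s in scans]
    dm = np.array([f[0] for f in mfits])
    mr2 = np.array([f[2] for f in mfits])
    ok = np.isfinite(dm)
    if ok.any():
        d_m = float(dm[ok].mean())
        sd_d_m = float(dm[ok].std(ddof=1)) if ok.sum() > 1 else 0.0
        d_m_min, d_m_max = float(dm[ok].min()), float(dm[ok].max())
        d_m_best = float(dm[ok][np.nanargmax(mr2[ok])])
    else:
        d_m = sd_d_m = d_m_min = d_m_max = d_m_best = float("nan")
    logmu = np.full((len(scans), sizes.size), np.nan)
    for g, s in enumerate(scans):
        pos = np.isfinite(s.mass_mean) & (s.mass_mean > 0)
        logmu[g, pos] = np.log(s.mass_mean[pos])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_logmu = np.nanmean(logmu, axis=0)
    pos = np.isfinite(mean_logmu)
    if pos.sum() >= 3:
        _, yint_d_m, _, se_d_m = _ols_loglog(np.log(sizes[pos].astype(float)), mean_logmu[pos])
    else:
        yint_d_m = se_d_m = float("nan")

    # --- optimal cover (minimum count across grids) -----------------------------
    allN = np.full((len(scans), sizes.size), np.nan)
    for g, s in enumerate(scans):
        allN[g] = s.counts
    minN = np.nanmin(allN, axis=0)
    pos = np.isfinite(minN) & (minN > 0)
    if pos.sum() >= 3:
        d_x, yint_d_x, _, se_d_x = _ols_loglog(np.log(1.0 / sizes[pos]), np.log(minN[pos]))
    else:
        d_x = yint_d_x = se_d_x = float("nan")

    # --- lacunarity family ------------------------------------------------------
    lam_g = np.array([float(np.nanmean(s.lacunarity)) for s in scans])
    lam = lam_g[0]
    all_lam = np.concatenate([s.lacunarity[np.isfinite(s.lacunarity)] for s in scans])
    lam_prime = float(all_lam.mean()) if all_lam.size else float("nan")
    lam_min, lam_max = float(np.nanmin(lam_g)), float(np.nanmax(lam_g))
    cv_lam_g = _cv(lam_g)
    cv_lam_prime_g = _cv(all_lam)

    return FractalFeatureSet(
        d_b=d_b, sd_d_b=sd_d_b, d_b_min=d_b_min, d_b_max=d_b_max,
        d_b_best_r2=d_b_best, se_d_b=se_d_b, yint_d_b=yint_d_b,
        d_m=d_m, sd_d_m=sd_d_m, d_m_min=d_m_min, d_m_max=d_m_max,
        d_m_best_r2=d_m_best, se_d_m=se_d_m, yint_d_m=yint_d_m,
        d_x_best_r2=d_x, se_d_x=se_d_x, yint_d_x=yint_d_x,
        lam=float(lam), lam_prime=lam_prime, lam_min=lam_min, lam_max=lam_max,
        cv_lam_g=cv_lam_g, cv_lam_prime_g=cv_lam_prime_g,
    )
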