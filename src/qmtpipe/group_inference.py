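"""Group-level statistics for the two-session crossover imaging study.

Implements the full inferential chain used on the parameter maps: masked
Gaussian smoothing, voxel-wise paired t maps, cluster extraction at a
cluster-forming threshold, Monte Carlo cluster-extent correction (smoothed
unit-noise simulation of the maximum cluster size under the null), ROI
small-volume family-wise error by sign-flip permutation of the paired
differences, ROI-mean extraction, OLS regression of behavioral change on
ROI change, the 2x2 within-subject interaction F test, and the grand-mean
scaling / exclusive masking contrast logic used for uptake-like maps.

Cluster-forming direction defaults to one-sided (condition A > condition B);
connectivity defaults to 26-neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "StatMap",
    "ClusterResult",
    "MonteCarloExtentResult",
    "smooth_volume",
    "paired_t_map",
    "extract_clusters",
    "monte_carlo_cluster_threshold",
    "roi_fwe_smallvolume",
    "roi_mean_change",
    "regress_change_on_covariate",
    "repeated_measures_interaction",
    "grand_mean_scale",
    "exclusive_mask",
    "paired_cluster_analysis",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StatMap:
    """Voxel-wise t statistics with validity mask (df = n_pairs - 1)."""

    t: np.ndarray
    df: int
    n_pairs: int
    mask: np.ndarray  # True where the statistic is defined


@dataclass
class ClusterResult:
    """One suprathreshold cluster."""

    label: int
    extent: int
    peak_t: float
    peak_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    corrected_p: float | None = None


@dataclass
class MonteCarloExtentResult:
    """Null distribution of the maximum cluster extent and its quantile."""

    k_star: int
    max_extents: np.ndarray
    p_voxel: float
    alpha: float
    fwhm_mm: float
    voxel_mm: float

    def corrected_p(self, extent: int) -> float:
        """P(max null extent >= extent), with the +1 permutation convention."""
        n = self.max_extents.size
        return float((1 + np.sum(self.max_extents >= extent)) / (1 + n))


def smooth_volume(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_mm: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Separable Gaussian smoothing with optional mask renormalization.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis in mm; ``fwhm = 0`` is the
    identity.  When a mask is given, values outside it are excluded and the
    kernel renormalized over in-mask voxels (a constant in-mask map stays
    constant); out-of-mask voxels are NaN in the output.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    if mask is None:
        return ndimage.gaussian_filter(volume, sigma)
    mask = np.asarray(mask, dtype=bool)
    filled = np.where(mask, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.full(volume.shape, np.nan)
    good = mask & (den > 1e-12)
    out[good] = num[good] / den[good]
    return out


def paired_t_map(
    maps_a: np.ndarray, maps_b: np.ndarray, mask: np.ndarray
) -> StatMap:
    """Voxel-wise paired t statistic of condition A minus condition B.

    ``maps_a``/``maps_b`` are (n_subjects, nx, ny, nz) with matching subject
    order.  Voxels with zero difference variance are flagged invalid rather
    than returning infinities.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("condition map stacks must have identical shapes")
    n = maps_a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subject pairs")
    mask = np.asarray(mask, dtype=bool)
    d = maps_a - maps_b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    finite = np.all(np.isfinite(d), axis=0)
    # identically zero differences are a well-defined t = 0; a constant
    # nonzero difference has no finite t and is flagged invalid
    zero_d = (sd == 0) & (mean == 0)
    valid = mask & finite & ((sd > 0) | zero_d)
    t = np.where(valid, np.where(zero_d, 0.0, t), np.nan)
    return StatMap(t=t, df=n - 1, n_pairs=n, mask=valid)


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    stat: StatMap,
    p_voxel: float,
    connectivity: int = 26,
    voxel_mm: float = 1.0,
    direction: str = "greater",
) -> list[ClusterResult]:
    """Suprathreshold clusters of a t map at a cluster-forming threshold.

    ``direction="greater"`` thresholds t at the upper one-sided t quantile
    for the map's df; ``"two-sided"`` thresholds |t| at the p/2 quantile.
    Clusters are returned sorted by extent, descending.
    """
    if not (0.0 < p_voxel < 1.0):
        raise ValueError("p_voxel must be in (0, 1)")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if direction == "greater":
        t_crit = stats.t.isf(p_voxel, stat.df)
        supra = stat.mask & (stat.t > t_crit)
        peak_stat = stat.t
    elif direction == "two-sided":
        t_crit = stats.t.isf(p_voxel / 2.0, stat.df)
        supra = stat.mask & (np.abs(stat.t) > t_crit)
        peak_stat = np.abs(stat.t)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    labels, n_labels = ndimage.label(supra, _CONNECTIVITY_STRUCTS[connectivity])
    clusters = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        vals = peak_stat[tuple(idx.T)]
        peak = idx[np.argmax(vals)]
        clusters.append(
            ClusterResult(
                label=lab,
                extent=len(idx),
                peak_t=float(stat.t[tuple(peak)]),
                peak_index=tuple(int(x) for x in peak),
                peak_mm=tuple(float(x) * voxel_mm for x in peak),
            )
        )
    clusters.sort(key=lambda c: c.extent, reverse=True)
    return clusters


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_mm: float,
    p_voxel: float = 0.001,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    connectivity: int = 26,
    df: int | None = None,
) -> MonteCarloExtentResult:
    """Monte Carlo estimate of the critical cluster extent under the null.

    Each iteration fills the mask with unit Gaussian noise, smooths it at
    the analysis FWHM, re-standardizes within the mask (so the voxel-wise
    threshold maps to an exact z quantile), thresholds one-sided at
    ``p_voxel`` and records the maximum cluster extent.  ``k_star`` is the
    smallest extent whose null exceedance probability is below ``alpha``:
    clusters at least that large have family-wise corrected p < alpha.

    With ``df`` set, each iteration instead simulates ``df + 1`` smoothed
    noise fields and thresholds their one-sample t map at the t quantile —
    a null matched to a paired-t pipeline with that df (a smoothed z field
    slightly overestimates t-field cluster extents, making the z-based
    threshold conservative).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    crit = stats.norm.isf(p_voxel) if df is None else stats.t.isf(p_voxel, df)
    max_extents = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        if df is None:
            noise = rng.standard_normal(mask.shape)
            sm = smooth_volume(noise, fwhm_mm, voxel_mm, mask=mask)
            vals = sm[mask]
            field = np.zeros(mask.shape)
            field[mask] = (vals - vals.mean()) / vals.std()
        else:
            fields = np.stack(
                [
                    smooth_volume(rng.standard_normal(mask.shape), fwhm_mm,
                                  voxel_mm, mask=mask)
                    for _ in range(df + 1)
                ]
            )
            mean = fields.mean(axis=0)
            sd = fields.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                field = np.where(mask & (sd > 0),
                                 mean / (sd / np.sqrt(df + 1)), 0.0)
        supra = mask & (field > crit)
        if supra.any():
            labels, n_labels = ndimage.label(supra, struct)
            max_extents[it] = np.bincount(labels.ravel())[1:].max()
    k_star = int(np.ceil(np.quantile(max_extents, 1.0 - alpha))) or 1
    # the smallest extent whose exceedance probability is below alpha
    while np.mean(max_extents >= k_star) >= alpha:
        k_star += 1
    return MonteCarloExtentResult(
        k_star=k_star, max_extents=max_extents, p_voxel=p_voxel,
        alpha=alpha, fwhm_mm=fwhm_mm, voxel_mm=voxel_mm,
    )


def roi_fwe_smallvolume(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    roi_mask: np.ndarray,
    n_perm: int = 2048,
    seed: int = 0,
):
    """Voxel-level FWE within an ROI by sign-flip permutation.

    Under the null the subject difference maps are sign-symmetric; the null
    distribution of the ROI maximum |t| is built by flipping the sign of
    each subject's difference map (full enumeration when 2^n <= n_perm,
    random flips otherwise).  Returns (peak_index, peak_t, corrected_p).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("ROI mask is empty")
    d = (np.asarray(maps_a, dtype=float) - np.asarray(maps_b, dtype=float))[
        :, roi_mask
    ]
    n = d.shape[0]
    if n < 5:
        raise ValueError("need at least 5 pairs for meaningful permutation")

    def max_abs_t(signs):
        ds = d * signs[:, None]
        mean = ds.mean(axis=0)
        sd = ds.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t[~np.isfinite(t)] = 0.0
        return t

    t_obs = max_abs_t(np.ones(n))
    obs = float(np.max(np.abs(t_obs)))
    peak_flat = int(np.argmax(np.abs(t_obs)))
    peak_index = tuple(int(x) for x in np.argwhere(roi_mask)[peak_flat])

    if 2**n <= n_perm:
        signs_iter = (
            np.array([1 if (m >> b) & 1 == 0 else -1 for b in range(n)])
            for m in range(2**n)
        )
        null = np.array([np.max(np.abs(max_abs_t(s))) for s in signs_iter])
        corrected_p = float(np.mean(null >= obs - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            s = rng.choice([-1.0, 1.0], size=n)
            if np.max(np.abs(max_abs_t(s))) >= obs - 1e-12:
                count += 1
        corrected_p = (1 + count) / (1 + n_perm)
    return peak_index, float(t_obs[peak_flat]), corrected_p


def roi_mean_change(diff_maps: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Per-subject unweighted mean of a difference map over ROI voxels."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("ROI mask is empty")
    diff_maps = np.asarray(diff_maps, dtype=float)
    if diff_maps.shape[1:] != roi_mask.shape:
        raise ValueError("difference maps and ROI grids do not match")
    return diff_maps[:, roi_mask].mean(axis=1)


def regress_change_on_covariate(delta_roi, delta_covariate):
    """OLS of behavioral change on ROI change: (slope, intercept, r2, p).

    Two-sided p from the t distribution with n - 2 df.
    """
    x = np.asarray(delta_roi, dtype=float)
    y = np.asarray(delta_covariate, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def repeated_measures_interaction(table, outcome: str):
    """2x2 within-subject treatment-by-time interaction F test.

    For a complete condition (vaccine/placebo) x timepoint (baseline/4h)
    design, the interaction reduces to a one-sample t test of the
    per-subject difference of differences: F = t^2 with df (1, n - 1).
    Returns (F, df1, df2, p).
    """
    piv = table.pivot_table(
        index="subject", columns=["condition", "timepoint"], values=outcome
    )
    needed = [
        ("vaccine", "baseline"), ("vaccine", "4h"),
        ("placebo", "baseline"), ("placebo", "4h"),
    ]
    if any(c not in piv.columns for c in needed) or piv[needed].isna().any().any():
        raise ValueError("incomplete 2x2 design: every subject needs all four cells")
    dod = (
        (piv[("vaccine", "4h")] - piv[("vaccine", "baseline")])
        - (piv[("placebo", "4h")] - piv[("placebo", "baseline")])
    ).to_numpy()
    n = dod.size
    sd = dod.std(ddof=1)
    if sd == 0:
        return 0.0, 1, n - 1, 1.0
    t = dod.mean() / (sd / np.sqrt(n))
    F = t**2
    p = float(stats.f.sf(F, 1, n - 1))
    return float(F), 1, n - 1, p


def grand_mean_scale(volume: np.ndarray, mask: np.ndarray, target: float = 50.0):
    """Scale a volume so its within-mask mean equals ``target`` exactly."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    mean = volume[mask].mean()
    if mean == 0 or not np.isfinite(mean):
        raise ValueError("within-mask mean is zero or undefined")
    return volume * (target / mean)


def exclusive_mask(stat: StatMap, control_stat: StatMap, p_mask: float = 0.005):
    """Remove voxels where the control contrast itself is suprathreshold.

    Voxels where the control t map exceeds its one-sided ``p_mask``
    threshold are invalidated in ``stat``; all others pass through
    unchanged.  This accounts for nonspecific (e.g. time-of-day) effects.
    """
    if stat.t.shape != control_stat.t.shape:
        raise ValueError("stat and control grids do not match")
    t_crit = stats.t.isf(p_mask, control_stat.df)
    excl = control_stat.mask & (control_stat.t > t_crit)
    new_mask = stat.mask & ~excl
    if not new_mask.any():
        logger.warning("exclusive mask removed every voxel")
    return StatMap(
        t=np.where(new_mask, stat.t, np.nan),
        df=stat.df, n_pairs=stat.n_pairs, mask=new_mask,
    )


def paired_cluster_analysis(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_mm: float,
    mc: MonteCarloExtentResult,
    p_voxel: float = 0.001,
    connectivity: int = 26,
    direction: str = "greater",
):
    """Smoothing + paired t + cluster extraction + extent correction.

    Smooths each subject's per-condition map at ``fwhm_mm`` within the
    analysis mask, computes the paired t map (A minus B), extracts clusters
    at ``p_voxel`` and attaches Monte Carlo corrected p values; clusters
    with extent >= ``mc.k_star`` survive at the corrected alpha.
    Returns (StatMap, [ClusterResult], [surviving ClusterResult]).
    """
    sm_a = np.stack([smooth_volume(m, fwhm_mm, voxel_mm, mask) for m in maps_a])
    sm_b = np.stack([smooth_volume(m, fwhm_mm, voxel_mm, mask) for m in maps_b])
    stat = paired_t_map(sm_a, sm_b, mask)
    clusters = extract_clusters(
        stat, p_voxel, connectivity=connectivity, voxel_mm=voxel_mm,
        direction=direction,
    )
    for c in clusters:
        c.corrected_p = mc.corrected_p(c.extent)
    surviving = [c for c in clusters if c.extent >= mc.k_star]
    return stat, clusters, surviving
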