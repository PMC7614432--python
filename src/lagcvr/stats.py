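"""Statistical surface of the lag/CVR analysis.

Subject-level voxelwise Spearman correlation between lag and CVR per ROI,
group inference by Wilcoxon signed-rank against zero (Bonferroni-corrected
across the six ROIs), spatial Pearson correlation of lag maps across
conditions, longitudinal paired one-tailed t-tests on hemisphere mean lag,
and a voxelwise two-factor (group x timepoint) OLS ANOVA with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from lagcvr.cvrmap import CvrMap
from lagcvr.lagmap import LagMap

__all__ = [
    "RoiCorrelation",
    "GroupAnovaResult",
    "roi_spearman",
    "bonferroni_alpha",
    "group_wilcoxon_vs_zero",
    "spatial_pearson",
    "paired_onetailed_ttest",
    "voxelwise_group_anova",
    "fdr_bh",
]


@dataclass
class RoiCorrelation:
    """Subject-level lag-CVR Spearman correlation within one ROI."""

    r: float
    n_voxels: int

    @property
    def ok(self) -> bool:
        return bool(np.isfinite(self.r))


def roi_spearman(
    lag: LagMap, cvr: CvrMap, roi: np.ndarray, min_voxels: int = 10
) -> RoiCorrelation:
    """Voxelwise Spearman rank correlation between lag and CVR over the
    jointly valid voxels of an ROI (average-rank tie handling).

    ROIs with fewer than ``min_voxels`` jointly valid voxels, or with
    degenerate (all-tied) values, are flagged with NaN and excluded from
    the group test.
    """
    roi = np.asarray(roi, dtype=bool)
    sel = roi & lag.valid & cvr.valid
    n = int(sel.sum())
    if n < min_voxels:
        return RoiCorrelation(float("nan"), n)
    x = lag.lag_s[sel]
    y = cvr.cvr[sel]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RoiCorrelation(float("nan"), n)
    r = sps.spearmanr(x, y).statistic
    return RoiCorrelation(float(r), n)


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test alpha under Bonferroni correction (e.g. 0.05 / 6 = 0.0083
    for the six tissue-compartment tests)."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return family_alpha / n_tests


def group_wilcoxon_vs_zero(
    values: np.ndarray, alpha: float
) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank test of median zero over per-subject
    correlation values.

    Zeros are dropped (standard convention); the exact null distribution is
    used for n <= 25 (when no ties in the absolute values prevent it) and
    the continuity-corrected normal approximation above. All-zero input
    yields p = 1 by convention. Significance is strict: ``p < alpha``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    nonzero = values[values != 0]
    if nonzero.size == 0:
        return 1.0, False
    if nonzero.size < 6:
        raise ValueError("Wilcoxon group test needs at least 6 non-zero values")
    n = nonzero.size
    ties = np.unique(np.abs(nonzero)).size < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(
            nonzero, alternative="two-sided", method=method, correction=True
        )
    p = float(res.pvalue)
    return p, bool(p < alpha)


def spatial_pearson(
    map_a: LagMap, map_b: LagMap, mask: np.ndarray, min_voxels: int = 10
) -> float:
    """Spatial Pearson correlation of two lag maps over jointly valid
    masked voxels (e.g. resting-state vs breath-hold consistency).
    Degenerate variance yields NaN."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & map_a.valid & map_b.valid
    if int(sel.sum()) < min_voxels:
        raise ValueError(
            f"need at least {min_voxels} jointly valid voxels in the mask"
        )
    a = map_a.lag_s[sel]
    b = map_b.lag_s[sel]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(sps.pearsonr(a, b).statistic)


def paired_onetailed_ttest(
    v1: np.ndarray, v2: np.ndarray, direction: str = "less"
) -> float:
    """One-tailed paired t-test p-value for a change from visit 1 to
    visit 2.

    ``direction='less'`` tests the alternative that v2 < v1 (e.g. lag
    reduction over time); ``'greater'`` the opposite. No change (t = 0)
    gives p = 0.5; a constant non-zero difference is the infinite-t limit
    and gives p = 0 (shift in the tested direction) or 1 (opposite).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.size < 3:
        raise ValueError("paired test needs matched samples with n >= 3")
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    diff = v2 - v1
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.5
        matches = (diff[0] < 0) == (direction == "less")
        return 0.0 if matches else 1.0
    res = sps.ttest_rel(v2, v1, alternative=direction)
    return float(res.pvalue)


@dataclass
class GroupAnovaResult:
    """Voxelwise two-factor OLS ANOVA maps with FDR-controlled
    significance.

    Per term (group, timepoint, interaction): F map, p map, the BH
    rejection mask at level ``q``, and the adaptive p threshold (largest
    rejected p; NaN if nothing was rejected). ``analysis_mask`` marks the
    voxels that entered the model.
    """

    f_group: np.ndarray
    p_group: np.ndarray
    f_timepoint: np.ndarray
    p_timepoint: np.ndarray
    f_interaction: np.ndarray
    p_interaction: np.ndarray
    analysis_mask: np.ndarray
    q: float
    sig_group: np.ndarray
    sig_timepoint: np.ndarray
    sig_interaction: np.ndarray
    threshold_group: float
    threshold_timepoint: float
    threshold_interaction: float


def _as_lag_arrays(maps) -> tuple[np.ndarray, np.ndarray]:
    values, valids = [], []
    for m in maps:
        if isinstance(m, LagMap):
            values.append(m.lag_s)
            valids.append(m.valid)
        else:
            arr = np.asarray(m, dtype=float)
            values.append(arr)
            valids.append(np.isfinite(arr))
    return np.stack(values), np.stack(valids)


def _effect_code(labels) -> np.ndarray:
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError("each factor must have exactly two levels")
    return np.where(np.asarray(labels) == levels[0], -1.0, 1.0)


def voxelwise_group_anova(
    maps,
    group,
    timepoint,
    q: float = 0.1,
    min_valid_fraction: float = 0.8,
) -> GroupAnovaResult:
    """Voxelwise two-factor (group x timepoint) ANOVA on lag maps by OLS
    with effect coding, F-tests per term, and BH-FDR control at ``q``.

    The analysis mask keeps voxels valid in at least ``min_valid_fraction``
    of subjects; within it, each voxel is fitted on the subjects valid
    there (voxels whose reduced subject set makes the design rank-deficient
    are dropped). Requires at least two subjects per design cell.
    """
    Y, V = _as_lag_arrays(maps)
    n_subj = Y.shape[0]
    g = _effect_code(group)
    t = _effect_code(timepoint)
    if len(g) != n_subj or len(t) != n_subj:
        raise ValueError("labels must match the number of subjects")
    for gi in (-1.0, 1.0):
        for ti in (-1.0, 1.0):
            if np.sum((g == gi) & (t == ti)) < 2:
                raise ValueError("need at least 2 subjects per design cell")
    X_full = np.column_stack([np.ones(n_subj), g, t, g * t])

    analysis_mask = V.mean(axis=0) >= min_valid_fraction
    vox_idx = np.nonzero(analysis_mask.reshape(-1))[0]
    Yf = Y.reshape(n_subj, -1)[:, vox_idx]
    Vf = V.reshape(n_subj, -1)[:, vox_idx]
    n_vox = vox_idx.size

    F = np.full((3, n_vox), np.nan)
    P = np.full((3, n_vox), np.nan)
    dropped = np.zeros(n_vox, dtype=bool)

    patterns = {}
    for j in range(n_vox):
        patterns.setdefault(Vf[:, j].tobytes(), []).append(j)

    for key, cols in patterns.items():
        inc = np.frombuffer(key, dtype=bool)
        X = X_full[inc]
        n = int(inc.sum())
        if n <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
            dropped[cols] = True
            continue
        Yp = Yf[np.ix_(inc, cols)]
        beta, *_ = np.linalg.lstsq(X, Yp, rcond=None)
        rss_full = np.sum((Yp - X @ beta) ** 2, axis=0)
        df_den = n - X.shape[1]
        for term, col_drop in enumerate((1, 2, 3)):
            Xr = np.delete(X, col_drop, axis=1)
            br, *_ = np.linalg.lstsq(Xr, Yp, rcond=None)
            rss_red = np.sum((Yp - Xr @ br) ** 2, axis=0)
            num = np.maximum(rss_red - rss_full, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = num / (rss_full / df_den)
            # a perfect fit (identical data within cells) has no evidence of
            # an effect: F -> 0, p -> 1 rather than 0/0
            f = np.where(rss_full == 0, np.where(num == 0, 0.0, np.inf), f)
            F[term, cols] = f
            P[term, cols] = sps.f.sf(f, 1, df_den)

    analysis_flat = analysis_mask.reshape(-1).copy()
    analysis_flat[vox_idx[dropped]] = False

    shape = Y.shape[1:]

    def volume(flat_vals: np.ndarray) -> np.ndarray:
        out = np.full(np.prod(shape, dtype=int), np.nan)
        out[vox_idx] = flat_vals
        out[~analysis_flat] = np.nan
        return out.reshape(shape)

    def significance(p_flat: np.ndarray) -> tuple[np.ndarray, float]:
        p_map = volume(p_flat)
        rej = fdr_bh(p_map, q)
        p_rej = p_map[rej]
        thr = float(p_rej.max()) if p_rej.size else float("nan")
        return rej, thr

    sig_g, thr_g = significance(P[0])
    sig_t, thr_t = significance(P[1])
    sig_i, thr_i = significance(P[2])
    return GroupAnovaResult(
        f_group=volume(F[0]),
        p_group=volume(P[0]),
        f_timepoint=volume(F[1]),
        p_timepoint=volume(P[1]),
        f_interaction=volume(F[2]),
        p_interaction=volume(P[2]),
        analysis_mask=analysis_flat.reshape(shape),
        q=q,
        sig_group=sig_g,
        sig_timepoint=sig_t,
        sig_interaction=sig_i,
        threshold_group=thr_g,
        threshold_timepoint=thr_t,
        threshold_interaction=thr_i,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    NaN entries are never rejected; the step-up rule is applied to the
    finite p-values only. Returns a boolean array of the input shape.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if not finite.any():
        return out
    pv = p[finite]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    out[finite] = reject
    return out
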