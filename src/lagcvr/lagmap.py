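"""Voxelwise haemodynamic lag mapping.

Each voxel's timecourse is compared with a grey-matter reference signal at
integer-TR shifts spanning +/-4 TR (+/-8 s at TR = 2 s, nine shift
positions). The correlation peak over the shift grid is refined by fitting
a parabola through the maximum and its two neighbours; the vertex abscissa
is the voxel's haemodynamic lag in seconds. Positive lag means the voxel
trails the reference (delayed haemodynamics), negative means it leads.
Voxels whose best correlation with the reference stays below 0.1 are
excluded as unmappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from lagcvr.preprocess import BoldSeries

__all__ = [
    "Correlogram",
    "LagMap",
    "PeakFit",
    "reference_timeseries",
    "cross_correlogram",
    "parabolic_peak",
    "compute_lag_map",
    "hemisphere_mean_lag",
]

MIN_SHIFT_PAIRS = 10


@dataclass
class Correlogram:
    """Correlation of one voxel with the reference over the shift grid.

    ``shifts_s`` is symmetric about zero with constant step TR; ``r`` is the
    Pearson correlation per shift (NaN where the valid-frame overlap was
    insufficient); ``n_pairs`` counts the overlapping valid frame pairs.
    """

    shifts_s: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.shifts_s = np.asarray(self.shifts_s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)

    @property
    def step_s(self) -> float:
        return float(self.shifts_s[1] - self.shifts_s[0])


@dataclass
class LagMap:
    """Voxelwise haemodynamic lag/lead in seconds.

    ``lag_s`` is NaN at invalid voxels; ``peak_r`` is the correlation at the
    fitted peak; ``at_boundary`` marks voxels whose correlation maximum sat
    at the edge of the shift grid (lag clamped, not extrapolated);
    ``degenerate`` marks flat correlogram triples.
    """

    lag_s: np.ndarray
    peak_r: np.ndarray
    valid: np.ndarray
    at_boundary: np.ndarray
    degenerate: np.ndarray
    reference_id: str = "gm"


class PeakFit(NamedTuple):
    lag_s: float
    peak_r: float
    at_boundary: bool
    degenerate: bool


def reference_timeseries(
    bold: BoldSeries,
    gm_mask: np.ndarray,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Frame-wise mean signal over grey-matter voxels, after excluding a
    mask (typically the lesion). Values at invalid frames are computed but
    carry no meaning downstream — correlations use valid frames only."""
    gm_mask = np.asarray(gm_mask, dtype=bool)
    effective = gm_mask & bold.brain_mask
    if exclude_mask is not None:
        effective &= ~np.asarray(exclude_mask, dtype=bool)
    if not effective.any():
        raise ValueError("reference mask is empty after exclusion")
    return bold.timeseries(effective).mean(axis=0)


def _shift_correlations(
    X: np.ndarray,
    reference: np.ndarray,
    frame_valid: np.ndarray,
    max_shift_frames: int,
    min_pairs: int = MIN_SHIFT_PAIRS,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each row of ``X`` with the reference shifted
    by k frames, for k in [-K, K].

    Positive k correlates ``X[:, t]`` with ``reference[t - k]`` (the voxel
    trails the reference). Returns ``(r, n_pairs)`` with shapes
    ``(n_vox, 2K+1)`` and ``(2K+1,)``; shifts with fewer than ``min_pairs``
    overlapping valid frames get NaN correlations.
    """
    n_t = X.shape[1]
    K = max_shift_frames
    r = np.full((X.shape[0], 2 * K + 1), np.nan)
    n_pairs = np.zeros(2 * K + 1, dtype=int)
    for col, k in enumerate(range(-K, K + 1)):
        if k >= 0:
            xv = slice(k, n_t)
            rv = slice(0, n_t - k)
        else:
            xv = slice(0, n_t + k)
            rv = slice(-k, n_t)
        pair_ok = frame_valid[xv] & frame_valid[rv]
        n = int(pair_ok.sum())
        n_pairs[col] = n
        if n < min_pairs:
            continue
        x = X[:, xv][:, pair_ok]
        ref = reference[rv][pair_ok]
        xc = x - x.mean(axis=1, keepdims=True)
        rc = ref - ref.mean()
        xnorm = np.linalg.norm(xc, axis=1)
        rnorm = np.linalg.norm(rc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r[:, col] = (xc @ rc) / (xnorm * rnorm)
    return r, n_pairs


def cross_correlogram(
    voxel: np.ndarray,
    reference: np.ndarray,
    frame_valid: np.ndarray,
    tr: float,
    max_shift_frames: int = 4,
    min_pairs: int = MIN_SHIFT_PAIRS,
) -> Correlogram:
    """Discrete cross-correlogram of one voxel against the reference at
    integer-TR shifts in ``[-K, K]`` (default K = 4, i.e. nine positions).

    Shifts with insufficient valid-frame overlap are flagged with NaN, not
    silently computed.
    """
    voxel = np.asarray(voxel, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if voxel.shape != reference.shape:
        raise ValueError("voxel and reference series must have equal length")
    frame_valid = np.asarray(frame_valid, dtype=bool)
    r, n_pairs = _shift_correlations(
        voxel[None, :], reference, frame_valid, max_shift_frames, min_pairs
    )
    shifts = np.arange(-max_shift_frames, max_shift_frames + 1) * tr
    return Correlogram(shifts_s=shifts, r=r[0], n_pairs=n_pairs)


def parabolic_peak(correlogram: Correlogram) -> PeakFit:
    """Sub-sample peak location by a three-point parabolic fit.

    With argmax index m interior, the unique parabola through
    ``(m-1, m, m+1)`` has its vertex at
    ``offset = 0.5 (r[m-1] - r[m+1]) / (r[m-1] - 2 r[m] + r[m+1])``
    grid steps from m; the lag is ``(shift_m + offset * step)`` seconds and
    the peak correlation is the vertex ordinate. A maximum at the grid
    boundary is clamped there (``at_boundary``); a flat triple returns the
    grid maximum with the ``degenerate`` flag instead of dividing by zero.
    A peak correlation of exactly 1 (the voxel is an affine copy of the
    shifted reference) cannot be improved by refinement, so the grid shift
    is returned as-is.
    """
    r = correlogram.r
    if np.any(np.isnan(r)):
        raise ValueError("correlogram is incomplete (NaN correlations)")
    m = int(np.argmax(r))
    if m == 0 or m == r.size - 1:
        return PeakFit(float(correlogram.shifts_s[m]), float(r[m]), True, False)
    if r[m] >= 1.0 - 1e-9:
        return PeakFit(float(correlogram.shifts_s[m]), float(r[m]), False, False)
    denom = r[m - 1] - 2.0 * r[m] + r[m + 1]
    if denom == 0.0 or r[m + 1] == r[m]:
        # zero curvature, or a flat plateau at the maximum (argmax takes the
        # plateau's left edge): no unique vertex
        return PeakFit(float(correlogram.shifts_s[m]), float(r[m]), False, True)
    offset = 0.5 * (r[m - 1] - r[m + 1]) / denom
    lag = correlogram.shifts_s[m] + offset * correlogram.step_s
    peak_r = r[m] - (r[m + 1] - r[m - 1]) ** 2 / (8.0 * denom)
    return PeakFit(float(lag), float(peak_r), False, False)


def compute_lag_map(
    bold: BoldSeries,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
    r_min: float = 0.1,
    max_shift_frames: int = 4,
    min_pairs: int = MIN_SHIFT_PAIRS,
    reference_id: str = "gm",
) -> LagMap:
    """Voxelwise lag map over the brain (or a given) mask.

    Per voxel: cross-correlogram over integer shifts, validity test (the
    maximum integer-shift correlation must reach ``r_min``; voxels below
    are excluded), then parabolic peak refinement. Per-voxel failures
    (insufficient overlap, flat signal) become invalid voxels, never
    aborts.
    """
    if mask is None:
        mask = bold.brain_mask
    mask = np.asarray(mask, dtype=bool) & bold.brain_mask
    X = bold.timeseries(mask)
    R, _ = _shift_correlations(
        X, np.asarray(reference, dtype=float), bold.frame_valid,
        max_shift_frames, min_pairs,
    )
    shifts = np.arange(-max_shift_frames, max_shift_frames + 1) * bold.tr
    step = bold.tr
    n_vox, n_shift = R.shape

    Rsafe = np.where(np.isnan(R), -np.inf, R)
    m = np.argmax(Rsafe, axis=1)
    max_r = Rsafe[np.arange(n_vox), m]
    valid = np.isfinite(max_r) & (max_r >= r_min)

    lag = np.full(n_vox, np.nan)
    peak = np.full(n_vox, np.nan)
    boundary = np.zeros(n_vox, dtype=bool)
    degen = np.zeros(n_vox, dtype=bool)

    edge = (m == 0) | (m == n_shift - 1)
    interior = valid & ~edge
    boundary[valid & edge] = True
    lag[valid & edge] = shifts[m[valid & edge]]
    peak[valid & edge] = max_r[valid & edge]

    if interior.any():
        mi = m[interior]
        rows = np.arange(n_vox)[interior]
        y0 = R[rows, mi - 1]
        y1 = R[rows, mi]
        y2 = R[rows, mi + 1]
        neighbour_bad = np.isnan(y0) | np.isnan(y2)
        denom = y0 - 2.0 * y1 + y2
        exact = y1 >= 1.0 - 1e-9  # perfect correlation: keep the grid shift
        flat = (denom == 0) | (y2 == y1) | neighbour_bad | exact
        with np.errstate(divide="ignore", invalid="ignore"):
            offset = 0.5 * (y0 - y2) / denom
        offset = np.where(flat, 0.0, offset)
        vlag = shifts[mi] + offset * step
        with np.errstate(divide="ignore", invalid="ignore"):
            vpeak = y1 - (y2 - y0) ** 2 / (8.0 * denom)
        vpeak = np.where(flat, y1, vpeak)
        lag[interior] = vlag
        peak[interior] = vpeak
        degen[rows[flat & ~exact]] = True

    def volume(values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(bold.shape, fill)
        out[mask] = values
        return out

    def bool_volume(values: np.ndarray) -> np.ndarray:
        out = np.zeros(bold.shape, dtype=bool)
        out[mask] = values
        return out

    return LagMap(
        lag_s=volume(np.where(valid, lag, np.nan)),
        peak_r=volume(np.where(valid, peak, np.nan)),
        valid=bool_volume(valid),
        at_boundary=bool_volume(boundary),
        degenerate=bool_volume(degen),
        reference_id=reference_id,
    )


def hemisphere_mean_lag(lagmap: LagMap, mask: np.ndarray) -> float:
    """Mean lag over valid voxels within a mask (e.g. the lesioned
    hemisphere's grey matter)."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & lagmap.valid
    if not sel.any():
        raise ValueError("no valid lag voxels inside the mask")
    return float(np.nanmean(lagmap.lag_s[sel]))
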