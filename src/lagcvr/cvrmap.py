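"""Breath-hold cerebrovascular reactivity (CVR) mapping.

CVR is estimated voxelwise as %BOLD signal change per mmHg change in
end-tidal CO2. The chain is: detect expiratory (end-tidal) peaks on the raw
capnograph trace, linearly interpolate them onto a fine 0.1 s grid, convolve
the deviation from the resting baseline with a canonical double-gamma HRF,
then — per voxel — exhaustively shift the resulting regressor between -15 s
and +15 s in 0.1 s steps, keep the delay that maximises the voxel–regressor
correlation, and convert the GLM slope into percent signal change per mmHg
using the fitted intercept as the voxel baseline. Voxels whose best-fit
correlation stays below 0.1 are marked as having an abnormal breath-hold
response and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from lagcvr.preprocess import BoldSeries

__all__ = [
    "Co2Trace",
    "EndTidalTrace",
    "CvrMap",
    "end_tidal_detect",
    "end_tidal_interpolate",
    "petco2_baseline",
    "double_gamma_hrf",
    "build_regressor",
    "fit_cvr_voxel",
    "compute_cvr_map",
]

DEFAULT_DELAY_RANGE_S = (-15.0, 15.0)
DEFAULT_DELAY_STEP_S = 0.1
DEFAULT_FINE_DT_S = 0.1


@dataclass
class Co2Trace:
    """Raw capnograph samples in mmHg at a stated sampling rate.

    ``t0`` is the time of the first sample relative to the first BOLD frame.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("CO2 trace must be 1D")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("CO2 trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EndTidalTrace:
    """End-tidal CO2 envelope, piecewise linear between expiratory peaks,
    sampled on a uniform fine grid (default step 0.1 s)."""

    time_s: np.ndarray
    petco2_mmHg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.petco2_mmHg = np.asarray(self.petco2_mmHg, dtype=float)
        if self.time_s.shape != self.petco2_mmHg.shape:
            raise ValueError("time and value arrays must match")
        if self.time_s.size < 2:
            raise ValueError("end-tidal trace needs at least 2 samples")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class CvrMap:
    """Voxelwise CVR (%BOLD per mmHg), best-fit CO2 delay, and model fit.

    Invalid voxels (fit correlation below the validity threshold, or
    degenerate fits) carry NaN in every value map.
    """

    cvr: np.ndarray
    delay_s: np.ndarray
    fit_r: np.ndarray
    valid: np.ndarray


def end_tidal_detect(
    co2: Co2Trace,
    min_peak_separation_s: float = 2.0,
    min_prominence_mmHg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate expiratory peaks (end-tidal points) on the capnograph trace.

    Peaks are local maxima separated by at least ``min_peak_separation_s``
    and rising at least ``min_prominence_mmHg`` above their surroundings;
    the flat trace during a breath-hold has no expiratory peaks by
    construction.

    Returns ``(times_s, values_mmHg)``.
    """
    distance = max(1, int(round(min_peak_separation_s * co2.fs)))
    idx, _ = find_peaks(co2.samples, distance=distance, prominence=min_prominence_mmHg)
    if idx.size == 0:
        raise ValueError(
            "no expiratory peaks detected — inspect the CO2 trace for an "
            "adequate breathing signal"
        )
    return co2.times[idx], co2.samples[idx]


def end_tidal_interpolate(
    peak_times_s: np.ndarray,
    peak_values_mmHg: np.ndarray,
    scan_duration_s: float,
    dt: float = DEFAULT_FINE_DT_S,
) -> EndTidalTrace:
    """Piecewise-linear end-tidal envelope on a fine uniform grid covering
    ``[0, scan_duration_s]``; constant extrapolation beyond the first/last
    peak."""
    peak_times_s = np.asarray(peak_times_s, dtype=float)
    peak_values_mmHg = np.asarray(peak_values_mmHg, dtype=float)
    if peak_times_s.size < 2:
        raise ValueError("end-tidal interpolation needs at least 2 peaks")
    n = int(round(scan_duration_s / dt))
    grid = np.arange(n + 1) * dt
    values = np.interp(grid, peak_times_s, peak_values_mmHg)
    return EndTidalTrace(grid, values)


def petco2_baseline(
    peak_times_s: np.ndarray,
    peak_values_mmHg: np.ndarray,
    first_hold_start_s: float,
) -> float:
    """Resting end-tidal CO2 baseline: the median of end-tidal points
    recorded before the first breath-hold starts."""
    peak_times_s = np.asarray(peak_times_s, dtype=float)
    pre = np.asarray(peak_values_mmHg, dtype=float)[peak_times_s < first_hold_start_s]
    if pre.size == 0:
        raise ValueError("no end-tidal points before the first breath-hold")
    return float(np.median(pre))


def double_gamma_hrf(
    dt: float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response kernel.

    Difference of two gamma-shaped lobes with modes at ``peak_s`` and
    ``undershoot_s`` and undershoot-to-peak amplitude ``ratio``; sampled at
    ``dt`` over ``[0, length_s]`` and normalised to unit peak amplitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(length_s / dt))
    t = np.arange(n + 1) * dt

    def lobe(mode: float) -> np.ndarray:
        # (t/m)^m * exp(m - t): gamma-shaped with unit peak exactly at t = m
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp(mode * np.log(np.where(t > 0, t / mode, 1.0)) + mode - t)
        out[t == 0] = 0.0
        return out

    h = lobe(peak_s) - ratio * lobe(undershoot_s)
    return h / h.max()


def _fine_response(
    etco2: EndTidalTrace,
    hrf: np.ndarray,
    baseline_mmHg: float,
    max_delay_s: float,
) -> tuple[np.ndarray, float, float]:
    """HRF-convolved end-tidal deviation on a padded fine grid.

    Returns ``(x_fine, t_start, dt)`` where ``x_fine[i]`` is the response at
    time ``t_start + i * dt``. Padding (constant extrapolation of the
    envelope) covers the HRF length plus the largest delay searched so that
    every in-scan shifted sample is defined.
    """
    dt = etco2.dt
    dev = etco2.petco2_mmHg - baseline_mmHg
    n_pad = int(np.ceil(max_delay_s / dt)) + hrf.size + 1
    padded = np.concatenate([np.full(n_pad, dev[0]), dev, np.full(n_pad, dev[-1])])
    x = np.convolve(padded, hrf)[: padded.size] * dt
    t_start = float(etco2.time_s[0] - n_pad * dt)
    return x, t_start, dt


def build_regressor(
    etco2: EndTidalTrace,
    hrf: np.ndarray,
    tr: float,
    n_frames: int,
    delay_s: float,
    baseline_mmHg: float,
    max_delay_s: float = 15.0,
) -> np.ndarray:
    """Frame-sampled CO2 regressor at a given arrival delay.

    The end-tidal deviation from baseline is convolved with the HRF on the
    fine grid, shifted by ``delay_s`` (positive = later arrival of the CO2
    response at the voxel), and sampled at the frame times ``j * tr``.
    """
    if abs(delay_s) > max_delay_s:
        raise ValueError(f"|delay| exceeds the search bound {max_delay_s} s")
    x, t_start, dt = _fine_response(etco2, hrf, baseline_mmHg, max_delay_s)
    frame_t = np.arange(n_frames) * tr
    idx = np.round((frame_t - delay_s - t_start) / dt).astype(int)
    if np.all((idx < 0) | (idx >= x.size)):
        raise ValueError("shift places the regressor fully outside the scan window")
    idx = np.clip(idx, 0, x.size - 1)
    return x[idx]


def _delay_grid(delay_min_s: float, delay_max_s: float, step_s: float) -> np.ndarray:
    n = int(round((delay_max_s - delay_min_s) / step_s))
    return np.round(delay_min_s + np.arange(n + 1) * step_s, 10)


def _tie_break_order(delays: np.ndarray) -> np.ndarray:
    """Ordering of delay indices so that the first occurrence of a tied
    maximum correlation is the smallest |delay| (then the negative one)."""
    return np.lexsort((delays, np.abs(delays)))


def fit_cvr_voxel(
    voxel: np.ndarray,
    frame_valid: np.ndarray,
    regressor_factory: Callable[[float], np.ndarray],
    delay_grid_s: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Exhaustive delay search and GLM fit for a single voxel.

    For each candidate delay, the voxel is regressed on
    ``[intercept | regressor]`` over valid frames; the delay maximising the
    voxel–regressor Pearson correlation is kept (ties broken toward the
    smallest absolute delay). Returns
    ``(cvr_percent_per_mmHg, delay_s, fit_r)``; a zero-variance voxel
    yields NaNs rather than an error.
    """
    voxel = np.asarray(voxel, dtype=float)
    fv = np.asarray(frame_valid, dtype=bool)
    if fv.sum() < 20:
        raise ValueError("CVR fit needs at least 20 valid frames")
    if delay_grid_s is None:
        delay_grid_s = _delay_grid(*DEFAULT_DELAY_RANGE_S, DEFAULT_DELAY_STEP_S)
    delays = np.asarray(delay_grid_s, dtype=float)

    y = voxel[fv]
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        return float("nan"), float("nan"), float("nan")

    order = _tie_break_order(delays)
    best_r = -np.inf
    best = None
    for i in order:
        reg = np.asarray(regressor_factory(float(delays[i])), dtype=float)[fv]
        rc = reg - reg.mean()
        rnorm = np.linalg.norm(rc)
        if rnorm == 0:
            continue
        r = float(yc @ rc / (ynorm * rnorm))
        if r > best_r:
            best_r = r
            best = (delays[i], reg, rc, rnorm)
    if best is None:
        return float("nan"), float("nan"), float("nan")
    delay, reg, rc, rnorm = best
    beta = float(yc @ rc / rnorm**2)
    intercept = float(y.mean() - beta * reg.mean())
    cvr = 100.0 * beta / intercept if intercept != 0 else float("nan")
    return cvr, float(delay), best_r


def compute_cvr_map(
    bold: BoldSeries,
    etco2: EndTidalTrace,
    baseline_mmHg: float,
    hrf: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    delay_min_s: float = DEFAULT_DELAY_RANGE_S[0],
    delay_max_s: float = DEFAULT_DELAY_RANGE_S[1],
    delay_step_s: float = DEFAULT_DELAY_STEP_S,
    r_min: float = 0.1,
) -> CvrMap:
    """Voxelwise CVR map over the brain (or a given) mask.

    Per voxel, the CO2 regressor delay is optimised on the
    ``[delay_min_s, delay_max_s]`` grid and the GLM slope is converted to
    %BOLD per mmHg; voxels with best-fit correlation below ``r_min``
    (abnormal breath-hold response) are marked invalid. Per-voxel failures
    (flat signal) become invalid voxels, never errors.
    """
    if hrf is None:
        hrf = double_gamma_hrf(etco2.dt)
    if mask is None:
        mask = bold.brain_mask
    mask = np.asarray(mask, dtype=bool) & bold.brain_mask
    fv = bold.frame_valid
    if fv.sum() < 20:
        raise ValueError("CVR fit needs at least 20 valid frames")

    delays = _delay_grid(delay_min_s, delay_max_s, delay_step_s)
    max_abs_delay = float(np.max(np.abs(delays)))
    x, t_start, dt = _fine_response(etco2, hrf, baseline_mmHg, max_abs_delay)
    frame_t = np.arange(bold.n_frames) * bold.tr

    order = _tie_break_order(delays)
    delays_ord = delays[order]
    idx = np.round(
        (frame_t[None, :] - delays_ord[:, None] - t_start) / dt
    ).astype(int)
    idx = np.clip(idx, 0, x.size - 1)
    R = x[idx]  # (n_delays, n_frames), tie-break order

    V = bold.timeseries(mask)[:, fv]  # (n_vox, n_valid)
    Rv = R[:, fv]
    Vc = V - V.mean(axis=1, keepdims=True)
    Rc = Rv - Rv.mean(axis=1, keepdims=True)
    vnorm = np.linalg.norm(Vc, axis=1)
    rnorm = np.linalg.norm(Rc, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Rc @ Vc.T) / np.outer(rnorm, vnorm)
    C[rnorm == 0, :] = -np.inf
    C[:, vnorm == 0] = -np.inf
    # NaN from 0/0 should never win the argmax
    C = np.where(np.isnan(C), -np.inf, C)

    best = np.argmax(C, axis=0)  # first occurrence = smallest |delay| on ties
    n_vox = V.shape[0]
    fit_r = C[best, np.arange(n_vox)]
    delay = delays_ord[best]

    Rsel_c = Rc[best]  # (n_vox, n_valid)
    Rsel_mean = Rv[best].mean(axis=1)
    denom = np.sum(Rsel_c**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.sum(Rsel_c * Vc, axis=1) / denom
        intercept = V.mean(axis=1) - beta * Rsel_mean
        cvr = 100.0 * beta / intercept

    good = np.isfinite(fit_r) & np.isfinite(cvr)
    valid = good & (fit_r >= r_min)

    def volume(values: np.ndarray) -> np.ndarray:
        out = np.full(bold.shape, np.nan)
        out[mask] = np.where(good, values, np.nan)
        return out

    valid_vol = np.zeros(bold.shape, dtype=bool)
    valid_vol[mask] = valid
    return CvrMap(
        cvr=volume(cvr),
        delay_s=volume(delay.astype(float)),
        fit_r=volume(fit_r),
        valid=valid_vol,
    )
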