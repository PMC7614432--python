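"""Synthetic 4D BOLD phantoms with known ground truth.

Every downstream stage (preprocessing, lag mapping, CVR mapping, ROI
statistics) is validated against phantoms generated here: a symmetric
two-hemisphere anatomy with grey matter, a CSF core, and a spherical
left-hemisphere lesion; a band-limited (0.01–0.1 Hz) shared resting signal
applied with a voxelwise temporal offset; a breath-hold BOLD response driven
by the HRF-convolved end-tidal CO2 envelope scaled by a voxelwise CVR field
and shifted by a voxelwise arrival delay; a cyclic capnograph trace; and
rigid-body motion traces with optional outlier frames.

Signals are synthesised on a fine 0.1 s grid before resampling to TR so
that fractional-second lags and delays are honoured exactly, matching the
0.1 s resolution of the CVR delay search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lagcvr.cvrmap import (
    Co2Trace,
    DEFAULT_FINE_DT_S,
    double_gamma_hrf,
    end_tidal_detect,
    end_tidal_interpolate,
    petco2_baseline,
    _fine_response,
)
from lagcvr.preprocess import BoldSeries, MotionParams

__all__ = [
    "Paradigm",
    "GroundTruth",
    "PhantomAnatomy",
    "make_paradigm",
    "default_paradigm",
    "make_phantom_anatomy",
    "make_ground_truth",
    "simulate_co2_trace",
    "simulate_rest_bold",
    "simulate_bh_bold",
    "simulate_motion_params",
]

MAX_LAG_S = 8.0
MAX_DELAY_S = 15.0


@dataclass(frozen=True)
class Paradigm:
    """Breath-hold task timing: repeated cycles of normal breathing, paced
    breathing, and an end-expiration hold, after an initial lead-in."""

    n_cycles: int
    normal_s: float
    paced_s: float
    hold_s: float
    lead_in_s: float

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one breath-hold cycle")
        for name in ("normal_s", "paced_s", "hold_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lead_in_s < 0:
            raise ValueError("lead_in_s cannot be negative")

    @property
    def cycle_period_s(self) -> float:
        return self.normal_s + self.paced_s + self.hold_s

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + self.n_cycles * self.cycle_period_s

    def hold_windows(self) -> np.ndarray:
        """Closed-open ``[start, end)`` windows of the holds, shape (n, 2)."""
        starts = (
            self.lead_in_s
            + np.arange(self.n_cycles) * self.cycle_period_s
            + self.normal_s
            + self.paced_s
        )
        return np.column_stack([starts, starts + self.hold_s])


def make_paradigm(
    n_cycles: int = 6,
    normal_s: float = 14.0,
    paced_s: float = 16.0,
    hold_s: float = 15.0,
    lead_in_s: float = 10.0,
) -> Paradigm:
    """Breath-hold paradigm; defaults are the study task (six cycles of
    14 s normal / 16 s paced breathing / 15 s end-expiration hold)."""
    return Paradigm(n_cycles, normal_s, paced_s, hold_s, lead_in_s)


def default_paradigm() -> Paradigm:
    return make_paradigm()


@dataclass
class PhantomAnatomy:
    """Mask set for the phantom: grey matter, CSF, lesion and the two
    hemispheres, on a grid whose midline sagittal plane separates left
    (low first-axis index) from right."""

    gm_mask: np.ndarray
    csf_mask: np.ndarray
    lesion_mask: np.ndarray
    left_hemi_mask: np.ndarray
    right_hemi_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in (
            "gm_mask", "csf_mask", "lesion_mask",
            "left_hemi_mask", "right_hemi_mask",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if np.any(self.gm_mask & self.csf_mask):
            raise ValueError("grey matter and CSF masks overlap")
        if np.any(self.lesion_mask & ~self.left_hemi_mask):
            raise ValueError("lesion must lie inside the left hemisphere")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gm_mask.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.left_hemi_mask | self.right_hemi_mask

    @property
    def midline_index(self) -> float:
        """Sagittal reflection plane (first axis, voxel coordinates)."""
        return (self.shape[0] - 1) / 2.0


def make_phantom_anatomy(
    shape: tuple[int, int, int] = (20, 20, 10),
    voxel_size_mm: float | tuple[float, float, float] = 2.0,
    lesion_centre: tuple[int, int, int] = (5, 10, 5),
    lesion_radius_mm: float = 4.0,
) -> PhantomAnatomy:
    """Symmetric two-hemisphere anatomy with a spherical lesion.

    The brain is an ellipsoid inscribed in the grid; a small central
    ellipsoid is CSF, the rest grey matter. The lesion is a sphere of the
    requested radius around ``lesion_centre`` and must lie strictly within
    the left (low-index) half of the grid.
    """
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    vox = np.asarray(voxel_size_mm, dtype=float)
    nx, ny, nz = shape
    centre = (np.asarray(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    coords = np.stack([ii, jj, kk], axis=-1).astype(float)

    semi = centre * np.array([0.95, 0.95, 0.95])
    semi = np.maximum(semi, 1.0)
    norm2 = (((coords - centre) / semi) ** 2).sum(axis=-1)
    brain = norm2 <= 1.0

    csf_semi = np.maximum(semi * 0.25, 1.0)
    csf = ((((coords - centre) / csf_semi) ** 2).sum(axis=-1)) <= 1.0
    csf &= brain
    gm = brain & ~csf

    midline = (nx - 1) / 2.0
    left = brain & (ii < midline)
    right = brain & (ii > midline)
    if nx % 2 == 1:
        # odd grid: the midline column is split between neither hemisphere
        left = brain & (ii < int(midline))
        right = brain & (ii > int(midline))

    d_mm = (coords - np.asarray(lesion_centre, dtype=float)) * vox
    lesion = (d_mm**2).sum(axis=-1) <= lesion_radius_mm**2
    if np.any(lesion & ~left):
        raise ValueError(
            "lesion sphere crosses the midline or leaves the left hemisphere"
        )
    return PhantomAnatomy(
        gm_mask=gm,
        csf_mask=csf,
        lesion_mask=lesion,
        left_hemi_mask=left,
        right_hemi_mask=right,
        voxel_size_mm=tuple(vox),
    )


@dataclass
class GroundTruth:
    """Latent voxel fields the estimators try to recover, plus the noise
    level and RNG seed of a phantom realisation.

    ``lag_field`` (s) is the temporal offset of the shared resting signal,
    ``cvr_field`` the %BOLD-per-mmHg reactivity, ``delay_field`` (s) the CO2
    arrival delay, ``amplitude_field`` the unitless coupling to the shared
    signal, and ``baseline_field`` the raw-unit voxel baseline.
    """

    lag_field: np.ndarray
    cvr_field: np.ndarray
    delay_field: np.ndarray
    amplitude_field: np.ndarray
    baseline_field: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = np.asarray(self.lag_field).shape
        for name in (
            "lag_field", "cvr_field", "delay_field",
            "amplitude_field", "baseline_field",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError("all ground-truth fields must share a grid")
            setattr(self, name, arr)
        if np.any(np.abs(self.lag_field) > MAX_LAG_S):
            raise ValueError(f"|lag| must not exceed {MAX_LAG_S} s")
        if np.any(np.abs(self.delay_field) > MAX_DELAY_S):
            raise ValueError(f"|delay| must stay within +/-{MAX_DELAY_S} s")
        if np.any(self.baseline_field <= 0):
            raise ValueError("baseline must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")


def make_ground_truth(
    anatomy: PhantomAnatomy,
    lag_range_s: tuple[float, float] = (-2.0, 2.0),
    cvr_range: tuple[float, float] = (0.1, 0.4),
    delay_range_s: tuple[float, float] = (-8.0, 8.0),
    amplitude: float = 0.01,
    baseline: float = 1000.0,
    noise_sd: float = 0.0,
    lesion_void: bool = True,
    seed: int = 0,
) -> GroundTruth:
    """Draw voxelwise ground-truth fields for a phantom.

    Lags and delays are uniform over their ranges, rounded to the 0.1 s
    simulation grid (the default +/-2 s lag range gives a mean absolute
    lag near 1 s, the scale reported in stroke cohorts); CVR is uniform
    over ``cvr_range`` in grey matter; the
    coupling amplitude is a fixed fraction of baseline (default 1%, i.e.
    a 1% BOLD fluctuation). With ``lesion_void`` the lesion loses both its
    shared-signal coupling and its CVR (signal suppression). Baselines vary
    mildly (+/-10%) around the nominal raw-unit level.
    """
    rng = np.random.default_rng(seed)
    shape = anatomy.shape
    brain = anatomy.brain_mask

    lag = np.zeros(shape)
    lag[brain] = np.round(
        rng.uniform(*lag_range_s, size=int(brain.sum())), 1
    )
    cvr = np.zeros(shape)
    cvr[anatomy.gm_mask] = rng.uniform(*cvr_range, size=int(anatomy.gm_mask.sum()))
    delay = np.zeros(shape)
    delay[brain] = np.round(rng.uniform(*delay_range_s, size=int(brain.sum())), 1)
    amp = np.where(brain, amplitude, 0.0)
    base = np.full(shape, baseline)
    base *= rng.uniform(0.9, 1.1, size=shape)
    if lesion_void:
        amp[anatomy.lesion_mask] = 0.0
        cvr[anatomy.lesion_mask] = 0.0
    return GroundTruth(
        lag_field=lag,
        cvr_field=cvr,
        delay_field=delay,
        amplitude_field=amp,
        baseline_field=base,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_co2_trace(
    paradigm: Paradigm,
    fs: float = 200.0,
    baseline_mmHg: float = 40.0,
    hold_rise_mmHg: float = 8.0,
    resp_rate_hz: float = 0.25,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float | None = None,
    trough_mmHg: float = 2.0,
    relax_tau_s: float = 10.0,
) -> Co2Trace:
    """Cyclic capnograph trace for a breath-hold task.

    The trace oscillates at the respiratory rate between an inspiratory
    trough and the end-tidal envelope. The envelope sits at
    ``baseline_mmHg`` during breathing; in the first expiration after each
    hold it reaches ``baseline_mmHg + hold_rise_mmHg`` (the hypercapnic
    end-tidal rise) and then relaxes exponentially back to baseline with a
    ``relax_tau_s`` time constant. During a hold the trace is flat at the
    trough — no expiration, no end-tidal points.
    """
    if fs <= 2 * resp_rate_hz:
        raise ValueError("sampling rate must exceed twice the respiratory rate")
    if duration_s is None:
        duration_s = paradigm.duration_s + 15.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    holds = paradigm.hold_windows()
    period = 1.0 / resp_rate_hz

    # breathing resumes from the inspiratory trough after each hold: the
    # respiratory phase restarts at every hold end
    phase_origin = np.zeros(n)
    for _, end in holds:
        phase_origin[t >= end] = end
    osc = 0.5 * (1.0 + np.sin(
        2 * np.pi * resp_rate_hz * (t - phase_origin) - np.pi / 2
    ))

    envelope = np.full(n, baseline_mmHg)
    for h, (start, end) in enumerate(holds):
        # first expiratory peak after the hold: half a period after phase reset
        t_peak = end + 0.5 * period
        seg_end = holds[h + 1, 0] if h + 1 < len(holds) else duration_s
        seg = (t >= end) & (t < seg_end)
        envelope[seg] = baseline_mmHg + hold_rise_mmHg * np.exp(
            -np.maximum(t[seg] - t_peak, 0.0) / relax_tau_s
        )

    signal = trough_mmHg + (envelope - trough_mmHg) * osc
    in_hold = np.zeros(n, dtype=bool)
    for start, end in holds:
        in_hold |= (t >= start) & (t < end)
    signal[in_hold] = trough_mmHg

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return Co2Trace(np.clip(signal, 0.0, None), fs=fs)


def _bandlimited_signal(
    rng: np.random.Generator,
    n: int,
    dt: float,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
) -> np.ndarray:
    """Zero-mean, unit-variance noise band-limited to [f_lo, f_hi] Hz by a
    top-hat frequency-domain filter of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    s = np.fft.irfft(spec, n=n)
    s -= s.mean()
    sd = s.std()
    if sd == 0:
        raise ValueError("degenerate band-limited signal (too few samples)")
    return s / sd


def _check_frames(n_frames: int, max_shift_frames: int) -> None:
    if n_frames < 2 * max_shift_frames + 1:
        raise ValueError(
            "too few frames for the downstream lag search: need at least "
            f"{2 * max_shift_frames + 1}"
        )


def _shifted_samples(
    fine: np.ndarray,
    frame_fine_idx: np.ndarray,
    shifts_s: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Sample ``fine[t - shift]`` at the frame times for per-voxel shifts."""
    k = np.round(shifts_s / dt).astype(int)
    idx = frame_fine_idx[None, :] - k[:, None]
    return fine[idx]


def simulate_rest_bold(
    anatomy: PhantomAnatomy,
    truth: GroundTruth,
    tr: float = 2.0,
    n_frames: int = 150,
    max_shift_frames: int = 4,
    dt: float = DEFAULT_FINE_DT_S,
) -> BoldSeries:
    """Resting-state phantom: ``S_v(t) = B_v (1 + a_v s(t - tau_v)) + eps``.

    ``s`` is a shared zero-mean unit-variance signal band-limited to
    0.01–0.1 Hz, generated on the fine grid so fractional-second lags are
    honoured before resampling at TR; CSF voxels carry an independent
    confound signal instead of the shared one; ``eps`` is white noise with
    the ground-truth noise SD.
    """
    _check_frames(n_frames, max_shift_frames)
    if truth.lag_field.shape != anatomy.shape:
        raise ValueError("ground truth and anatomy grids differ")
    rng = np.random.default_rng(truth.seed)
    pad_s = MAX_LAG_S + 2 * tr
    n_fine = int(round((n_frames * tr + 2 * pad_s) / dt))
    s = _bandlimited_signal(rng, n_fine, dt)
    confound = _bandlimited_signal(rng, n_fine, dt)
    frame_idx = np.round((np.arange(n_frames) * tr + pad_s) / dt).astype(int)

    brain = anatomy.brain_mask
    n_vox = int(brain.sum())
    S = _shifted_samples(s, frame_idx, truth.lag_field[brain], dt)
    csf_in_brain = anatomy.csf_mask[brain]
    S[csf_in_brain] = confound[frame_idx][None, :]

    B = truth.baseline_field[brain][:, None]
    a = truth.amplitude_field[brain][:, None]
    sig = B * (1.0 + a * S)
    if truth.noise_sd > 0:
        sig = sig + rng.normal(0.0, truth.noise_sd, size=sig.shape)

    data = np.zeros(anatomy.shape + (n_frames,))
    data[brain] = sig
    return BoldSeries(
        data=data,
        tr=tr,
        frame_valid=np.ones(n_frames, dtype=bool),
        brain_mask=brain,
        voxel_size_mm=anatomy.voxel_size_mm,
    )


def simulate_bh_bold(
    anatomy: PhantomAnatomy,
    truth: GroundTruth,
    co2: Co2Trace,
    paradigm: Paradigm,
    tr: float = 2.0,
    n_frames: int | None = None,
    max_shift_frames: int = 4,
    dt: float = DEFAULT_FINE_DT_S,
) -> BoldSeries:
    """Breath-hold phantom:
    ``S_v(t) = B_v (1 + (CVR_v/100) x(t - delta_v) + a_v s(t - tau_v)) + eps``.

    ``x`` is the HRF-convolved end-tidal deviation from baseline in mmHg,
    built with exactly the same operators the CVR estimator uses (end-tidal
    peak detection, linear interpolation, double-gamma convolution on the
    fine grid) and resampled at TR with the voxel's arrival delay.
    """
    if n_frames is None:
        n_frames = int(paradigm.duration_s / tr)
    _check_frames(n_frames, max_shift_frames)
    scan_duration = n_frames * tr
    if co2.duration_s < scan_duration:
        raise ValueError("CO2 trace must cover the full scan duration")
    rng = np.random.default_rng(truth.seed)

    peak_t, peak_v = end_tidal_detect(co2)
    etco2 = end_tidal_interpolate(peak_t, peak_v, scan_duration, dt)
    baseline = petco2_baseline(peak_t, peak_v, paradigm.hold_windows()[0, 0])
    hrf = double_gamma_hrf(dt)
    x, t_start, _ = _fine_response(etco2, hrf, baseline, MAX_DELAY_S)

    brain = anatomy.brain_mask
    frame_t = np.arange(n_frames) * tr
    delta = truth.delay_field[brain]
    idx = np.round(
        (frame_t[None, :] - delta[:, None] - t_start) / dt
    ).astype(int)
    X = x[np.clip(idx, 0, x.size - 1)]  # (n_vox, n_frames)

    pad_s = MAX_LAG_S + 2 * tr
    n_fine = int(round((scan_duration + 2 * pad_s) / dt))
    s = _bandlimited_signal(rng, n_fine, dt)
    confound = _bandlimited_signal(rng, n_fine, dt)
    frame_idx = np.round((frame_t + pad_s) / dt).astype(int)
    S = _shifted_samples(s, frame_idx, truth.lag_field[brain], dt)
    S[anatomy.csf_mask[brain]] = confound[frame_idx][None, :]

    B = truth.baseline_field[brain][:, None]
    a = truth.amplitude_field[brain][:, None]
    cvr = truth.cvr_field[brain][:, None]
    sig = B * (1.0 + (cvr / 100.0) * X + a * S)
    if truth.noise_sd > 0:
        sig = sig + rng.normal(0.0, truth.noise_sd, size=sig.shape)

    data = np.zeros(anatomy.shape + (n_frames,))
    data[brain] = sig
    return BoldSeries(
        data=data,
        tr=tr,
        frame_valid=np.ones(n_frames, dtype=bool),
        brain_mask=brain,
        voxel_size_mm=anatomy.voxel_size_mm,
    )


def simulate_motion_params(
    n_frames: int,
    outlier_frames: tuple[int, ...] = (),
    outlier_magnitude_mm: float = 1.5,
    seed: int = 0,
    baseline_amplitude_mm: float = 0.05,
) -> MotionParams:
    """Smooth low-amplitude head motion with optional single-frame
    translation spikes at the listed outlier frames.

    Baseline motion is a sum of slow sinusoids with amplitude
    ``baseline_amplitude_mm`` for translations and the arc-length
    equivalent (amplitude / 50 mm) for rotations; each outlier frame gets a
    ``outlier_magnitude_mm`` step added to the x-translation.
    """
    outlier_frames = tuple(int(f) for f in outlier_frames)
    if any(f < 0 or f >= n_frames for f in outlier_frames):
        raise ValueError("outlier frame index out of range")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float)
    params = np.zeros((n_frames, 6))
    for c in range(6):
        amp = baseline_amplitude_mm if c < 3 else baseline_amplitude_mm / 50.0
        f = rng.uniform(0.002, 0.01)
        phase = rng.uniform(0, 2 * np.pi)
        params[:, c] = amp * np.sin(2 * np.pi * f * t + phase)
    for fidx in outlier_frames:
        params[fidx, 0] += outlier_magnitude_mm
    return MotionParams(params)
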