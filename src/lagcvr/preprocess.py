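"""Frame-level quality control and nuisance removal for BOLD series.

The cleaning chain applied identically before lag and CVR estimation is:
framewise displacement -> motion-outlier flagging -> nuisance regression
(six motion parameters + CSF timecourse) -> high-pass filtering. Flagged
frames are excluded from every estimation step but are kept in the array so
that shift alignment downstream stays index-true.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BoldSeries",
    "MotionParams",
    "FdSeries",
    "framewise_displacement",
    "flag_motion_outliers",
    "scan_exclusion_check",
    "regress_nuisance",
    "highpass_filter",
]


@dataclass
class BoldSeries:
    """A 4D BOLD acquisition with its sampling and validity metadata.

    Parameters
    ----------
    data:
        Array of shape ``(x, y, z, t)`` in raw scanner units.
    tr:
        Repetition time in seconds (sampling interval of the series).
    frame_valid:
        Boolean per frame; ``False`` marks motion-censored frames.
    brain_mask:
        Boolean 3D volume selecting in-brain voxels.
    voxel_size_mm:
        Per-axis voxel edge length in millimetres.
    """

    data: np.ndarray
    tr: float
    frame_valid: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 frames")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        self.frame_valid = np.asarray(self.frame_valid, dtype=bool)
        if self.frame_valid.shape != (self.data.shape[3],):
            raise ValueError("frame_valid length must equal the number of frames")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape must match the BOLD grid")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def timeseries(self, mask: np.ndarray) -> np.ndarray:
        """Extract the ``(n_voxels, t)`` matrix of in-mask timecourses."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("mask shape must match the BOLD grid")
        return self.data[mask]


@dataclass
class MotionParams:
    """Rigid-body motion estimates: per frame, 3 translations (mm) and 3
    rotations (radians), in that column order."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be a (frames, 6) array")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class FdSeries:
    """Framewise displacement in millimetres; the first frame is 0 by
    definition."""

    fd: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ValueError("FD must be a 1D series")
        if np.any(self.fd < 0):
            raise ValueError("FD cannot be negative")


def framewise_displacement(
    motion: MotionParams, sphere_radius_mm: float = 50.0
) -> FdSeries:
    """Power-style framewise displacement.

    ``FD_t = sum |d translation_i| + radius * sum |d rotation_i|`` with
    backward differences; rotations are converted to arc length on a sphere
    of the given radius (default 50 mm). ``FD_0 = 0``.
    """
    if motion.n_frames < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + sphere_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return FdSeries(np.concatenate([[0.0], fd]))


def flag_motion_outliers(fd: FdSeries, threshold_mm: float = 1.0) -> np.ndarray:
    """Frame validity under the motion rule: a frame is invalid iff its FD
    strictly exceeds the threshold (default 1 mm)."""
    return fd.fd <= threshold_mm


def scan_exclusion_check(
    frame_valid: np.ndarray, max_invalid_fraction: float = 0.5
) -> bool:
    """Whole-scan keep/discard decision.

    Returns ``True`` (keep) unless the invalid-frame fraction strictly
    exceeds ``max_invalid_fraction`` (default: more than half the acquired
    volumes lost to motion discards the scan).
    """
    frame_valid = np.asarray(frame_valid, dtype=bool)
    invalid_fraction = 1.0 - frame_valid.mean()
    return bool(invalid_fraction <= max_invalid_fraction)


def _drop_zero_columns(regressors: np.ndarray) -> np.ndarray:
    keep = np.ptp(regressors, axis=0) > 0
    keep |= np.any(regressors != 0, axis=0)  # constant non-zero columns stay
    return regressors[:, keep]


def _check_design_rank(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via incremental rank growth
        bad = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                bad.append(j)
            r = rj
        raise ValueError(
            f"rank-deficient nuisance design; collinear columns (0-based, "
            f"including leading intercept): {bad}"
        )


def regress_nuisance(bold: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Remove nuisance signals (e.g. motion parameters and a CSF timecourse)
    by voxelwise OLS over valid frames.

    The design is ``[intercept | regressors]`` restricted to valid frames;
    residuals replace the signal there and the voxel mean is added back so
    baseline units are preserved. Invalid frames pass through unchanged and
    remain flagged. All-zero regressor columns are ignored.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != bold.n_frames:
        raise ValueError(
            f"regressor rows ({regressors.shape[0]}) must match BOLD frames "
            f"({bold.n_frames})"
        )
    regressors = _drop_zero_columns(regressors)
    fv = bold.frame_valid
    n_valid = int(fv.sum())
    X = np.column_stack([np.ones(n_valid), regressors[fv]])
    if X.shape[1] > 1:
        _check_design_rank(X)

    vox = bold.data[bold.brain_mask]  # (n_vox, t)
    y = vox[:, fv].T  # (n_valid, n_vox)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    cleaned = resid + y.mean(axis=0)

    out = bold.data.copy()
    block = vox.copy()
    block[:, fv] = cleaned.T
    out[bold.brain_mask] = block
    return replace(bold, data=out)


def dct_drift_basis(n_frames: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis spanning frequencies strictly below the
    cutoff, evaluated at every frame index (DCT-II convention)."""
    T = n_frames * tr
    ks = [k for k in range(1, n_frames) if k / (2.0 * T) < cutoff_hz]
    j = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (j + 0.5) / n_frames) for k in ks]
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


def highpass_filter(bold: BoldSeries, cutoff_hz: float = 0.01) -> BoldSeries:
    """Remove slow drifts below the cutoff (default 0.01 Hz) by regressing
    out a discrete-cosine basis over valid frames; the voxel mean is
    re-added. Censored frames are handled cleanly because the basis is
    evaluated per frame and fitted on valid frames only."""
    if cutoff_hz <= 0:
        raise ValueError("high-pass cutoff must be positive")
    if bold.n_frames * bold.tr <= 1.0 / cutoff_hz:
        raise ValueError(
            "scan duration must exceed one period of the high-pass cutoff"
        )
    basis = dct_drift_basis(bold.n_frames, bold.tr, cutoff_hz)
    if basis.shape[1] == 0:
        return replace(bold, data=bold.data.copy())
    return regress_nuisance(bold, basis)
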