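"""End-to-end orchestration: preprocess -> lag map -> CVR map -> ROIs ->
subject statistics, and group-level aggregation.

`RunConfig` carries every tunable with the study defaults (1 mm FD
threshold, 50% scan-exclusion rule, 0.01 Hz high-pass, r >= 0.1 validity
for both lag and CVR, +/-4 TR shift grid, -15..+15 s CO2 delay search in
0.1 s steps, 10 mm perilesional radius, FDR q = 0.1, family alpha 0.05
over 6 ROIs). Every written output carries a JSON sidecar with the config
hash and package version so results are reconstructible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lagcvr import io as lio
from lagcvr.cvrmap import (
    CvrMap,
    compute_cvr_map,
    end_tidal_detect,
    end_tidal_interpolate,
    petco2_baseline,
)
from lagcvr.lagmap import (
    LagMap,
    compute_lag_map,
    hemisphere_mean_lag,
    reference_timeseries,
)
from lagcvr.preprocess import (
    flag_motion_outliers,
    framewise_displacement,
    highpass_filter,
    regress_nuisance,
    scan_exclusion_check,
)
from lagcvr.roi import RoiSet, build_roi_set
from lagcvr.stats import (
    bonferroni_alpha,
    group_wilcoxon_vs_zero,
    roi_spearman,
    voxelwise_group_anova,
)
from lagcvr.synth import Paradigm

logger = logging.getLogger("lagcvr")

__all__ = ["RunConfig", "SubjectResult", "GroupResult", "run_subject", "run_group"]


@dataclass
class RunConfig:
    """Paths and parameters for one subject run; numeric defaults are the
    study constants."""

    bold_path: str = ""
    motion_path: str = ""
    gm_mask_path: str = ""
    csf_mask_path: str = ""
    lesion_mask_path: str = ""
    left_hemi_path: str = ""
    right_hemi_path: str = ""
    co2_path: str = ""  # empty: resting-state run, no CVR
    out_dir: str = ""
    tr_s: float = 2.0
    fd_threshold_mm: float = 1.0
    max_invalid_fraction: float = 0.5
    highpass_hz: float = 0.01
    lag_r_min: float = 0.1
    max_shift_frames: int = 4
    cvr_r_min: float = 0.1
    delay_min_s: float = -15.0
    delay_max_s: float = 15.0
    delay_step_s: float = 0.1
    roi_radius_mm: float = 10.0
    fdr_q: float = 0.1
    family_alpha: float = 0.05
    n_roi_tests: int = 6
    paradigm: dict = field(
        default_factory=lambda: dict(
            n_cycles=6, normal_s=14.0, paced_s=16.0, hold_s=15.0, lead_in_s=10.0
        )
    )
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SubjectResult:
    """Outputs of one subject run."""

    kept: bool
    qc: dict
    lag_map: LagMap | None = None
    cvr_map: CvrMap | None = None
    roi_set: RoiSet | None = None
    roi_spearman: dict | None = None
    lesioned_hemisphere_mean_lag_s: float | None = None


@dataclass
class GroupResult:
    anova: object
    roi_table: pd.DataFrame
    wilcoxon_table: pd.DataFrame


def _load_grid_checked(config: RunConfig):
    bold = lio.load_bold(config.bold_path, tr=config.tr_s)
    masks = {}
    for key in ("gm_mask_path", "csf_mask_path", "lesion_mask_path",
                "left_hemi_path", "right_hemi_path"):
        path = getattr(config, key)
        mask = lio.load_mask(path)
        if mask.shape != bold.shape:
            raise ValueError(
                f"grid mismatch: {path} has shape {mask.shape}, BOLD grid is "
                f"{bold.shape}"
            )
        masks[key.replace("_path", "")] = mask
    return bold, masks


def _sidecar(config: RunConfig) -> dict:
    from lagcvr import __version__

    return {"config": config.to_dict(), "config_hash": config.config_hash(),
            "version": __version__}


def run_subject(config: RunConfig) -> SubjectResult:
    """Run the full subject-level pipeline from files on disk.

    Preprocessing (FD flagging, scan-exclusion check, nuisance regression
    of the six motion parameters plus the CSF mean timecourse, 0.01 Hz
    high-pass) is followed by lag mapping against the lesion-excluded
    grey-matter reference and, when a CO2 trace is configured, CVR
    mapping; ROI construction and subject statistics close the run. All
    declared outputs are written under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bold, masks = _load_grid_checked(config)
    motion = lio.load_motion_tsv(config.motion_path)
    if motion.n_frames != bold.n_frames:
        raise ValueError(
            f"motion rows ({motion.n_frames}) do not match BOLD frames "
            f"({bold.n_frames}) in {config.motion_path}"
        )
    bold.brain_mask = masks["left_hemi"] | masks["right_hemi"]

    logger.info("preprocessing: FD, outlier flagging, nuisance, high-pass")
    fd = framewise_displacement(motion)
    bold.frame_valid = flag_motion_outliers(fd, config.fd_threshold_mm)
    kept = scan_exclusion_check(bold.frame_valid, config.max_invalid_fraction)
    qc = {
        "fd_mean_mm": float(fd.fd.mean()),
        "fd_max_mm": float(fd.fd.max()),
        "n_invalid_frames": int((~bold.frame_valid).sum()),
        "n_frames": bold.n_frames,
        "kept": bool(kept),
    }
    lio.write_sidecar(out_dir / "qc.json", {**qc, **_sidecar(config)})
    if not kept:
        logger.warning("scan discarded: >%.0f%% frames invalid",
                       100 * config.max_invalid_fraction)
        return SubjectResult(kept=False, qc=qc)

    csf_ts = bold.timeseries(masks["csf_mask"] & bold.brain_mask).mean(axis=0)
    nuisance = np.column_stack([motion.params, csf_ts])
    bold = regress_nuisance(bold, nuisance)
    bold = highpass_filter(bold, config.highpass_hz)

    logger.info("lag mapping")
    reference = reference_timeseries(
        bold, masks["gm_mask"], exclude_mask=masks["lesion_mask"]
    )
    lag = compute_lag_map(
        bold, reference,
        r_min=config.lag_r_min, max_shift_frames=config.max_shift_frames,
    )
    lio.save_nifti(out_dir / "lag_s.nii.gz", lag.lag_s, bold.voxel_size_mm)
    lio.save_nifti(out_dir / "lag_peak_r.nii.gz", lag.peak_r, bold.voxel_size_mm)
    lio.save_mask(out_dir / "lag_valid.nii.gz", lag.valid, bold.voxel_size_mm)

    cvr = None
    if config.co2_path:
        logger.info("CVR mapping")
        co2 = lio.load_co2(config.co2_path)
        paradigm = Paradigm(**config.paradigm)
        peak_t, peak_v = end_tidal_detect(co2)
        etco2 = end_tidal_interpolate(
            peak_t, peak_v, bold.n_frames * bold.tr
        )
        baseline = petco2_baseline(peak_t, peak_v, paradigm.hold_windows()[0, 0])
        cvr = compute_cvr_map(
            bold, etco2, baseline,
            delay_min_s=config.delay_min_s, delay_max_s=config.delay_max_s,
            delay_step_s=config.delay_step_s, r_min=config.cvr_r_min,
        )
        lio.save_nifti(out_dir / "cvr.nii.gz", cvr.cvr, bold.voxel_size_mm)
        lio.save_nifti(out_dir / "cvr_delay_s.nii.gz", cvr.delay_s,
                       bold.voxel_size_mm)
        lio.save_nifti(out_dir / "cvr_fit_r.nii.gz", cvr.fit_r,
                       bold.voxel_size_mm)
        lio.save_mask(out_dir / "cvr_valid.nii.gz", cvr.valid,
                      bold.voxel_size_mm)

    logger.info("ROI construction and subject statistics")
    roi_set = build_roi_set(
        masks["lesion_mask"], masks["gm_mask"],
        masks["left_hemi"], masks["right_hemi"],
        bold.voxel_size_mm, radius_mm=config.roi_radius_mm,
    )
    for label, mask in roi_set.as_dict().items():
        lio.save_mask(out_dir / f"roi_{label}.nii.gz", mask, bold.voxel_size_mm)

    hemi_lag = hemisphere_mean_lag(
        lag, masks["left_hemi"] & masks["gm_mask"]
    )
    spearman = None
    if cvr is not None:
        spearman = {
            label: roi_spearman(lag, cvr, mask)
            for label, mask in roi_set.as_dict().items()
        }
    summary = {
        "lesioned_hemisphere_mean_lag_s": hemi_lag,
        "lag_valid_fraction": float(lag.valid[bold.brain_mask].mean()),
    }
    if spearman is not None:
        summary["roi_spearman_r"] = {k: v.r for k, v in spearman.items()}
        summary["roi_spearman_n"] = {k: v.n_voxels for k, v in spearman.items()}
    lio.write_sidecar(out_dir / "subject_summary.json",
                      {**summary, **_sidecar(config)})
    return SubjectResult(
        kept=True, qc=qc, lag_map=lag, cvr_map=cvr, roi_set=roi_set,
        roi_spearman=spearman, lesioned_hemisphere_mean_lag_s=hemi_lag,
    )


def run_group(
    subjects: list[SubjectResult],
    group_labels,
    timepoint_labels,
    fdr_q: float = 0.1,
    family_alpha: float = 0.05,
) -> GroupResult:
    """Group-level aggregation: voxelwise two-factor ANOVA on lag maps,
    plus per-ROI Wilcoxon tests of the subject-level lag-CVR Spearman
    correlations against zero at the Bonferroni-corrected alpha."""
    kept = [s for s in subjects if s.kept]
    if len(kept) < len(subjects):
        logger.info("excluding %d discarded scans", len(subjects) - len(kept))
    maps = [s.lag_map for s in kept]
    anova = voxelwise_group_anova(
        maps, list(group_labels), list(timepoint_labels), q=fdr_q
    )

    rows = []
    for i, s in enumerate(kept):
        if s.roi_spearman is None:
            continue
        for label, rc in s.roi_spearman.items():
            rows.append({"subject": i, "roi": label, "r": rc.r,
                         "n_voxels": rc.n_voxels})
    roi_table = pd.DataFrame(rows)

    wrows = []
    if not roi_table.empty:
        labels = roi_table["roi"].unique()
        alpha = bonferroni_alpha(family_alpha, len(labels))
        for label in labels:
            vals = roi_table.loc[roi_table["roi"] == label, "r"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size >= 6:
                p, sig = group_wilcoxon_vs_zero(vals, alpha)
            else:
                p, sig = float("nan"), False
            wrows.append({"roi": label, "n_subjects": int(vals.size),
                          "mean_r": float(vals.mean()) if vals.size else float("nan"),
                          "wilcoxon_p": p, "significant": sig,
                          "alpha": alpha})
    wilcoxon_table = pd.DataFrame(wrows)
    return GroupResult(anova=anova, roi_table=roi_table,
                       wilcoxon_table=wilcoxon_table)
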