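"""File formats: NIfTI volumes, motion TSV, CO2 text traces, JSON sidecars.

Volumes travel as NIfTI-1 with the voxel size encoded in the affine;
motion parameters as 6-column TSV (3 translations in mm, 3 rotations in
radians); CO2 traces as single-column text with a one-line header stating
the sampling rate; scalar phantom parameters as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from lagcvr.cvrmap import Co2Trace
from lagcvr.preprocess import BoldSeries, MotionParams
from lagcvr.synth import GroundTruth

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_mask",
    "load_mask",
    "save_bold",
    "load_bold",
    "save_motion_tsv",
    "load_motion_tsv",
    "save_co2",
    "load_co2",
    "save_ground_truth",
    "load_ground_truth",
    "write_sidecar",
]

MOTION_COLUMNS = [
    "trans_x_mm", "trans_y_mm", "trans_z_mm",
    "rot_x_rad", "rot_y_rad", "rot_z_rad",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_nifti(
    path, data: np.ndarray, voxel_size_mm, tr: float | None = None
) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm))
    if tr is not None and data.ndim == 4:
        zooms = list(voxel_size_mm) + [tr]
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return np.asarray(img.get_fdata()), tuple(float(z) for z in zooms[:3])


def save_mask(path, mask: np.ndarray, voxel_size_mm) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm)
    )
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0


def save_bold(path, bold: BoldSeries) -> None:
    save_nifti(path, bold.data, bold.voxel_size_mm, tr=bold.tr)


def load_bold(
    path,
    brain_mask: np.ndarray | None = None,
    frame_valid: np.ndarray | None = None,
    tr: float | None = None,
) -> BoldSeries:
    """Read a 4D NIfTI as a BoldSeries; TR defaults to the header's fourth
    zoom, the brain mask to all non-zero-variance voxels."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    zooms = img.header.get_zooms()
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if brain_mask is None:
        brain_mask = data.std(axis=3) > 0
    if frame_valid is None:
        frame_valid = np.ones(data.shape[3], dtype=bool)
    return BoldSeries(
        data=data,
        tr=tr,
        frame_valid=frame_valid,
        brain_mask=brain_mask,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
    )


def save_motion_tsv(path, motion: MotionParams) -> None:
    pd.DataFrame(motion.params, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_motion_tsv(path) -> MotionParams:
    df = pd.read_csv(path, sep="\t")
    return MotionParams(df[MOTION_COLUMNS].to_numpy())


def save_co2(path, co2: Co2Trace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={co2.fs} t0_s={co2.t0}\n")
        for v in co2.samples:
            fh.write(f"{v:.6f}\n")


def load_co2(path) -> Co2Trace:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(
            item.split("=") for item in header.lstrip("# ").split()
        )
        samples = np.loadtxt(fh)
    return Co2Trace(
        samples, fs=float(fields["fs_hz"]), t0=float(fields.get("t0_s", 0.0))
    )


def save_ground_truth(out_dir, truth: GroundTruth, voxel_size_mm) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("lag_field", "cvr_field", "delay_field",
                 "amplitude_field", "baseline_field"):
        save_nifti(out_dir / f"{name}.nii.gz", getattr(truth, name), voxel_size_mm)
    write_sidecar(
        out_dir / "ground_truth.json",
        {"noise_sd": truth.noise_sd, "seed": truth.seed},
    )


def load_ground_truth(out_dir) -> GroundTruth:
    out_dir = Path(out_dir)
    fields = {
        name: load_nifti(out_dir / f"{name}.nii.gz")[0]
        for name in ("lag_field", "cvr_field", "delay_field",
                     "amplitude_field", "baseline_field")
    }
    with open(out_dir / "ground_truth.json") as fh:
        scalars = json.load(fh)
    return GroundTruth(**fields, **scalars)


def write_sidecar(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
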