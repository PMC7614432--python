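"""Lesion-anchored region-of-interest geometry.

Six tissue compartments drive the subject-level statistics: the lesion,
perilesional tissue (within 10 mm of the lesion boundary), and remaining
remote tissue of the lesioned (left) hemisphere, plus their homologues in
the non-lesioned hemisphere obtained by sagittal reflection. All ROIs are
restricted to grey matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = ["RoiSet", "perilesional_mask", "homologue_mask", "build_roi_set"]


@dataclass
class RoiSet:
    """The six tissue-compartment masks plus the perilesional radius used.

    Left-side ROIs partition left-hemisphere grey matter; each homologue is
    the sagittal reflection of its source confined to the right hemisphere.
    """

    lesion: np.ndarray
    perilesional: np.ndarray
    remote_left: np.ndarray
    lesion_homologue: np.ndarray
    perilesional_homologue: np.ndarray
    remote_right: np.ndarray
    radius_mm: float

    LABELS = (
        "lesion",
        "perilesional",
        "remote_left",
        "lesion_homologue",
        "perilesional_homologue",
        "remote_right",
    )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {label: getattr(self, label) for label in self.LABELS}


def perilesional_mask(
    lesion: np.ndarray,
    brain: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    radius_mm: float = 10.0,
) -> np.ndarray:
    """Brain voxels whose centre lies within ``radius_mm`` (inclusive) of
    any lesion voxel centre, minus the lesion itself.

    Distance is centre-to-centre Euclidean in millimetres (anisotropic
    voxels handled via the sampling argument of the exact distance
    transform).
    """
    lesion = np.asarray(lesion, dtype=bool)
    brain = np.asarray(brain, dtype=bool)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    dist = distance_transform_edt(~lesion, sampling=voxel_size_mm)
    return (dist <= radius_mm) & brain & ~lesion


def homologue_mask(
    mask: np.ndarray,
    midline_index: float,
    axis: int = 0,
) -> np.ndarray:
    """Reflection of a mask about the sagittal midline plane.

    ``midline_index`` may be half-integer (even grid: the plane lies
    between two voxel columns). Voxels mapping outside the grid are
    dropped; voxels lying exactly on an integer midline plane map to
    themselves, with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.shape[axis]
    if float(midline_index) == (n - 1) / 2.0:
        out = np.flip(mask, axis=axis)
    else:
        out = np.zeros_like(mask)
        idx = list(np.nonzero(mask))
        dst = np.round(2.0 * midline_index - idx[axis]).astype(int)
        keep = (dst >= 0) & (dst < n)
        idx = [i[keep] for i in idx]
        idx[axis] = dst[keep]
        out[tuple(idx)] = True
    if float(midline_index).is_integer():
        on_plane = np.take(mask, int(midline_index), axis=axis)
        if on_plane.any():
            warnings.warn(
                "mask overlaps the midline plane; on-plane voxels map to "
                "themselves",
                stacklevel=2,
            )
    return out


def build_roi_set(
    lesion: np.ndarray,
    gm: np.ndarray,
    left_hemi: np.ndarray,
    right_hemi: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    radius_mm: float = 10.0,
    midline_index: float | None = None,
    axis: int = 0,
) -> RoiSet:
    """Construct the six tissue compartments from lesion and hemisphere
    geometry, all intersected with grey matter.

    ``remote_left`` is left-hemisphere grey matter minus lesion and
    perilesional tissue; homologues are sagittal reflections confined to
    the right hemisphere.
    """
    lesion = np.asarray(lesion, dtype=bool)
    gm = np.asarray(gm, dtype=bool)
    left_hemi = np.asarray(left_hemi, dtype=bool)
    right_hemi = np.asarray(right_hemi, dtype=bool)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    if np.any(lesion & right_hemi):
        raise ValueError("lesion extends into the right hemisphere")
    if midline_index is None:
        midline_index = (lesion.shape[axis] - 1) / 2.0

    brain = left_hemi | right_hemi
    peri = perilesional_mask(lesion, brain, voxel_size_mm, radius_mm)

    lesion_roi = lesion & gm
    peri_roi = peri & gm & left_hemi
    remote_left = left_hemi & gm & ~lesion & ~peri

    lesion_hom = homologue_mask(lesion_roi, midline_index, axis) & right_hemi & gm
    peri_hom = homologue_mask(peri_roi, midline_index, axis) & right_hemi & gm
    remote_right = right_hemi & gm & ~lesion_hom & ~peri_hom

    if not (peri & gm).any():
        warnings.warn("no grey matter within the perilesional shell", stacklevel=2)
    return RoiSet(
        lesion=lesion_roi,
        perilesional=peri_roi,
        remote_left=remote_left,
        lesion_homologue=lesion_hom,
        perilesional_homologue=peri_hom,
        remote_right=remote_right,
        radius_mm=float(radius_mm),
    )
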