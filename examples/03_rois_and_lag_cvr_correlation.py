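"""Build the six lesion-anchored ROIs and test the lag-CVR association.

Runs a small cohort of breath-hold phantoms whose lag and CVR fields are
drawn independently, computes the subject-level voxelwise Spearman
correlation between the two maps inside each tissue compartment, and tests
the per-ROI correlations against zero with a Wilcoxon signed-rank test at
the Bonferroni-corrected alpha (0.05 / 6 ROIs = 0.0083).
"""

import numpy as np

import lagcvr as lc

anatomy = lc.make_phantom_anatomy()
paradigm = lc.default_paradigm()
roi_set = lc.build_roi_set(
    anatomy.lesion_mask, anatomy.gm_mask,
    anatomy.left_hemi_mask, anatomy.right_hemi_mask,
    anatomy.voxel_size_mm,
)
print("ROI sizes (voxels):",
      {label: int(mask.sum()) for label, mask in roi_set.as_dict().items()})

r_by_roi = {label: [] for label in roi_set.LABELS}
for subject in range(8):
    truth = lc.make_ground_truth(anatomy, noise_sd=10.0 / 3.0,
                                 seed=300 + subject)
    co2 = lc.simulate_co2_trace(paradigm, seed=300 + subject)
    bold = lc.simulate_bh_bold(anatomy, truth, co2, paradigm)
    ref = lc.reference_timeseries(bold, anatomy.gm_mask,
                                  exclude_mask=anatomy.lesion_mask)
    lag = lc.compute_lag_map(bold, ref)
    peak_t, peak_v = lc.end_tidal_detect(co2)
    etco2 = lc.end_tidal_interpolate(peak_t, peak_v, bold.n_frames * bold.tr)
    base = lc.petco2_baseline(peak_t, peak_v, paradigm.hold_windows()[0, 0])
    cvr = lc.compute_cvr_map(bold, etco2, base)
    for label, mask in roi_set.as_dict().items():
        res = lc.stats.roi_spearman(lag, cvr, mask)
        if res.ok:
            r_by_roi[label].append(res.r)

alpha = lc.stats.bonferroni_alpha(0.05, 6)
print(f"per-ROI Wilcoxon vs 0 at alpha = {alpha:.4f}:")
for label, values in r_by_roi.items():
    if len(values) >= 6:
        p, sig = lc.stats.group_wilcoxon_vs_zero(np.asarray(values), alpha)
        print(f"  {label:24s} mean r = {np.mean(values):+.3f}  "
              f"p = {p:.3f}  significant = {sig}")
    else:
        print(f"  {label:24s} mean r = {np.mean(values):+.3f}  "
              f"(too few subjects with enough voxels)")
# Because lag and CVR were injected independently, the mean correlations
# hover near zero and no compartment reaches the corrected threshold —
# the calibrated null behaviour of the association test.
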