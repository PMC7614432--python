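"""Simulate a resting-state phantom and map voxelwise haemodynamic lag.

Builds the default 20x20x10 phantom (2 mm voxels, TR 2 s, 150 frames) with
a known voxelwise lag field, derives the grey-matter reference signal with
the lesion excluded, runs the +/-4 TR cross-correlation search with
parabolic peak refinement, and compares the recovered lags with the
injected ones.
"""

import numpy as np

import lagcvr as lc

anatomy = lc.make_phantom_anatomy()
truth = lc.make_ground_truth(anatomy, noise_sd=10.0 / 3.0, seed=1)
bold = lc.simulate_rest_bold(anatomy, truth)

reference = lc.reference_timeseries(bold, anatomy.gm_mask,
                                    exclude_mask=anatomy.lesion_mask)
lag = lc.compute_lag_map(bold, reference)

carrying = anatomy.gm_mask & lag.valid & (truth.amplitude_field > 0)
err = lag.lag_s[carrying] - truth.lag_field[carrying]
hemi = lc.hemisphere_mean_lag(lag, anatomy.left_hemi_mask & anatomy.gm_mask)

print(f"grey-matter voxels mapped : {int(lag.valid[anatomy.gm_mask].sum())} "
      f"of {int(anatomy.gm_mask.sum())}")
print(f"lag recovery RMSE         : {np.sqrt(np.mean(err**2)):.3f} s")
print(f"lesioned-hemisphere mean  : {hemi:+.3f} s")
# The RMSE shows how closely the cross-correlation + parabolic-interpolation
# chain recovers the injected per-voxel timing offsets at SNR ~3; the
# hemisphere mean is the summary the longitudinal comparison uses.
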