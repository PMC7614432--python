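# lagcvr

Voxelwise haemodynamic lag and breath-hold cerebrovascular reactivity (CVR)
mapping for post-stroke fMRI, with synthetic phantoms that make every stage
of the measurement chain testable against known ground truth.

## The problem

After a stroke, the BOLD signal of surviving tissue can be *delayed*
relative to the rest of the brain, and its vasodilatory capacity can be
blunted. Two voxelwise measurements capture this:

- **Haemodynamic lag.** Each voxel's timecourse `v(t)` is compared with a
  grey-matter reference signal `s(t)` (the mean grey-matter timecourse with
  the lesion excluded) at integer-TR shifts `k ∈ [−4, +4]` (±8 s at
  TR = 2 s, nine positions):

      r(k) = corr( v(t), s(t − k·TR) )

  The maximum of `r(k)` and its two neighbours are fitted with a parabola;
  the vertex abscissa is the voxel's lag in seconds
  (`offset = ½ (r[m−1] − r[m+1]) / (r[m−1] − 2 r[m] + r[m+1])`,
  `lag = (m + offset)·TR`). Positive lag means the voxel trails the
  reference; voxels whose best correlation stays below 0.1 are excluded.

- **Breath-hold CVR.** End-tidal CO₂ points (expiratory peaks of the
  capnograph) are linearly interpolated, the deviation from the resting
  baseline is convolved with a canonical double-gamma HRF, and the
  resulting regressor `x(t − δ)` is fitted per voxel over an exhaustive
  delay grid `δ ∈ [−15, +15]` s in 0.1 s steps. At the correlation-maximal
  delay, the GLM `v = β₀ + β·x` yields

      CVR = 100 · β / β₀   [%BOLD / mmHg]

The package also builds the six lesion-anchored tissue compartments
(lesion, perilesional within 10 mm, remote; plus their mirror homologues),
and provides the statistical surface used on such cohorts: per-ROI
voxelwise Spearman correlation of lag and CVR with Wilcoxon signed-rank
group inference (Bonferroni α = 0.05/6 = 0.0083), spatial Pearson
correlation of lag maps across conditions, one-tailed paired t-tests on
hemisphere mean lag, and a voxelwise two-factor OLS ANOVA with
Benjamini–Hochberg FDR (q = 0.1).

Because no patient data ship with the package, the `synth` module generates
4D phantoms with known lag, CVR and delay fields — band-limited
(0.01–0.1 Hz) shared resting fluctuations with voxelwise temporal offsets,
HRF-convolved CO₂ responses with voxelwise arrival delays, CSF confounds,
and motion traces with outlier frames — so recovery and calibration are
verifiable end to end.

## Worked example

`examples/01_phantom_and_lag_map.py` simulates a resting phantom at
per-voxel SNR ≈ 3 and maps lag against the lesion-excluded grey-matter
reference:

```text
grey-matter voxels mapped : 1402 of 1424
lag recovery RMSE         : 0.089 s
lesioned-hemisphere mean  : -0.005 s
```

The RMSE says the cross-correlation + parabolic-interpolation chain
recovers the injected per-voxel timing offsets to better than a tenth of a
second — well below the 2 s sampling interval. The unmapped voxels are the
signal-void lesion. `examples/02_breath_hold_cvr.py` does the same for
CVR on a noise-free breath-hold phantom:

```text
end-tidal peaks detected  : 54 (baseline 40.0 mmHg)
CVR relative RMSE         : 5.32e-14 %
largest delay error       : 0.00 s
mean CVR in grey matter   : 0.250 %BOLD/mmHg
```

i.e. the estimator returns the injected reactivity to machine precision
and every CO₂ arrival delay lands on the correct 0.1 s search step. The
remaining examples exercise the ROI statistics (independent lag/CVR fields
give near-zero correlations that never pass the corrected threshold) and
the group ANOVA (a +0.5 s group offset region is flagged in full after FDR
while false positives stay at the q level).

A thin CLI mirrors the pipeline stages for shell use:

```bash
lagcvr simulate --kind bh --out phantom/ --seed 1
lagcvr lagmap --bold phantom/bold.nii.gz --gm-mask phantom/gm_mask.nii.gz \
       --lesion-mask phantom/lesion_mask.nii.gz --out maps/
lagcvr run-subject --config subject.json
```

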