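# Methods

This note documents the models, parameter choices and numerical decisions
behind `lagcvr`, and what the phantom-based validation does and does not
establish about real data.

## Preprocessing

Framewise displacement (FD) is the Power-style sum of absolute backward
differences of the six rigid-body parameters, with rotations converted to
arc length on a 50 mm sphere; the first frame is 0 by definition. A frame
is censored when FD strictly exceeds 1 mm, and a scan is discarded when
more than half its frames are censored (both boundaries are kept: the
rules are strict inequalities). Censored frames are retained in the array
but excluded from every estimation step, so shift indexing downstream
remains aligned with acquisition time.

Nuisance removal regresses each voxel on an intercept, the six motion
parameters and the mean CSF timecourse over valid frames, keeps the
residuals and adds the voxel mean back (baseline units are needed later
for %BOLD normalisation). The high-pass is realised as regression on a
discrete-cosine drift basis containing every DCT-II component with
frequency strictly below the 0.01 Hz cutoff (five components for a 300 s
scan). A cosine basis was chosen over a recursive filter because it is
exactly linear, handles censored frames cleanly (the basis is evaluated
per frame and fitted on valid frames only), and its attenuation is easy to
characterise: a sinusoid at cutoff/4 keeps < 10% of its amplitude, one at
5x the cutoff keeps > 95% (amplitude measured as sqrt(2) x RMS; the
maximum residual additionally contains edge ringing inherent to any
finite-window drift fit). The fixed stage order is FD → flagging →
nuisance regression → high-pass.

## Lag mapping

The reference is the frame-wise mean over grey-matter voxels after
excluding the lesion. Per voxel, Pearson correlations are computed at
integer shifts k ∈ [−K, K] (K = 4) between the voxel at frame t and the
reference at frame t − k, over frame pairs where both frames are valid
(minimum 10 pairs per shift; shifts with fewer pairs are flagged, and a
flagged shift at or next to the argmax invalidates the parabolic fit for
that voxel rather than silently shrinking it). Positive lag = the voxel
trails the reference.

Validity requires the maximum integer-shift correlation to reach 0.1; the
maximum (rather than the zero-shift value) is used so a voxel that is well
correlated only at a non-zero shift remains mappable. The sub-sample peak
is the vertex of the parabola through the argmax and its two neighbours.
Numerical edge cases: an argmax at the grid boundary is clamped to ±K·TR
and flagged (extrapolating beyond the searched range would invent lags
outside ±8 s); a flat plateau at the maximum has no unique vertex and
returns the argmax shift with a degeneracy flag; a peak correlation of
exactly 1 (the voxel is an affine copy of the shifted reference) is
returned unrefined, since a correlation of 1 cannot be improved and the
vertex of a parabola through (r, 1, r') would lie above 1.

With 150 frames, a pure-noise voxel's maximum correlation over the nine
shifts exceeds 0.1 about two thirds of the time (the null standard
deviation of a single correlation is 1/sqrt(148) ≈ 0.08), so the r ≥ 0.1
rule thins but does not eliminate unmappable voxels at this scan length —
recovery statistics are therefore evaluated over voxels that actually
carry the shared signal.

## CVR mapping

End-tidal points are the expiratory peaks of the capnograph (local maxima
at least 2 s apart with at least 1 mmHg prominence; the flat trace during
a hold contributes none). They are linearly interpolated onto a 0.1 s
grid with constant extrapolation at the ends. The resting baseline is the
median of the end-tidal points recorded before the first hold. The
deviation from baseline is convolved with a double-gamma HRF — two
gamma-shaped lobes `(t/m)^m e^(m−t)` with modes at 6 s (response) and 16 s
(undershoot), undershoot ratio 1:6, 32 s support, unit peak — on the fine
grid.

Per voxel, the regressor is shifted over δ ∈ [−15, +15] s in 0.1 s steps
(positive δ = later arrival) and the delay maximising the voxel–regressor
Pearson correlation is kept; for a single-regressor OLS this is the same
delay that minimises the residual sum of squares. Exact ties break toward
the smallest |δ|, then toward the negative one, for determinism. CVR is
100·β/β₀ with β₀ the fitted intercept — using the intercept rather than
the raw voxel mean makes the %BOLD normalisation exact even though the
regressor has non-zero mean. Voxels with best-fit correlation below 0.1
(abnormal breath-hold response) or degenerate fits are invalid. The GLM is
intercept-only by design; the preprocessing high-pass has already removed
drifts, and optional cosine drift columns can be added through the
preprocessing module if data arrive unfiltered.

## ROI geometry

Perilesional tissue is every brain voxel whose centre lies within 10 mm
(inclusive) of a lesion-voxel centre, lesion excluded; distances are
centre-to-centre Euclidean in millimetres via an exact distance transform,
so anisotropic voxels are handled. Homologues are sagittal reflections
about the grid's midline plane, confined to the right hemisphere. All six
compartments are intersected with grey matter, and the perilesional
compartment is additionally confined to the left hemisphere so that
{lesion, perilesional, remote} partitions left-hemisphere grey matter and
the three right-side ROIs partition the right.

## Statistics

- **Lag–CVR association:** per subject and ROI, Spearman rank correlation
  (average ranks on ties) over the jointly valid voxels (lag-valid ∧
  cvr-valid ∧ ROI; at least 10). Group inference is a two-sided Wilcoxon
  signed-rank test of the per-subject correlations against zero — exact
  null distribution for n ≤ 25 when the absolute values are tie-free,
  continuity-corrected normal approximation otherwise; zeros dropped — at
  the Bonferroni-corrected per-ROI alpha 0.05/6 = 0.0083.
- **Cross-condition consistency:** spatial Pearson correlation of two lag
  maps over jointly valid masked voxels.
- **Longitudinal change:** one-tailed paired t-test on hemisphere mean
  lag; t = 0 gives p = 0.5, and an exactly constant non-zero difference is
  reported as the infinite-t limit (0 or 1 by direction).
- **Group maps:** voxelwise OLS ANOVA of lag on effect-coded group,
  timepoint and their interaction (cell-means OLS; no random-effects
  machinery), F-tests per term by full-vs-reduced model comparison.
  Voxels valid in at least 80% of subjects form the analysis mask; within
  it each voxel is fitted on the subjects valid there (voxels grouped by
  missingness pattern; rank-deficient patterns are dropped). When a voxel
  fits perfectly (identical data within cells) the F statistic is defined
  as 0 with p = 1. Benjamini–Hochberg FDR at q = 0.1 per term, with NaN
  p-values never rejected.

## The phantom generator

The phantom is the package's study condition, not a tuning knob. Defaults:
20x20x10 voxels at 2 mm isotropic, TR 2 s, 150 frames (~300 s); an
ellipsoidal brain split into symmetric hemispheres, a small central CSF
core, and a 4 mm-radius spherical lesion in the left hemisphere (33
voxels). All signals are synthesised on a 0.1 s grid before resampling at
TR, so fractional-second lags and delays are representable at exactly the
resolution of the CVR delay search.

- The shared resting signal is white noise top-hat filtered to
  0.01–0.1 Hz in the frequency domain and standardised; each voxel
  receives it shifted by its lag τ_v, scaled by coupling a_v (default 1%
  of baseline) on a baseline B_v (1000 ± 10% raw units). CSF voxels carry
  an independent band-limited confound instead.
- Lags are uniform on ±2 s (mean |lag| ≈ 1 s, the scale observed in
  stroke cohorts); CO2 arrival delays uniform on ±8 s; CVR uniform on
  0.1–0.4 %BOLD/mmHg in grey matter. The lesion defaults to a signal
  void (a = 0, CVR = 0), reflecting suppressed reactivity in infarcted
  tissue; this is configurable.
- The capnograph oscillates at the respiratory rate (0.25 Hz) between an
  inspiratory trough and the end-tidal envelope: 40 mmHg at rest, flat at
  the trough during each 15 s hold (no expirations), then a first
  post-hold expiratory peak at 48 mmHg relaxing exponentially back to
  baseline with a 10 s time constant. The respiratory phase restarts at
  each hold end, as breathing resumes from the trough. Only the end-tidal
  peaks matter downstream; the within-breath waveform is cosmetic.
- The breath-hold BOLD forward model uses the same end-tidal detection,
  interpolation and HRF convolution operators as the estimator, so
  noise-free recovery of CVR and delay is exact by construction — that
  closure validates the estimator's bookkeeping (shifting, sampling,
  normalisation), while the noisy configurations probe its robustness.
- "SNR ≈ 3" means white noise with SD = (signal SD)/3 = 10/3 raw units on
  top of the 1% coupling.
- Motion traces are sums of slow sinusoids (0.05 mm translations, the
  arc-length equivalent for rotations) with optional single-frame
  translation spikes.

What the phantoms do *not* emulate: spatially structured vascular
territories, cardiac/respiratory aliasing, susceptibility dropout,
imperfect coregistration, or task non-compliance. Passing recovery tests
therefore demonstrates the correctness and calibration of the estimation
chain under its stated model, not performance on any particular clinical
dataset.

## Validation experiments and problem sizes

`lagcvr.validation` holds the standing experiments the test suite and the
acceptance script run: exact integer-TR lag recovery (whole-TR shifts
injected into a region excluded from the reference), lag RMSE at SNR ≈ 3
on the default phantom, CVR/delay recovery noise-free and at SNR ≈ 3, the
null calibration of the lag–CVR pipeline (20 subjects x 200 replicate
cohorts of independent fields; group-mean r and Wilcoxon type-I rate at
α = 0.0083), a 1000-triple parabolic-vertex oracle comparison against an
independent quadratic fit, and group-ANOVA power (ten 2x2 cohorts, five
subjects per cell, +0.5 s offset against 0.1 s between-subject noise)
plus a KS uniformity check of null p-values. These sizes keep the whole
battery at desk scale — the full suite and the acceptance script each run
in well under a minute — while leaving every measured margin wide.

## Known limitations

- The r ≥ 0.1 validity rule is weakly specific at 150 frames (see above);
  longer scans sharpen it.
- Boundary lags are clamped at ±8 s, so true lags beyond the search range
  are censored, not estimated.
- The ANOVA treats timepoint as a between-voxel OLS factor (no subject
  random effect); its p-values are calibrated for the phantom's
  independent-error model.
- The Wilcoxon exact path requires tie-free absolute values; tied inputs
  fall back to the corrected normal approximation even at small n.
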