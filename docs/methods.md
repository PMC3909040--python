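# Methods

## The generative model behind the phantom

Every brain voxel time series in a simulated run is a linear mixture of
three mutually independent, zero-mean, unit-variance components:

    x_v(t) = a_v · s(t) + b_v · c(t) + σ_e · ε_v(t)

where `s` is the midbrain seed signal, `c` a physiological confound shared
across the run, and `ε_v` voxel-specific noise. All three are generated by
masking the DFT of white Gaussian noise to the bins inside the analysis
band (0.009–0.08 Hz at the run's length and TR) and inverting, then
re-standardizing. This gives exact spectral control with no filter
transients, and it makes the temporal band-pass stage of preprocessing
approximately variance-neutral on synthetic data — deliberately so, since
otherwise filtering broadband noise would inflate every planted
correlation by a band-dependent factor and no closed-form oracle would
hold after preprocessing.

Under this model the population Pearson correlation between `s` and `x_v`
is

    ρ = a σ_s / sqrt(a² σ_s² + b² σ_c² + σ_e²),

implemented as `planted_correlation`; `coupling_for_correlation` inverts
it for `a`. The simulator plants an exact per-cell correlation for the
"dopaminergic" caudate voxels by solving `a` separately for each of the
four drug-by-span design cells. The sample Fisher z of a band-limited
series pair is biased upward by roughly ρ/(2·n_eff), where n_eff ≈ n ·
(band width / Nyquist) ≈ 43 at 150 timepoints — about +0.008 at ρ = 0.6,
well inside the ±0.03 recovery tolerance used in validation.

### Spatial layout of the planted effect

The caudate (208 voxels: 112 head/body anterior to world y = 2 mm, 96
tail) is partitioned into three classes by whole coronal slices: a
central contiguous slab gets the inverted-U pattern (the number of slices
closest to `frac_dopaminergic` of the caudate; 48 voxels at the default
0.25), a shell of up to two slices on each side is connected to the seed
at a constant level in every cell (`r_constant` = 0.3), and the rest is
null (confound + noise only). The slab is contiguous rather than
scattered because a dopaminergic territory is spatially compact in real
anatomy, and because a compact effect behaves sensibly under the 4-mm
smoothing kernel and the 20-voxel cluster-extent threshold. The
constant-connectivity shell plays the role of ordinary
(non-drug-modulated) midbrain-coupled striatum between the planted effect
and the null voxels; putamen and ventral striatum carry the same constant
coupling. White matter and CSF voxels carry the confound (plus 30%
noise), midbrain seed voxels the seed signal (plus 10% noise), and
other-brain voxels pure noise.

### Default study conditions

16 subjects (8 low span, 8 high span; scores uniform on [1.5, 3.4] and
[3.5, 5.5] around the inclusive 3.5 cutoff — only the cutoff and the 8/8
split are given, the score distribution is this package's choice), two
counterbalanced sessions (placebo, bromocriptine), 150 timepoints at
TR = 2 s, voxels 1.8 × 1.8 × 3.45 mm, default planted cell correlations
(0.1, 0.5, 0.5, 0.1), noise σ_e = 1, confound weight b = 0.5. The phantom
grid is 18 × 24 × 10 (2,816 brain voxels) — large enough to carry the
caudate/putamen/ventral-striatum/nuisance geometry and thousands of null
voxels for calibration, small enough that a full 32-run cohort analysis
takes a few seconds, which is what makes the 20-replicate validation
studies routine. Randomness flows from a single required seed; each
subject-session draws a child generator keyed by a CRC32 of its
identifiers, so cohorts are bit-reproducible and runs are independent.

## Preprocessing decisions

- **Filter**: 2nd-order Butterworth band-pass applied forward–backward
  (`sosfiltfilt`), i.e. zero phase and an effective 4th-order magnitude
  response. Each series is mean- and linear-trend-removed first to
  suppress edge transients on 150-point series.
- **Smoothing**: per-axis sigma = FWHM / (voxel size · 2√(2 ln 2)) so an
  isotropic 4-mm FWHM is honored on anisotropic voxels; boundary mode is
  reflection (configurable). FWHM 0 is an exact identity.
- **Nuisance regression**: white-matter and CSF mean series plus an
  intercept, extracted from the *filtered and smoothed* data, removed by
  ordinary least squares; residuals are orthogonal to the regressors as
  they appear in the data entering correlation. Whether nuisance series
  should be extracted before or after filtering is genuinely open; this
  package extracts them after, so the regressors live in the same band as
  the data they clean.
- Pipeline order: filter → smooth → regress. Because regression removes
  the confound that `planted_correlation` counts in its denominator, the
  post-preprocessing correlations sit above the planted raw values; the
  inverted-U *pattern* across cells is preserved (the transformation is
  monotone), which is what the group statistics consume. Closed-form
  recovery checks are therefore run on raw simulated series.

## Group statistics

The design crosses a within-subject factor (drug) with a between-subject
factor (span group). The quadratic contrast (−0.5, 0.5, 0.5, −0.5) on the
four cell means equals (mean d_low − mean d_high)/2 where d = z(drug) −
z(placebo), so the interaction is tested exactly as a pooled two-sample t
on the per-subject paired differences, df = n_low + n_high − 2 — the
likelihood-equivalent test for this mixed design that avoids choosing an
ANOVA sum-of-squares convention. Positive t means the inverted-U pattern.
All p-values are two-tailed by default.

The overall-connectivity map is a one-sample t across all subject-session
maps treated as independent observations (32 at the default design); this
overstates the effective sample because sessions share subjects, so a
`subject_mean` variant that averages within subject first is available.

FDR is Benjamini–Hochberg (step-up, independence variant); degenerate
(zero-variance) voxels carry no p-value and are excluded from m. The
small-volume threshold runs BH over the p-values inside an anatomical
mask, then removes connected components smaller than the cluster
threshold (face connectivity 6 by default; 18 and 26 available).
Correlations of exactly ±1 are clamped to 1 − 1e-7 before the Fisher
transform (with a warning) or invalidated, per the clamp flag.

Two printed statistics from the source analysis are *not* exactly
reproduced by the standard formulas implemented here, and no attempt is
made to force agreement: the independent-samples Fisher comparison of
r = 0.66 and r = −0.69 at n = 16 gives Z = 4.183 (4.14 was printed;
the original recipe — possibly a dependent-correlations test or a
different n — is not recoverable), and the two-tailed p for r = 0.66 at
n = 16 is 0.0054 (0.003 was printed, closer to one-tailed).

## Overlap analysis

Integer overlap percentages use round-half-away-from-zero, which matches
122/955 → 13 and 4/28 → 14. "Anterior to the coronal plane at y = 2 mm"
is interpreted strictly: world y > 2 → head/body, voxels exactly on the
boundary go to the tail (both the boundary and the rule are
configurable). The regional proportion test is the 2×2 Pearson chi-square
without continuity correction (counts at this scale are large; a Yates
flag exists). In the pipeline's Venn analysis, set A is the caudate
voxels with significant overall connectivity (FDR, small volume) and set
B the inverted-U voxels at the uncorrected threshold; the regional
chi-square compares |A∩B| vs |A\B| between head/body and tail, a
definition chosen here since the original regional counts appear only in
figure graphics.

## What the synthetic validation does and does not show

The phantom validates the *inference machinery*: that planted
correlations are recovered at their closed-form Fisher-z values, that the
interaction contrast is calibrated under a null effect (uncorrected
rejection ≈ 5%, FDR small-volume sets empty), and that a planted
inverted-U territory is recovered with high sensitivity and few false
positives among truly null voxels. It does not emulate hemodynamic
response shapes, head motion, scanner drift or physiological noise
spectra, spatial normalization error, or anatomical variability — so
passing these checks says the statistics behave as designed, not that the
preprocessing would suffice on real scanner data. Sessions are
exchangeable in the generator (no order or practice effects), and the
confound couples uniformly within a run.

## Validation study sizes

The packaged validation routines use: 200 simulated runs for the
planted-z recovery, 20 seeded cohort replicates for the null calibration
(pooling ≈ 55,000 gray-voxel tests for the uncorrected rate), and 20
seeded replicates for the parameter-recovery study. These sizes put the
Monte-Carlo standard error comfortably below the tolerances they are
checked against while keeping a full validation pass in the
few-minutes range.
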