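# Methods

`segflow` re-creates, as a tested library, the analysis chain used to study
brain dynamics at musical event boundaries in naturalistic fMRI: a
continuous boundary-salience regressor derived from listeners' real-time
segmentation, a lagged voxelwise GLM, group spatial ICA with subject-level
back-reconstruction, and difference-of-influence Granger causality, with
nonparametric group inference throughout. Because the original fMRI
recordings are access-restricted, every stage is validated on synthetic 4-D
data whose generating truth is planted and known.

## Boundary-salience regressor

Listeners mark "instants of significant change" while the music plays.  The
marker times of all participants are pooled and smoothed with a Gaussian
kernel (bandwidth 2 s by default — one TR; configurable) on a fine grid
(0.1 s step), giving a density in participations-per-second.  The density is
deliberately *unnormalised*: it integrates to the total marker count, so
peak height directly measures inter-listener consensus and remains
comparable across stimuli with different marker counts (a normalised variant
is a one-line rescale).  Pooling is across both participant groups by
default, with a per-group option.

The scan-grid regressor is the density linearly interpolated at frame onsets
(`t = i * TR`, 0-based).  Lagged copies shift by whole scans with zero fill
(`out[i] = x[i - lag]`; positive lag models post-boundary response), and the
design columns are convolved with a canonical double-gamma HRF (positive
lobe near 5-6 s, undershoot near 15-16 s, sampled at TR, unit peak).  An
identity-HRF option exists because several unit tests need the convolution
to be invisible; whether the original analysis convolved the regressor is
not stated in the main text, so convolution is the default and a flag turns
it off.

The loudness confound is the per-scan RMS of the stimulus waveform
(rectangular windows of one TR).  `check_confound` reports Pearson and
Spearman associations between regressor and RMS; the study design expects
these to be small.

## Synthetic data generator

The generator emulates the study conditions rather than anatomical realism:

- **Markers.**  Each of the 2 x `n_subjects_per_group` listeners marks
  boundary *k* with probability equal to its salience (in (0,1]), at the
  true time plus Gaussian jitter (SD 0.5 s), plus uniformly-timed false
  alarms at 0.5 events/min.  Defaults: 12+12 subjects at desk scale (the
  full study's 18+18 by config), 150 scans at TR = 2 s, boundaries every
  ~25 s with a 20 s post-boundary tail.
- **Loudness.**  A temporally smoothed noise series is orthogonalised
  against the true salience regressor and remixed to hit a target
  correlation exactly (default 0.05, matching the observed near-zero
  association), then shifted into a strictly positive range.
- **Networks.**  Two disjoint 3-D Gaussian blobs (sigma 2 voxels,
  thresholded at 1% of peak, non-overlapping above half maximum) on a
  20x20x10 grid.  The *early* network loads the HRF-convolved regressor at
  lag -1 with weight 1; the *transition* network at lags 0 and +1 with
  weights 1 and 0.8.  Musicians' lag weights are scaled by 1.5 (a scalar
  gain is the simplest mechanism that yields detectable group-difference
  maps).
- **Coupling.**  Network time courses are signal + white innovation noise
  (innovation SD = signal SD / SNR); the transition network additionally
  receives 0.4 x the early network's previous sample — a unidirectional
  VAR(1) cross-term.  Nothing ever feeds back from transition to early.
- **Voxel data.**  map x time course, plus a 0.5 share of the RMS series in
  every in-mask voxel, plus AR(1) Gaussian noise (phi = 0.3, unit marginal
  SD, spatially independent) scaled so in-network signal SD / noise SD
  equals the target SNR (default 1).

All draws flow from a single seed through named substreams
(markers/rms/timecourses/noise, the last two keyed per subject), so identical
configurations are bit-reproducible.

What the generator does *not* emulate — anatomy, motion, physiological
noise, spatially correlated noise, genre structure — bounds what green tests
mean: they certify the statistical machinery (recovery, calibration, error
control) under the stated noise model, not performance on real scanner data.

## GLM stage

The RMS series is regressed out of every in-mask voxel (OLS on intercept +
confound); residuals are exactly orthogonal to the confound.  When the data
have been residualised, the same series should also be passed to
`fit_subject_glm` as a nuisance design column: by the Frisch-Waugh theorem
that is equivalent to residualising both sides, whereas residualising the
data alone leaves the confound's share inside the design columns and biases
the lag betas — noticeably so here, because the smooth RMS correlates with
the HRF-convolved lag regressors far more than with the raw salience
series.  The pipeline always passes it.  The lagged GLM
fits all three lag columns jointly by default — the lagged regressors share
variance, and a joint fit splits it by least squares instead of counting it
three times; a per-lag mode exists for comparison.  Per voxel and lag the
fit yields beta, t, and the one-sided pair (p_pos, p_neg) with
p_pos + p_neg = 1.

Group pooling uses Fisher's combined-probability test, -2 Σ ln p ~
chi-square(2k), applied separately to the activation and deactivation
one-sided maps so the two directions never cancel.  Lag contrasts use
two-sample Wilcoxon rank-sum tests voxelwise (as printed in the source
analysis, although lags are paired within subject; a paired signed-rank
variant sits behind `paired=True`).  Group contrasts are rank-sum between
musicians and nonmusicians.  Spearman rank correlation per voxel is the
assumption-free alternative association.

## Nonparametric inference

- **Exact rank tests.**  Signed-rank: exact null for n <= 25 by
  generating-function convolution over doubled mid-ranks (doubling makes
  tied mid-ranks integral); beyond that, a tie-corrected normal
  approximation with continuity correction.  Rank-sum: exact null by
  dynamic programming when tie-free (cached per (n1, n2) so voxelwise maps
  reuse one distribution), full enumeration for tied inputs up to
  C(n, n1) <= 2e5, normal approximation otherwise.  Two-sided p is twice
  the smaller tail, capped at 1; fully tied inputs give p = 1 and a zero
  statistic.
- **Cluster-extent FWE.**  Voxels beyond a parametric-t forming threshold
  (default two-sided p < 0.001) are labelled into 26-connected components,
  positive and negative excursions separately.  The null of the *maximum*
  extent is built by sign-flipping subjects (one-sample) or shuffling group
  labels (two-sample); corrected p uses the add-one estimator
  (1 + #{max >= extent}) / (n_perm + 1), so no cluster gets p = 0.  Sign
  flips exploit the fact that squared values are flip-invariant, so the
  permuted t maps are computed from precomputed sums of squares — 500
  permutations on a 20x20x10 grid take well under a second.
- **FDR.**  Benjamini-Hochberg step-up via statsmodels.
- **Lag-map clustering.**  Pairwise distance 1 - Pearson over in-mask
  voxels, average linkage by default (the source analysis names neither the
  linkage nor the distance; complete linkage is available).

## Group spatial ICA and GICA3

Reduction is the standard two-step temporal-concatenation scheme: per
subject, PCA of the time dimension to `subject_dim`; concatenation of the
reduced data across subjects; group PCA to `group_dim`.  Spatial ICA runs
FastICA with voxels as samples, so sources are spatially independent maps.
The log-cosh contrast is the default; the *deflationary* fixed-point update
is used rather than the symmetric one because, after whitening, everything
beyond the few genuinely non-Gaussian dimensions is near-Gaussian noise in
which the symmetric update rotates indefinitely without meeting its
convergence criterion, while deflation extracts components one at a time
and converges in a handful of iterations (recovering planted maps at
|r| > 0.98).  Fits are deterministic given a seed; non-convergence retries
with shifted internal seeds and then raises.  Components are sign-fixed
(peak-magnitude voxel positive) and ordered by explained variance; group
maps are z-scaled over voxels.

Since one "true" model order is unknowable, `scan_model_orders` refits over
a range (default {2, 4, 6} at desk scale), matches components across orders
greedily by absolute spatial correlation (threshold 0.7), and scores each
reference component's stability as its mean match correlation.

GICA3 back-reconstruction is algebraic, not re-estimated: with X_i the
subject-reduced data, G_i the subject's block of the group projection, W the
spatial unmixing and mu the feature means removed during ICA, the subject
map is S_i = W (M G_i' X_i - mu) for M subjects, so mean_i S_i = W (R - mu)
= S — the group map — *identically*, at machine precision, for any order and
seed.  Subject time courses are TC_i = F_i G_i A.  The z-scaling applied to
group maps is applied affinely to subject maps, preserving the identity.

**Lag profiling.**  Per component and lag, each subject's OLS beta of its IC
time course on the HRF-convolved lagged regressor is tested across subjects
with the one-sample signed-rank test.  OLS betas (not correlations) are used
so amplitude differences — the group gain — survive into group comparisons.
A component is *early* if its minimum-p lag is -1, *transition* if 0 or +1,
*unrelated* if nothing reaches alpha.  One subtlety: the exact signed-rank p
floors at 2/2^n once all subjects agree in sign, and the lagged regressors
are correlated enough (KDE + HRF smoothing) that several lags often reach
the floor together; ties at the minimum are therefore broken by the largest
absolute median beta before any positional preference, which is what lets a
genuinely lag -1-tuned component be classified "early" at realistic sample
sizes.

Group differences on subject-specific maps use voxelwise rank-sum statistics
with label-shuffle cluster correction at a forming threshold of p < 0.05
(the group-difference maps were thresholded more leniently than the main
effect maps in the source analysis; both thresholds are exposed).

## Granger difference of influence

Time courses are variance-normalised (the measure is scale-invariant; this
only stabilises OLS).  For order p, both directions are computed on the
common sample t = p..n-1:

    F_{x->y} = ln( RSS(y | own lags) / RSS(y | own + x lags) )

and symmetrically for F_{y->x}; DOI = F_{x->y} - F_{y->x} is antisymmetric
by construction.  Order is selected per subject by AIC (BIC recorded), both
computed from the bivariate VAR's residual covariance on the common sample
t = max_order..n-1 with k = 2(1 + 2p) free parameters — matching the
statsmodels VAR convention, which the tests cross-check.  Max order defaults
to 10 at TR resolution.

The group test is a one-sample signed-rank on subject DOIs against zero
(the printed "two-sample ... signed rank" naming is internally inconsistent
with one DOI per participant); direction is the sign of the median DOI when
the FDR-adjusted p clears alpha (default 1e-4), else "undetermined".  Note
the alpha floor: with n subjects the exact two-sided p cannot go below
2/2^n, so alpha = 1e-4 requires n >= 15 even with unanimous signs.

A caveat the DOI cannot remove: when the two networks have *different* lag
tuning to the stimulus, the stimulus itself creates genuine lead-lag
predictability between their time courses.  With the default planted tuning,
zero VAR coupling still yields a systematically positive DOI — correctly, as
a statement about predictability, but it means "coupling = 0" is not a
type-I null.  The calibration runs in the acceptance suite therefore use
matched lag tuning (both networks (0, 1, 0.8)), which makes the pair
exchangeable and DOI symmetric about zero; measured false-positive rates sit
inside the binomial band around the nominal 5%.

## Pipeline, formats, determinism

`run_pipeline` executes the stages in study order and emits `report.json`
(every tunable echoed, wall-clock timings stripped so identical config+seed
reproduce the file byte for byte) plus TSV/NIfTI/JSON artifacts.  Volumes
are NIfTI-1 with TR in the time-axis pixdim; tables are TSV with `%.17g`
floats and round-trip parsing; voxel indices and scan indices are 0-based,
times in seconds.  The `segflow` CLI wraps the library thinly
(simulate / regressor / glm / cluster / gca / run); exit code 2 flags
validation errors, 1 runtime failures.

## Problem sizes in the test and acceptance runs

Desk scale keeps everything on one CPU in minutes: 20x20x10 voxels
(4,000), 150 scans, 12+12 subjects for GLM/ICA recovery; 18+18 subjects and
200 scans for the Granger runs (200 replicates each for power and null);
100 null datasets x 500 permutations for FWE control; 50 seeded runs for
lag-profile classification.  These sizes were chosen as the smallest at
which the planted effects are comfortably detectable, and they are stated
here so results can be reproduced exactly.

## Known limitations

- No prewhitening in the GLM: AR(1) noise makes parametric voxel p-values
  mildly optimistic.  The group-level conclusions rest on permutation and
  rank tests, which do not inherit that optimism, and the Fisher pooling is
  validated under its own null.
- No hemodynamic deconvolution before Granger analysis (none was described
  in the source analysis); at TR = 2 s the DOI, not the raw F terms, carries
  the interpretable signal.
- The generator's noise is spatially independent; cluster-extent FWE under
  smooth noise would need the permutation scheme unchanged but would yield
  larger null clusters.
- Model-order scanning matches components greedily; a full ICASSO-style
  stability analysis is out of scope.
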