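# Methods

This note records the modelling assumptions, numerical choices and open
design decisions behind `progmod`, in the spirit of a model-description
appendix.

## Synthetic cohorts

The generator (`progmod.synthetic_cohort`) emulates a multi-centre
longitudinal study of two patient phenotypes plus controls. Each biomarker
follows a logistic transition over a latent disease-time axis,

    value(t) = healthy_mean + abnormal_shift · σ((t − onset) / (duration/6)),

so ~95% of the transition occurs within `transition_duration` years of
`onset_time`. The two groups share healthy parameters and differ only in
onset times, which define the ground-truth orderings.

Design choices and defaults:

* **Latent stage distribution.** Patients' baseline latent times are uniform
  over `latent_time_range` (default −8 to +12 years), so a cross-section
  spans the disease course — the assumption both the EBM and the DEM rely
  on. Controls sit at a fixed pre-onset time (earliest onset minus the
  longest transition), where all biomarkers are at their healthy plateau.
  Nothing is known about the real stage distribution in such cohorts; the
  uniform choice is a modelling convenience, stated rather than inferred.
* **Visits.** Annual visits up to six, with independent per-visit dropout
  (default 0.4), which reproduces the steep attrition characteristic of
  dementia cohorts (roughly half of subjects contribute ≥2 visits). An
  explicit distribution over 1–6 visits can be supplied instead.
* **Covariates.** Additive, linear effects of age, gender, TIV, scanner and
  site, expressed in units of each biomarker's healthy SD so a single
  coefficient set applies across biomarkers on different native scales
  (defaults: −0.02 SD/year of age, 0.3 SD per TIV-SD, −0.1 SD for female,
  0.2 SD for 3T, ±0.15 SD by site). Additivity matches the general-linear
  -model correction applied downstream.
* **Cohort sizes.** Defaults of 115 controls and 90 patients per group
  mirror the scale of multi-centre neuroimaging studies of rare syndromes.
* **Default ROI design.** Eight composite volumes (occipital, parietal,
  temporal, ventricle, whole brain, frontal, entorhinal, hippocampal) with
  4-SD abnormal shifts, 8-year transitions and noise at 0.35 healthy SD
  (≈9% of dynamic range). Group A is posterior-first, group B
  medial-temporal-first; middle events (temporal, ventricular) are shared.
  The ventricle is the one increasing biomarker. A floored cognitive design
  (`cognitive=True`) has seven tests with floor value 0.
* **What the generator does not emulate:** informative (disease-dependent)
  dropout, practice effects, non-logistic trajectory shapes, scanner
  upgrades mid-study, and measurement error correlated across biomarkers.
  Passing recovery tests therefore demonstrates correctness of the
  estimators under their own assumptions, not robustness to every
  real-data pathology.

## Preprocessing

* **Covariate adjustment** fits per-biomarker OLS on controls only
  (default), then subtracts the fitted covariate contribution from all
  subjects; fitting on controls avoids regressing out disease effects that
  correlate with age. The contribution is centred at the reference-sample
  covariate means so adjusted values keep the native scale (intercept
  retained), which also makes the operation idempotent to machine
  precision. Categoricals are one-hot encoded with the first level as
  reference; a rank-deficient design raises an error naming the collinear
  columns (identified by pivoted QR), as does a category unseen in the
  reference sample.
* **ROI aggregation** averages left/right hemispheric columns first, then
  takes the unweighted mean of the constituent bilateral regions (the
  simplest reading of "averaged"; volume-weighted averaging is a plausible
  alternative and deliberately not the default). The packaged 46-region →
  8-ROI mapping is a synthetic reconstruction with Neuromorphometrics-style
  names — a stand-in for the atlas grouping used in practice, which is why
  its filename carries `synthetic`.
* **z-scores** use control baseline visits only, so multi-visit controls are
  not over-weighted.
* **Floor rule** for longitudinal cognitive series: after a subject's first
  visit at floor, the next visit is assigned the floor score and all later
  visits become missing (test administration is discontinued).

## Differential equation model

* **Subject slopes**: OLS per subject; the x-coordinate is the subject's
  mean observed value (not the fitted midpoint). Subjects with <2 usable
  visits are excluded and counted. Slopes are fitted on all participants —
  controls contribute near-zero rates at healthy values and anchor the
  healthy plateau of the rate function.
* **GP rate model**: squared-exponential × constant + white noise,
  `normalize_y`, 5 optimizer restarts with a fixed seed. The length-scale
  is bounded below at one fifth of the observed value range: rate structure
  narrower than that is indistinguishable from subject-level slope noise at
  realistic cohort sizes, and the bound also prevents the GP from
  interpolating duplicated points in bootstrap resamples. Targets are
  standardised by the slope SD before fitting.
* **Integration**: dt/du = 1/f(u) is accumulated by the trapezoid rule on a
  2000-point value grid from the upper integration limit downward, then
  inverted onto a uniform 500-point time grid. Integration covers the
  contiguous segment of dominant-signed rate around the rate peak; it stops
  where |f| falls below 10⁻³·max|f| (a fixed point — the trajectory
  asymptotes). An opposite-signed excursion beyond 25% of max|f| while the
  dominant segment covers less than 60% of the value range is treated as a
  genuinely alternating rate and raises an error naming the crossing value
  — such dynamics cannot be integrated into a monotone trajectory. Smaller
  opposite excursions are extrapolation noise beyond a zero crossing and
  are truncated with a warning.
* **Anchoring**: t0 is the pooled-midpoint threshold maximising raw
  classification accuracy of controls vs patients; ties take the median
  maximiser (warned). Anchoring shifts time and attaches control-referenced
  z-scores; it never changes the trajectory's shape.
* **Staging**: argmin over a common time grid of the summed squared
  difference between a subject's observed z-scores and each trajectory's
  z(t), equal weights per biomarker, trajectories clamped at their
  endpoints so extreme subjects stage at the grid boundary.
* **Bootstrap**: subject-level resampling with replacement, stratified by
  group so every replicate retains controls and patients; full DEM refit
  per replicate; failed integrations are dropped and counted, >50% failures
  is an error. Default 100 replicates (smaller in the test-bench).
* **Trajectory comparisons** at fixed times from t0 (−10, 0, +10 years):
  paired t-tests across replicate pairs for within-group biomarker
  contrasts, two-sample t-tests between groups, one Bonferroni threshold
  over all evaluable tests. Whether such tests should run on bootstrap
  replicates or another sampling of estimated values is an open choice;
  replicate-based testing is used here.
* **Recovery scoring** (`trajectory_recovery_rmse`) compares a
  reconstruction against its generating sigmoid over a window of 1.5×
  the transition duration centred on the reconstructed midpoint crossing,
  after an exhaustive time-shift search. Plateaus outside the window are
  flat, and the time the integrator spends on them diverges as the rate
  approaches zero, so including them would score an unidentifiable
  quantity.

## Event-based model

* **Gaussian flavour**: two-component constrained mixture; the normal
  component is initialised from controls, the abnormal from patients, EM
  refines both on pooled data with the normal mean constrained to the
  control side of the abnormal mean. Biomarkers whose components end up
  less than one SD apart are flagged uninformative.
* **KDE flavour**: classification EM — points are hard-assigned to the
  component with the larger weighted density, each component is refit as a
  Gaussian KDE (Silverman bandwidth) on its members, and the loop runs
  until the assignment vector is stable. Hard assignment is what keeps the
  two kernel densities from gradually absorbing each other, which soft
  responsibilities provably do here (each iteration leaks mass across the
  boundary and inflates both bandwidths). A degenerate component (e.g. all
  mass on a score floor) falls back to a narrow Gaussian at the spike. The
  returned P(event | x) is continuous, from the final densities and mixing
  weight. The exact reassignment scheme used in practice varies between
  implementations; this one is recorded as the package's choice.
* **Likelihood**: uniform stage prior, missing values contribute a factor
  of 1, densities floored at 10⁻¹² to avoid −∞ log-likelihoods, all
  computation in log space with per-subject log-sum-exp over stages.
* **Search**: steepest-ascent over all pairwise swaps from `n_starts`
  random permutations (the identity is always one start); exhaustive
  enumeration for N ≤ 7 serves as the oracle mode.
* **MCMC**: single chain, random pairwise-swap proposal (symmetric, so
  Metropolis acceptance min(1, L'/L)), every state stored, default 100 000
  iterations thinned 1-in-100 before use as position samples.
* **Positional variance**: event-by-position frequencies over a sequence
  set — either the thinned chain or bootstrap ML sequences (subject-level,
  group-stratified resampling); both sources are exposed because either is
  defensible for headline diagrams.
* **Staging**: stage posterior ∝ Π_{i≤k} p(x|E) Π_{i>k} p(x|¬E), uniform
  prior, argmax with ties to the smaller stage.

## Ordering statistics

Positions are ordinal, so comparisons are non-parametric. Within-group
precedence uses the one-tailed Wilcoxon signed-rank with the zero-discard
convention and continuity-corrected normal approximation (exact small-sample
p-values where scipy's auto mode permits); the continuity correction keeps
the test from being anticonservative on heavily tied position samples,
which matters for family-wise calibration. Between-group position shifts
use the two-tailed Mann–Whitney U with tie correction and rank-biserial
effect size. Bonferroni control is applied per family with the family size
reported; degenerate tests (all differences zero, constant identical
vectors) return p = 1 with a flag rather than failing.

## Pipeline

`run_pipeline` executes preprocess → per-group DEM → per-group EBM →
ordering statistics. Every stochastic stage derives its seed from the run
seed via a hash-based substream, so reruns with the same config and input
are reproducible; the manifest records the config hash, seed, package
version and a content hash of every output file. Mixture flavour is
declared per biomarker in the config (volumes → gaussian, cognitive → kde)
rather than inferred from the data. The test-bench and the acceptance
script run the pipeline with reduced problem sizes (≈80 subjects per arm,
5 000 MCMC iterations, 5 DEM bootstrap replicates), chosen as the smallest
sizes at which the design's recovery properties are stable.

## Known limitations

* The DEM requires a single-signed rate function; biomarkers that genuinely
  improve then worsen (or vice versa) cannot be integrated and raise an
  error by design.
* Trajectories are fitted independently per biomarker; correlations between
  biomarkers enter only through staging, never the fits.
* The EBM assumes a single ordering per group (no subtypes) and step-like
  transitions; subjects far from both components inflate no warning beyond
  the density floor.
* Bootstrap confidence bands are percentile bands from modest replicate
  counts in the default test-bench configuration and will be wiggly; raise
  `n_boot` for publication-quality bands.
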