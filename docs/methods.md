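# Methods

This note documents the statistical models implemented in `vbmtraj`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## The design matrix and the differential-age F-test

All voxel-wise analyses share one design: for groups g ∈ {ASD, CTRL} an
indicator column, and for each covariate x (age in years; age², squared
*before* centring; TBV in ml; full-scale, verbal and performance IQ) one
column per group containing x mean-centred within that group and zero
elsewhere.  Within-group centring makes every covariate column exactly
orthogonal to every indicator column, so

- group comparisons are unaffected by covariate level differences, and
- covariate (including age-trajectory) effects explain only variance
  beyond the group means — the two questions are orthogonal by
  construction.

Fitting is massively univariate ordinary least squares, solved once per
design via the Moore–Penrose pseudoinverse (rank-deficient designs — e.g.
a covariate constant within a group — degrade gracefully, with the rank
reflected in the residual degrees of freedom `df = n − rank(X)`).

The differential-age test is the Wald F for the 2-row contrast
`β_age,ASD − β_age,CTRL = 0` and `β_age²,ASD − β_age²,CTRL = 0`, which is
algebraically the nested-model comparison between the full design and one
with pooled age columns (the test suite verifies this identity against an
explicit nested-OLS oracle).  The contrast spans only the four age
columns, not the group intercepts; testing intercepts too would conflate
level differences with trajectory differences, which the orthogonalised
design deliberately separates.

Multiple testing uses Benjamini–Hochberg step-up FDR at q = 0.05
(delegated to `statsmodels.stats.multitest`, verified against a
brute-force implementation including ties), followed by a cluster extent
threshold of 100 voxels on the suprathreshold mask.  Connected components
use 18-connectivity by default (faces + edges, the common convention for
3-D statistical maps); 6 and 26 are available, all verified against a
flood-fill oracle.

## The posterior probability map

The group-difference map is Bayesian rather than frequentist: inference is
about the contrast *exceeding a threshold γ* — the background noise level
— not about being exactly non-zero, so with enough data negligible
differences do not become "significant", and sub-threshold posterior
probabilities quantify evidence for the *absence* of differences.

The estimator is a single-level parametric empirical-Bayes scheme.  With
per-voxel contrast estimate ĉ and sampling variance s² from the GLM, the
true contrast is modelled a priori as Normal(0, τ²) with one global

    τ² = max(0, var(ĉ) − mean(s²))

moment-matched across voxels (marginally var(ĉ) = τ² + s²; the prior mean
0 encodes "no difference").  The posterior at each voxel is
Normal(w·ĉ, w·s²) with shrinkage weight w = τ²/(τ² + s²), and

    PP = P(contrast > γ | data) = 1 − Φ((γ − w·ĉ) / (√w·s)).

Maps are thresholded at PP > 0.99.  γ defaults to one prior standard
deviation (√τ̂², the "background noise" convention) and is always
overridable; the γ actually used is recorded in the output.  Degenerate
voxels with zero posterior sd get PP ∈ {0, 1} by the obvious limits.

This replaces a full two-level ReML covariance-component estimation: the
inferential logic (posterior of the contrast against γ at 0.99) is
preserved, the estimator is the simplest model honouring it.  Shrinkage
guarantees |posterior mean| ≤ |ĉ| and posterior sd ≤ s; as τ² → ∞ the map
converges to the unshrunk frequentist exceedance probability (both are
tested).  Under a null simulation τ̂² collapses to ~0 and the
suprathreshold fraction stays ≪ 1%.

## Confound adjustment and per-group trajectory fits

For region-level analyses the per-subject GM values are residualised on
group indicators plus group-centred confounds (TBV and the IQ scores —
never age or age², which would destroy the quantity of interest).  The
stored adjusted values are centred within groups (the natural quantity to
plot against age); the per-group mean offsets are kept alongside, for the
reason below.  Adjustment is idempotent, and the adjusted values are
orthogonal to every confound within each group.

Each group's trajectory is then an independent OLS quadratic in age.  The
peak age −β₁/(2β₂) is reported only when β₂ < 0 (inverted U); a U-shaped
fit (β₂ > 0) reports its trough age instead, and a degenerate β₂ = 0
reports neither.

## The trajectory-shift statistic

To ask whether one group's growth curve is displaced along the age axis,
each ASD subject is compared with the controls "most similar in brain
development", i.e. in GM volume:

1. rank controls by |GM difference| on the *common scale* (confounds
   removed, group means retained — see below); keep the k most similar;
2. among them, take the signed age difference (control − ASD) with the
   minimum absolute value (ties in GM similarity and in age distance
   resolve to the smaller subject index, so the statistic is
   deterministic);
3. test the n_ASD differences against zero with a one-sample t-test
   (two-sided by default), df = n_ASD − 1.

Mean difference Δ̄ > 0 ⇒ controls at the same GM level are older ⇒ the ASD
curve is shifted leftward.

**Why matching retains group means.**  Matching on group-mean-removed
values subtracts a *different* constant from each group, imposing an
arbitrary vertical offset between the two groups' GM scales.  Simulations
show the consequences are fatal: under identical group trajectories the
test rejects at ~34% instead of 5% (the finite-sample difference in group
means becomes a shared pseudo-shift for all subjects), and under a true
+5-year shift the estimate comes out near −2.4 years, because a peak-age
shift changes the groups' mean GM levels and re-centring converts that
level difference into a spurious age displacement.  Cross-group "similar
in GM volume" is only meaningful on one common scale, so the default
removes confound contributions but keeps the group means
(`match_scale="common"`; the centred variant is retained for comparison).

**k and the minimum-|age| rule.**  The default k = 5 with minimum-|age|
selection follows the "set of similar controls, then minimum distance"
reading.  The min-|age| step, however, selects the candidate closest to
the subject's *own* age, which biases the magnitude of Δ̄ toward zero by
roughly half the age-width of the candidate set — demonstrably even with
zero noise.  The direction and the test's power are essentially
unaffected (power ≈ 0.9 at δ = 5 y, n = 40/group), but magnitude
estimation should use k = 1, plain nearest-neighbour matching, which
recovers δ = 5 y to within its confidence interval.  The package
therefore uses k = 5 as the reporting default and k = 1 in its
calibration and recovery validation; the k ∈ {1, 3, 5, 10} attenuation
profile is part of the test suite.

**Geometry limits.**  The statistic presumes the sampled age window is
dominated by one monotone branch of the trajectory.  When the peak sits
mid-window, controls on the mirror branch carry the same GM value at a
very different age and min-|age| matching mixes branches, destroying the
estimate; subjects within δ of the age-range ceiling have no older
controls to match, attenuating Δ̄ by a few tenths of a year.  The
validation therefore places the control peak in middle adulthood
(μ = 40 y for an 8–50 y cohort), the regime the method is designed for —
consistent with regions that mature into middle adulthood.  Conversely,
when the two groups' curve *shapes* differ qualitatively (one declining
linearly, one U-shaped), the matched differences are structured by the
curve geometry rather than by any age displacement; depending on where
the control curve's extremum sits relative to the cohort's age density
this can manufacture a systematic pseudo-shift in either direction.  The
built-in divergent-trajectory region is constructed with the control
curve's extremum at the cohort's age centre, where the geometry produces
no systematic displacement and the shift test is correctly
non-significant while the differential-age F-test fires.

The test treats the n_ASD matched differences as independent although
controls can be reused across subjects; measured type-I error at α = 0.05
is ~0.055–0.065 (k = 1, 1000 replicates) — near-nominal but with a small
upward drift that users should keep in mind at marginal p-values.

## Other pieces

- **One-sample t, Cohen's d.**  Textbook forms; zero-variance inputs are
  handled explicitly (t = 0, p = 1 when the mean is also zero; flagged
  ±∞/NaN otherwise).  d uses the pooled (n−1-weighted) SD.
- **Global-volume ANCOVA.**  Nested-model F for the group factor on TBV
  (or any global volume) controlling for grand-mean-centred age, age² and
  the three IQ scores.
- **Symptom-severity regression.**  Within the ASD group, a per-voxel t
  on the (centred) ADOS total score with age, age² and confound columns,
  FDR-corrected.

## The synthetic cohort generator

`generate_cohort` draws, by default, two *matched* groups: one truncated
normal age distribution (mean 19.8 y, SD 8.8, range 8–50 — the pooled
profile of a typical cross-sectional ASD/control sample), and shared
normal IQ (FSIQ 110 ± 14.5, VIQ 108 ± 17.7, PIQ 105 ± 14.2) and TBV
(1374 ± 126 ml) distributions; a two-scanner indicator with a ~10%
minority scanner; ADOS-G totals (12 ± 3.5) for ASD subjects only.
Group-specific age means/SDs and a performance-IQ offset are available to
emulate demographic mismatch — worth noting because the shift statistic
converts age-distribution differences directly into apparent shifts
(simulated mismatched ages alone push its false-positive rate to ~0.39),
which is precisely why such studies age-match their groups.

Regional data follow y = a − c(age − μ)² + Σλₖ·covₖ + ε with group-specific
(a, c, μ), confound slopes λ and i.i.d. Gaussian noise; with c > 0 an
inverted U peaking at μ, c < 0 a U, c ≈ 0 with a far-off vertex an
effectively linear course.  Image data place spherical regions with their
own trajectory parameters on a default 20³ grid of 2 mm voxels over a
no-group-difference background, then smooth each subject with a Gaussian
kernel of configurable FWHM (8 mm default).  Smoothing uses a wrap-around
boundary, which conserves the image sum exactly — matching the "modulated"
semantics in which voxel values represent local volume and their total is
meaningful.

What the generator does *not* emulate: tissue segmentation or
registration error, spatially correlated residual noise (noise is i.i.d.
before smoothing, so residual spatial autocorrelation is understated),
non-Gaussian heavy tails, or any dependence of covariates on diagnosis
beyond the optional offsets.  Passing calibration here therefore shows the
statistics behave correctly under the model's own assumptions, not that
real VBM data meet those assumptions.

## Numerical and validation choices

- Deterministic throughout: every stochastic function takes a seed; the
  pipeline re-run with the same config+seed is byte-identical; all writes
  are atomic (temp file + rename).
- Validation problem sizes: oracle equivalence on 10⁴ random p-vectors
  and random 12³ masks; calibration on 4000 null sites (F and PPM) and
  1000 replicate cohorts (shift test, ±3σ binomial band around α);
  recovery on 200 replicates at n = 40/group.  The whole suite runs in
  seconds, so these sizes are comfortable rather than binding.
- The qualitative end-to-end check aggregates over six fixed seeds and
  allows one exception for each of two known benign events: two true
  clusters merging through FDR-admitted voxels in the smoothing halo, and
  the ~5% false-positive floor of the no-shift claim.
- Voxel↔mm via the image affine (origin at the grid centre by default);
  voxel indices are 0-based internally.

## Known limitations

- The global (single-τ²) prior shrinks uniformly; voxel-specific or
  locally smoothed priors are out of scope.
- No family-wise (random-field or permutation) correction — FDR plus
  extent thresholding only, by design.
- The shift statistic is cross-sectional: it infers trajectory
  displacement from between-subject matching, not within-subject change,
  and inherits the geometry caveats above.
- With very small groups the pseudoinverse keeps fits defined, but
  contrasts on collapsed columns are flagged rather than inferred.
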