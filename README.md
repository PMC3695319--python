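# vbmtraj

Second-level statistics for voxel-based morphometry (VBM) studies of
grey-matter (GM) development, built for the cross-sectional two-group
design used in neurodevelopmental research (e.g. autism spectrum disorder
vs typical controls, ages spanning childhood to middle adulthood).

Given a subject table (group, age, IQ scores, total brain volume) and
modulated GM images on a common grid, the package provides:

- **Group-difference posterior probability maps (PPMs).**  An
  empirical-Bayes Normal–Normal shrinkage model with a global,
  moment-matched prior variance τ² yields, per voxel, the posterior
  probability that the group contrast exceeds an effect-size threshold γ
  (interpreted as the background noise level; γ = τ by default).  Maps are
  thresholded at posterior probability 0.99.
- **Differential age-trajectory ANCOVA.**  A voxel-wise GLM with group
  indicators and, for each covariate (age, age², TBV, full-scale/verbal/
  performance IQ), one column per group mean-centred within that group —
  so covariate columns are orthogonal to the group main effects.  An
  F-contrast tests whether the groups' linear and quadratic age
  coefficients differ jointly, with Benjamini–Hochberg FDR control
  (q < 0.05) and a cluster extent threshold (100 voxels) on the result.
- **Trajectory fits and the leftward-shift test.**  At a voxel of
  interest, GM values are adjusted (group mean and confound effects
  removed, age effects retained) and a second-order polynomial
  `y = β₀ + β₁·age + β₂·age²` is fitted independently per group.  The
  shift test then asks whether one group's growth curve is displaced
  along the age axis: for each ASD subject, find the k controls most
  similar in GM volume, take the signed age difference with minimum
  absolute value, and test the per-subject differences against zero with
  a one-sample t-test.  A positive mean difference Δ̄ means the controls
  at the same developmental stage are older — a leftward shift in ASD.
- **A synthetic-cohort generator** that produces seeded subject tables
  and GM images with known inverted-U trajectories
  `y = a − c(age − μ)² + Σλₖ·covₖ + ε`, configurable peak-age shift δ,
  confound effects, Gaussian voxel noise and mass-conserving Gaussian
  smoothing at a configurable FWHM — so the full pipeline is testable
  without any imaging data.

## Worked example

Run the full pipeline on the built-in synthetic study (47 ASD / 51
control subjects, three regions on a 20³ grid of 2 mm voxels, 8 mm
smoothing):

```bash
vbmtraj run --seed 1 --out report/
```

`report/f_age_peaks.tsv` — two clusters where the age trajectories differ
between groups (peak mm coordinates via the affine, F at peak, extent):

```
analysis            x_mm  y_mm  z_mm  peak_mm       peak_stat    extent
differential_age_f  -9    -9    -9    (-9, -9, -9)  2448.539827  956
differential_age_f  11    11    11    (11, 11, 11)  495.393602   668
```

`report/trajectory_fits.tsv` (first region): the fitted quadratics peak at
31.8 y in ASD vs 37.4 y in controls — the generative model placed the
control peak at 40 y with a 5-year earlier ASD peak, and the ~5.6 y fitted
difference recovers it.

`report/shift_tests.tsv`:

```
site  peak_ijk      mean_delta    t            df  p             direction  k
2105  (5, 5, 5)     2.487490059   6.112279953  46  1.96496709e-07  leftward  5
6315  (15, 15, 15)  0.7218853981  1.36336755   46  0.1794025831    none      5
```

In the shifted inverted-U region the controls most similar in GM volume
are on average 2.5 years older than the matched ASD subjects
(p ≈ 2·10⁻⁷): a leftward shift of the ASD growth curve.  In the second
region the curves differ in shape (significant F above) but show no
systematic displacement — the shift test is non-significant, as designed.
(The default k = 5 with minimum-|age| selection is deliberately
conservative about the shift magnitude; `--k 1` gives the plain
nearest-neighbour estimate, which centres on the true 5-year shift.  See
`docs/methods.md`.)

`report/ppm_summary.tsv` shows the Bayesian group-difference map
(τ̂² = 0.043, γ = 0.21) flagging 314 voxels at posterior probability
> 0.99, all in the region built with a pure GM reduction in ASD, and
`report/global_ancova.tsv` the (non-significant) total-brain-volume
ANCOVA, F(1, 91) = 3.21, p = 0.077.

The same stages are available individually (`vbmtraj simulate`, `glm`,
`ppm`, `trajectory`, `shift`) and as library functions.

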