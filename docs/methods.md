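# Methods

## The analysis model

A patient's modulated gray-matter map is treated as a control template minus
a degeneration field, and the degeneration field is factored as

    d_i(v) = s_i · p_i(v),        mean_v∈mask p_i(v) = 1,

where `s_i` (unitless intensity loss; divided by the template mean it reads
as a fractional volume reduction, e.g. 0.15 ≙ 15%) is the *severity* and
`p_i` the *pattern* — the relative spatial distribution of that patient's
degeneration.  Severity is estimated as the mask-mean of the control-mean-
referenced degeneration map, and the pattern as the degeneration map divided
by severity.  The factorization is exact and scale-invariant: two patients
with proportional degeneration maps get identical patterns.  Negative
degeneration values (patient locally above the control mean) are retained;
clipping them would destroy the unit-mean identity and distort the pattern
geometry that MDS and LDA operate on.

Patients whose severity magnitude falls below a floor (default 1e-3 of the
template mean) have no stable pattern — dividing by near-zero severity
amplifies noise without bound — and are flagged and excluded from
pattern-space analyses (corrected-map classification and embedding), a
situation that genuinely occurs for barely-affected patients.

### Brain-size correction

Cerebellar volume scales with head size, which is a nuisance for
between-subject comparisons.  The correction regresses cerebellar
gray-matter volume on cerebrum volume (OLS, all subjects by default;
controls-only is a switch) and multiplies each subject's map by
`average / predicted` cerebellar volume.  Multiplying by the *inverse* ratio
(`predicted / average`) would amplify rather than remove the dependence;
this package uses the direction that zeroes the fitted slope of scaled
volume on cerebrum volume, which is exact when the coupling is linear (a
property the tests verify to 1e-8).

### Classification

Pairwise group classification uses LDA on masked voxel vectors with the
paired leave-one-out scheme: for every pair (a ∈ A, b ∈ B), train on the
remaining subjects of both groups, test on {a, b}.  Mean accuracy averages
the 2|A||B| test evaluations; per-subject accuracy averages the folds
containing that subject.  With p ~ 10²–10⁵ voxels and tens of subjects the
pooled within-class covariance is singular, so the default classifier
shrinks it toward a scaled identity with the Ledoit–Wolf coefficient
(numerically identical to scikit-learn's `lsqr` + `shrinkage="auto"` LDA,
verified to 1e-13 in tests, but solved with the Woodbury identity in
O(n²p) per fold instead of O(p³) — the fold loops would otherwise dominate
the pipeline).  An alternative mode reduces each training fold by PCA
(components explaining 95% of training variance only; no test-set leakage)
before plain LDA.  Features are standardized with training-fold statistics;
exact decision-boundary ties go to the first-listed group.

Controls-vs-subtype comparisons run on uncorrected (scaled) degeneration
maps — the amount of degeneration is the legitimate signal there.
Subtype-vs-subtype comparisons run on both uncorrected and corrected maps;
the before/after contrast isolates what the severity confound costs.  The
per-patient accuracy curve averages each patient's accuracy over the two
pairwise subtype tasks involving their group (control folds excluded), and
fits a two-parameter logistic (location, scale; floor 0, ceiling 1) by
maximum likelihood with the per-patient fold counts as binomial weights.
The fitted curve is monotone by construction; all-equal accuracies are
flagged flat with an infinite scale.

### Embedding

Classical (Torgerson) MDS: double-center the squared Euclidean distance
matrix, eigendecompose, scale eigenvectors by the square roots of the
positive eigenvalues.  For Euclidean distances this equals PCA scores of the
centered feature matrix — the test suite uses scikit-learn PCA as the
independent oracle.  Variance fractions are eigenvalue shares of the
positive spectrum; numerically null dimensions (eigenvalue < 1e-12 of the
largest) are zeroed rather than reported as roundoff noise.

### Symptom mapping

The correlation map is voxelwise Pearson r between the SARA score and
scaled (not severity-corrected) gray-matter intensity across all patients,
with two-sided p from the t transform at df = n − 2, vectorized and verified
against a per-voxel loop oracle to 1e-12.  Voxels exactly constant across
patients have undefined r and are dropped and counted.  The significance
mask is uncorrected p < α (default .05), matching common practice for these
maps; Benjamini–Hochberg FDR is available as an option.  Local maxima are
26-neighborhood maxima of |r| inside the significance mask, selected
greedily in descending |r| under a minimum-separation constraint (default
twice the sphere radius).  Sphere contrasts average each patient's
degeneration over voxels whose world-space centers lie within the radius
(default 6 mm; the radius is a parameter because reasonable choices between
6 and 10 mm exist) and compare one focus subtype against the pooled
remaining patients with a pooled-variance two-sample t, df = n_patients − 2;
per-pair contrasts are an option.  Cohort statistics are standard: one-way
ANOVA on severity across subtypes, Pearson severity–SARA correlation, and a
type-II GLM ANCOVA (group factor + SARA covariate, F for the group factor,
residual df = n − groups − 1).

## The synthetic-cohort generator

The generator emulates exactly the structure the analysis assumes, so the
pipeline's correctness can be checked by round trip.  For subject i of
group g:

    m_i = f_i · (t − s_i · (P_g + η_i)) + ε_i,   clipped at 0,

- `t`: template, flat baseline 0.7 with an optional smooth ±5% field.
- `P_g`: subtype signature — log-normal region weights (region sd 0.25) on a
  Voronoi lobule parcellation, each subtype's own disjoint region set
  elevated (+1.0), motor regions multiplied by a per-subtype emphasis,
  nucleus ROIs scaled per subtype, lightly smoothed, normalized to unit
  cortical mean.  The default cohort gives the SCA3 analog lower severity
  (0.07 vs 0.12), stronger motor emphasis (3.5 vs 0.8) and weaker nucleus
  involvement (0.5 vs 1.0): less degenerated overall, harder-hit motor
  regions, mirroring the clinical scenario the analysis is designed to
  expose.
- `s_i`: severity, truncated normal on [0, 1) per group; controls 0.
- `η_i`: per-patient pattern individuality — a smooth zero-cortical-mean
  field (sd 0.15 relative to the unit-mean signature).  Patients do not
  degenerate in lockstep with their group's mean pattern, and this
  variability scales with severity, unlike scanner noise.  It is also what
  makes the severity confound bite: with only white voxel noise the
  severity direction is a cleanly estimable rank-1 covariance component
  that a shrinkage LDA whitens away on its own, and severity correction
  would look unnecessary.
- `f_i = 1 + c·(V_i − V̄)/V̄`: brain-size factor, linear in cerebrum volume
  (default coupling 0.4, V ~ N(1.1e6, 8e4²) mm³).
- `ε_i`: Gaussian noise, spatially smoothed (kernel 1.5 voxels) and rescaled
  to marginal sd 0.02 — VBM maps are strongly autocorrelated; white noise is
  available by setting the kernel to 0.
- SARA: `1 + 90 · (mean true degeneration over motor regions) + N(0, 4.5²)`,
  clipped to [0, 40].  The defaults put the cohort severity–SARA correlation
  near 0.5 and group-mean SARA near 10–13 on similar scales across subtypes.

Negative intensities are clipped at 0 and the clipped-voxel count reported.
Identical configs (including seed) reproduce cohorts bit-for-bit.

With zero noise, zero jitter and unit brain factor the adjustment stage
recovers each severity exactly and each signature to 1e-6 (the analysis and
the generator share the same decomposition); under noise the severity error
shrinks as the mask grows.  What passing tests do *not* show: real VBM maps
have registration error, smoothing-kernel structure, tissue-class
misclassification and site effects that no parameter here emulates, and
real subtype signatures are not region-wise-constant fields.  Results on
synthetic cohorts validate the *machinery*, not clinical performance.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on 10³–32³ grids with
cortical masks of roughly 200–8000 voxels and cohorts of 20–100 subjects —
small enough for minutes-scale runs while leaving every statistic
well-conditioned; the method itself is grid-size-agnostic.  The acceptance
script uses a realistic single-center sample (15/14/17/23) on a 16³ grid.  Chance-
level checks pool several seeded cohorts because a single cohort's
leave-one-out accuracy under the null has sd ≈ 0.1 (folds share training
data); pooled accuracy is compared against a subject-level binomial
interval.  MDS eigenvalues below 1e-12 of the maximum are treated as zero.
OLS fits use `numpy.polyfit`/`statsmodels`; ANOVA/ANCOVA and t/Pearson
statistics come from `statsmodels` and `scipy.stats`.

## Known limitations

- The generator's noise model is a stand-in; no noise model for modulated
  VBM intensities is established, and Gaussian smooth noise is a pragmatic
  choice.
- The gray-matter mask is group-level by default (per-subject masks would
  make severities incomparable across subjects), and the brain-size
  regression uses all subjects by default; both choices are switchable.
- The ANCOVA residual df follows the standard GLM (n − groups − 1).
- Pattern-space analyses exclude controls: with severity ≈ 0 a control's
  pattern is noise divided by noise.
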