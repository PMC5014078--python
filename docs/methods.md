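# Methods

## Scope

`lesionprog` studies how linear lesion-deficit models trained on one
patient group transfer to another, and whether group differences reflect a
shared network with different sensitivity (convergence) or distinct
networks (divergence). The pipeline operates on binary lesion masks in a
common voxel grid, a region parcellation, a demographic table, and a
task-by-patient T-score table with missing entries; a synthetic cohort
generator supplies all of these with known ground truth.

## Synthetic cohorts

**Geometry.** A toy "left hemisphere" is a 3-D grid (default 16×20×16
voxels at 5 mm, ≈ 640 cm³). The parcellation seeds `n_regions` voxels
(default 199), assigns every voxel to its nearest seed (a Voronoi
partition, so regions are non-empty), and lets each region annex boundary
voxels of its neighbours with probability `atlas_overlap` (default 0.25),
emulating the overlapping union of several published atlases. Lesions are
grown voxel-by-voxel from seeds scattered (SD `territory_spread` = 2
voxels) around `territory_count` = 2 territory centres — vascular-territory
analogues fixed per cohort and shared by all patients and the reference
sample. Growth is 6-connected, so every lesion is one connected component;
target volumes are log-normal within [1, 250] cm³ (floor = the 1 cm³
inclusion threshold), median ≈ 20 cm³.

**Scores.** Each task has a sparse weight vector over regions: the default
draws `n_active_regions` = 8 active regions per task with probability
proportional to (mean lesion load)², so the deficit-relevant network lies
inside the lesioned territories, as a language network lies inside the
middle-cerebral-artery territory; magnitudes are uniform in
[0.06, 0.18] raw units per % load and **negative** (damage lowers scores).
Time post-stroke carries a small positive weight (slow recovery,
0.02/month); a quarter of tasks carry a negative age weight. The raw score
for patient *i* on task *t* is

    raw_it = intercept + Σ_R w_tR · load_iR · (λ if group b)
             + w_time·time_i + w_age·age_i + (δ if group b)
             + u_i + ε_it

with two noise components: a patient-level severity draw `u_i`
(`noise_shared_sd`, default 5) common to all tasks — aphasia battery
scores correlate strongly across tasks — and a task-specific draw `ε_it`
(`noise_sd`, default 3). λ (`lambda_sensitivity`, default 1 = null)
multiplies group-b lesion weights only: the enhanced-sensitivity
mechanism. δ (`intercept_shift`, default 0, T-units) shifts group-b
expected scores: the premorbid-proficiency mechanism. The two are separate
knobs so each explanation can be simulated alone. A third mode
(`divergent_regions`, `divergent_weight`) adds group-b-only loading on
chosen regions to emulate neural divergence.

**Standardization.** Raw scores are converted to T-scores against a
simulated reference sample of 60 lesioned patients scored through the same
model (T = 50 + 10(x − m)/s with the sample mean and SD), and an
impairment cutoff is taken at the 5th percentile of 27 lesion-free
controls. The raw scale itself is a free construction chosen so one raw
unit ≈ one T unit in the reference population. Missingness is MCAR at
`missing_rate` (default 0.03, matching the small per-task gaps typical of
such batteries). Group b additionally receives native-language scores on
seven narrative/naming tasks (English score + `native_shift`, default
−0.8 T, + noise, ~35 % missing) and language-history fields (counts, ages,
proportions with ~20 % missingness), independent of scores by default so
the history screen has a true null; `history_effect` injects an
association for power testing.

**What the generator does not emulate:** real CAT psychometrics (floor and
ceiling effects, item structure), real vascular anatomy, registration
error, informative missingness, and the (unknown) dependence structure of
a real clinical cohort. Passing calibration tests therefore demonstrates
that the pipeline's statistics behave correctly under the stated linear
model, not that clinical findings themselves are reproduced.

## Model selection

Models are ordinary least squares with an intercept (scores are T-scaled,
so an intercept is required); rank-deficient designs get the minimum-norm
solution. The search starts from time post-stroke and alternates a forward
phase (repeatedly add the candidate that most reduces the criterion) and a
backward phase (repeatedly remove the member whose removal most reduces
it), cycling until a whole cycle changes nothing. The criterion is the
LOOCV mean absolute error (RMSE available); LOOCV uses the exact
hat-matrix identity e₋ᵢ = eᵢ/(1 − hᵢᵢ) on a column-standardized design
when it has full column rank, and explicit per-fold minimum-norm refits
otherwise. A step is accepted only if it improves the criterion by more
than 1e−9 (prevents cycling on ties); candidate ties break to the lowest
column index; zero-variance columns within the task's complete cases are
skipped; the seed feature is *not* protected from elimination. Complete
cases are used per task throughout. The random-model ensemble draws
feature sets with sizes uniform on [2, 40] and members uniform without
replacement over all predictors.

## Transfer and permutation control

Reference-group predictions come from LOOCV; transfer-group predictions
from one fit on all reference complete cases. Error = predicted − actual.
Per-task shifts use the equal-variance t-test (positive t = transfer group
overestimated) unless a classic (mean-centred) Levene test rejects
variance equality at 0.05, in which case Welch is used. The permutation
null shuffles the pooled cohort's group labels once per permutation and
recomputes every task's t on the labels induced on that task's complete
cases — one shared shuffle preserves the between-task dependence that
max-statistic control exploits. With n_perm permutations (default 1000)
the corrected per-task alpha is the k-th smallest per-permutation minimum
p (k = ⌊0.05·n_perm⌋), capped at the nominal 0.05; a task is flagged iff
its nominal p is below it. `n_perm = 0` skips the stage and marks outputs
as uncorrected. Wilcoxon rank-sum (midranks, tie-corrected z; exact
enumeration available for small tie-free samples) and paired t-tests cover
the demographic and native-vs-second-language comparisons; the history
screen correlates history fields with per-task errors on pairwise-complete
data, reporting nominal p-values with an explicit no-correction note.

## Bayes factors and the convergence screen

BF₁₀(r, n) is the default g-prior Bayes factor for a correlation versus an
intercept-plus-Gaussian-noise null (see README for the integral). It is
evaluated in log space: the (0, ∞) integral is mapped to (0, 1) by
g = u/(1 − u), the log-integrand's peak is located on a coarse grid and
factored out, and adaptive quadrature (`scipy.integrate.quad`, relative
tolerance 1e−8) integrates the rescaled function. Non-convergence raises
an explicit numerical error — never a silent default. |r| = 1 returns ∞
(the integral diverges). The result is symmetric in the sign of r,
strictly increasing in |r| at fixed n, and matches both a 10⁶-node
dense-grid oracle and an independent implementation to ≤ 1e−6 relative
error in the tests. Evidence categories follow Jeffreys: > 10 strong and
> 3 substantial for the correlation; < 1/10 and < 1/3 the same for the
null; [1/3, 3] inconclusive. No multiplicity correction is applied inside
the screen (categories, not corrected p-values, carry the inference); the
association table records n per (region, task, group) since complete
cases differ, and skips cells with constant load or score.

The convergence screen enumerates (region, task) pairs with BF₁₀ > 10 in
the transfer group and checks the reference group's BF₁₀ for each; the
divergent list holds the unshared cases with the reference BF attached.
The slope comparison pairs the two groups' univariate slopes (T-units per
% load — deliberately univariate, matching the region-by-region
correlations; multivariate model coefficients are not reused) over the
shared cases and applies a paired t-test with df = cases − 1, positive t
meaning steeper (more negative) transfer-group slopes. **Caveat:** cases
that share patients and correlated regions are not independent, so this
t-test is anticonservative under the null when many cases overlap (we
measure ~21 % rejection at nominal 5 % in such designs); with
near-independent cases (one region per task) it calibrates at ~5 %. The
sign and the slope-ratio estimate of λ are unaffected; treat the p-value
as descriptive, as the df convention implies. Identical slope pairs yield
an explicit degenerate result rather than a spurious statistic.

## Pipeline, determinism, problem sizes

Every stage persists flat TSV/JSON/NIfTI artefacts plus a manifest with
the config and SHA-256 of each output; re-running a config reproduces
every hash (asserted in tests). All randomness flows from explicit integer
seeds (cohort seeds spawn per-stage streams via `SeedSequence`).

`scripts/acceptance.py` runs the demographic comparisons from published
summary statistics and one full-scale pipeline: 174 + 33 patients, 199
regions, 22 tasks, λ = 1.5, 1000 permutations, a 2000-model random
ensemble (the package's default demonstration size for the 10 000-model
design), and the association screen over the flagged tasks. The
calibration suite uses 500 scaled-down null replicates (40 + 12 patients,
10 regions, 6 tasks, 200 permutations) for the family-wise false-positive
rate, and 100 score replicates at λ = 1.5 for shift detection.

## Known limitations

- The generator's linearity matches the model class; it cannot probe
  robustness to nonlinear lesion-deficit relations.
- Synthetic inter-task error correlation (~0.6–0.7) is lower than the
  near-total correlation the original corrected threshold implies, so the
  permutation-corrected alpha here sits closer to the Bonferroni bound
  and fewer tasks pass it than in the clinical report.
- The paired slope test's independence caveat above.
- No resampling: masks and parcellation must share one grid.
- Left-hemisphere-only by construction; no right-hemisphere handling.
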