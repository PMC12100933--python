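# Methods

## Problem setting

Two studies measure pairwise genetic distances over partially
overlapping population sets, on incompatible genotyping platforms.  Each
matrix is assumed to capture the *relative* relationships within its own
study correctly, while the absolute scale and orientation of its
underlying configuration differ across studies.  The goal is one
complete distance matrix over the union of populations.

## Frequency genotyping and Nei distance

Population genotypes are reference-allele frequencies estimated from the
VCF allelic-depth field: `f = AD_ref / (AD_ref + AD_alt)` per biallelic
SNP and pooled sample.  A call is treated as missing when the site depth
does not exceed `depth_min` (default 5; the requirement is strict, DP of
exactly 5 is rejected) or when the AD pair sums to zero.  Loci whose
missing fraction reaches `locus_missing_max` (default 0.05) are dropped
first, then samples whose missing fraction reaches `sample_missing_max`
(default 0.20) — the locus filter runs first so a handful of bad sites
cannot drag down otherwise usable samples.

Nei's (1972) standard distance accumulates the identity sums
`Jxy = Σ p·q + (1−p)(1−q)`, `Jx = Σ p² + (1−p)²`, `Jy` likewise, over
the loci where both populations are present (pairwise deletion), and
`D = −ln(Jxy/√(Jx·Jy))`.  Floating-point can push `D` marginally
negative for near-identical populations, so it is clamped at 0; a pair
fixed for opposite alleles at every shared locus has `Jxy = 0` and is
reported as `+inf` with a warning rather than NaN.  For complete data
the summed-identity and per-locus-averaged conventions give identical
`D`; pairwise-complete summation is used so that ragged missingness
stays computable.

Threshold clustering of a distance matrix (for deciding which
populations share a genetic background) uses hierarchical agglomerative
clustering cut at a distance threshold; single linkage is the default
and the linkage is a parameter.

## Classical MDS

Torgerson scaling: `G = −½·H·(D ∘ D)·H` with `H = I − (1/n)·11′`, where
`∘` is the elementwise square — the only reading under which `G` is a
Gram matrix.  Axes with eigenvalue above `eig_rel_tol` (default 1e-9)
times the largest are retained; zero and negative axes contribute no
usable coordinates and are dropped.  Cumulative explained variance is
reported under both denominator conventions (sum of positive
eigenvalues, and sum of absolute values), since for indefinite Gram
matrices the two differ and neither is canonically "the" variance.

The shared dimensionality ζ of a matrix pair is the smaller of the two
retained-axis counts.  A configuration asked for more axes than it owns
is zero-padded, never extrapolated.

## Procrustes calibration

Over the shared populations γ (at least 2 required), with centred shared
configurations `Xc`, `Yc`:

* scale `s = ‖Xc‖_F / ‖Yc‖_F` — the Frobenius-norm ratio, not the
  least-squares trace-optimal scale of common Procrustes
  implementations; both recover an exact similarity exactly, and the
  norm ratio is the contract here;
* rotation `R = argmin ‖Xc − Yc·R‖_F` over orthogonal matrices, from
  the SVD of `Yc′·Xc`; reflections are permitted (det R may be −1)
  because MDS axes carry arbitrary sign;
* translation `τ = X̄ − s·Ȳ·R`.

The calibrated configuration `Y′ = s·Y·R + τ` is mapped back to
distance space by pairwise Euclidean norms.  Distance-space diagnostics
over unordered shared pairs (diagonal excluded): mean signed bias, bias
relative to the mean reference distance, and the sum of squared
differences (SSD).  With the norm-ratio scale the anchor SSD after
calibration never exceeds the SSD before (provable via Cauchy–Schwarz),
which the test suite asserts.

## Merge and structural missingness

The union matrix averages shared-pair distances, copies within-study
distances, and leaves cross-study unique pairs missing.  Merging a 72-
and a 63-population matrix sharing 22 labels gives 113 populations and
2·50·41 = 4100 missing cells, 32.1% of the 113² total — bookkeeping the
acceptance tests reproduce exactly.

## Chained imputation

Missing cells are completed column by column: the target column's
observed rows are the training set, the feature vector of a row is its
distances to every population except the target, and currently missing
features hold the freshest available estimate (column means before the
first sweep).  Columns are visited in ascending order of missing count
(ties broken by label order) so the best-informed columns stabilise
first.  Within a sweep each new prediction is propagated into both
triangle copies of its cell, so later columns immediately see it; at
the end of a sweep every imputed cell is set to the average of the two
column models that predict it, and from the second sweep onward the
result is further averaged with the previous iterate (a damping
recursion that suppresses oscillation of the chain).  The literal
variant that symmetrises only once at the very end was measured to
settle at visibly biased fixed points on exact-Euclidean fixtures
(held-out R² around 0.95 instead of above 0.99) because the cross-block
feature state lags a full sweep behind; the freshest-prediction reading
is therefore the default.

Convergence is declared when the largest change of any imputed cell
between sweeps, measured relative to the mean observed distance, drops
below `rel_tol` (default 1e-4); per-cell relative change is not used
because it diverges at near-zero distances.  Non-convergence within
`max_iter` (default 10) returns the current result with a flag, not an
exception.  Observed cells are never modified (asserted bit-identical),
imputed cells are clamped at 0, and the output is symmetric by
construction.

Predictor menu and defaults: lasso (L1 penalty chosen by internal
cross-validation over a 30-point grid, folds capped at the training
size); regression tree (min leaf 2); random forest (100 trees, √p
feature subsampling); KNN (k = min(5, n_train), inverse-distance
weights); PMM (linear fit, one of the 5 donors with closest fitted
values drawn uniformly); WPMM (donor draw weighted by 1/(|fitted gap| +
1e-6)); random sampling; column mean.  Model-based methods with fewer
than 2 training rows degrade to the mean with a logged downgrade;
constant feature columns are dropped before fitting.  Per-column random
streams are derived from the master seed and recreated identically each
sweep, so the fitted models admit a fixed point and the whole chain is
a pure function of its seed.

## BESMI

Scattered random holdouts misrepresent the failure mode of merged
matrices, where whole cross-study blocks are absent at once.  Per
replicate, `round(fraction·|side|)` labels are drawn from each study
side (default fraction 1/5: 14 of 72 and 13 of 63) and every *observed*
cell pairing a drawn A-side label with a drawn B-side label is hidden —
the structural cross-block pattern extended over the drawn populations.
Masking literal full rows and columns of the drawn populations would
leave them with no observed anchor and make any prediction ill-posed,
so the cross-block geometry is the default; draws that would starve a
label of observed entries are retried (bounded).  Each method re-imputes
each masked replicate and is scored by R² on the held-out cells over
unordered pairs (each pair counted once); methods are ranked by mean R²
across replicates.  Replicates are independent seeded draws.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not any particular organism:

* **Allele frequencies** — Balding–Nichols drift: ancestral frequency
  per locus Uniform(0.05, 0.95); clade frequency Beta-distributed with
  the ancestral mean and variance scaled by `fst_between`; population
  frequency likewise around its clade with `fst_within`.  Note that
  under this nested model a between-clade pair accumulates the clade
  *and* population drift variances, so with `fst_between = fst_within`
  the expected within/between distance ratio is ½ (verified by
  Monte-Carlo), not 1.
* **Study pairs** — latent coordinates as Gaussian clade blobs; study A
  observes true pairwise norms of its subset, study B observes norms
  after its coordinates are scaled, rotated, translated and jittered.
  Distortion is applied in coordinate space so a Procrustes-recoverable
  ground truth exists by construction.
* **Structured benchmark** (`structured_study_pair`) — the standard
  conditions for method-comparison runs: 60 populations, 8-dimensional
  latent space, 6 clades (spread 3.0, within-clade spread 1.2), a fifth
  of the populations shared, platform scale 1.5, coordinate noise 0.05.
  The dimensionality and clade structure were chosen to mimic the
  regime in which distance columns are strongly collinear but nearest
  neighbours are not near-duplicates; in that regime the regression
  imputers clearly outrank KNN and the baselines, which is the ranking
  the acceptance test asserts.  Problem sizes are scaled to desk scale
  (a 60-population benchmark, a 30-population end-to-end fixture) as
  the package's own test budget.
* **Trait estimates** — per-population predictions Normal(clade mean,
  within_sd) with standard errors Uniform(se_low, se_high); defaults
  (means around 1500, within_sd 30, SEs 20–60) sit on the
  dry-matter-yield scale (kg DM/ha per harvest) the group estimators
  target.

What passing these tests does *not* show: real genotyping data carry
linkage, allele-frequency spectra and platform biases that no Gaussian
latent model reproduces, and real merged matrices need not be close to
Euclidean-embeddable.  The synthetic results certify the machinery
(exact recovery where recovery is possible, correct bookkeeping,
method-ranking behaviour in the intended regime), not field
performance.

## Group and combination estimators

Group trait value: `ν = Σωᵢ·Pᵢ/Σωᵢ`, `ωᵢ = 1/seᵢ²`.  Its standard error
is `√((1/k²)·Σseᵢ² + Σωᵢ(Pᵢ−ν)²/Σωᵢ)` — the first term is the
equal-weight variance of the mean rather than the inverse-variance one;
the formula is implemented as printed in its source convention
(fidelity over textbook form), and ν always lies inside the member
range.  Populations without a direct estimate inherit their group's ν
and standard error, flagged `group_fallback`; orphans are reported, not
dropped.  Host–endophyte combinations are additive, `PE = μ + P + E`,
with independence-assuming error aggregation; the grand intercept μ
must be supplied (it is not re-estimated here).

The neighbor-joining tree is built with scikit-bio; negative branch
lengths, an NJ artefact on non-additive input, are clamped to zero with
the deficit transferred to the adjacent branch.

## Numerical choices and limitations

* Eigendecomposition uses symmetric `eigh` on the explicitly
  symmetrised Gram matrix; CSV serialisation is `%.17g` with
  round-trip float parsing, so write→read is exact; tiny on-disk
  asymmetries (≤1e-9) are symmetrised by averaging on read, larger ones
  are errors.
* Mask-size rounding is nearest-integer (72/5 → 14, 63/5 → 13).
* The imputer assumes every population retains at least one observed
  off-diagonal distance; a starved label is a hard error naming it.
* BESMI R² is undefined when the held-out cells have zero variance;
  this is raised, and single (method, replicate) failures are recorded
  in the report rather than aborting the sweep.
* Chained imputation is a single-completion method; it provides no
  multiple-imputation uncertainty.  BESMI's across-replicate spread is
  the uncertainty handle instead.
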