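# Methods

`netcog` re-implements, as a tested and reusable pipeline, an analysis
chain from parcellated resting-state time series to the classification and
prediction of cognitive performance from strength-based functional-network
features.  Because the cohort the original analysis was run on is not
publicly deposited, the package ships a first-class synthetic-cohort
generator with planted ground truth; every statistical claim the package
makes is a property of its own computation on those cohorts.

## The synthetic cohort generator

The generator emulates an ageing neuroimaging cohort at the level the
pipeline consumes, not at the level of raw images:

- **Time series.**  Each subject contributes a node × time matrix
  (default 296 timepoints, matching a 300-volume echo-planar acquisition
  with the first four volumes dropped) over a parcellation of `P` nodes in
  `K` networks (defaults emulate a 400-node, 7-network scheme; experiments
  use smaller parcellations of the same shape).  The series are Gaussian
  with a block-exchangeable correlation matrix built from a global factor,
  one factor per network, and white node noise:
  `x_i = sqrt(ρ_b)·g + sqrt(ρ_w − ρ_b)·f_net(i) + sqrt(1 − ρ_w)·e_i`.
  This is the smallest structure that makes segregation/integration
  meaningful, and it is positive semi-definite by construction.
- **Segregation.**  Each subject's within/between contrast is shifted by a
  single offset δ ~ N(0, `segregation_sd`), applied antagonistically
  (+within, −between), so one scalar indexes how segregated that
  subject's connectome is.  Offsets are clipped to the feasible range
  `0 ≤ ρ_b − δ ≤ ρ_w + δ < 1`.
- **Baseline correlations.**  Defaults are ρ_within = 0.35,
  ρ_between = 0.18.  The between value is deliberately clear of the
  per-edge detection threshold at T = 296 (r ≈ 0.114 at α = 0.05): when
  the baseline sits at the threshold, the surviving-edge truncation
  destroys the between-subject variance of the inter-network score and
  the measured segregation no longer tracks the planted one.  With these
  defaults the planted offsets correlate ≥ 0.9 with the measured
  network-level ratio scores.
- **Cognition.**  A latent cognition variable is a linear combination of
  the standardized segregation offset (`effect_beta`), standardized
  confounds (`confound_betas` for age, education, sex), and residual
  noise, normalized to unit variance.  A 14-test battery loads on two
  factors (nine "non-verbal/executive" tests, five "verbal" tests), both
  driven by latent cognition (weights 0.85 / 0.75) plus factor-specific
  and test-unique noise (`unique_sd` = 0.5).  Tests can be emitted on an
  inverted scale (higher = worse) and cells go missing completely at
  random at a configurable rate.
- **Confounds.**  Age is uniform on [55, 85]; sex is Bernoulli(0.5);
  education is a discretized normal on a 1–10 ordinal scale with mean 6.5
  and SD 1.9; a screening score (0–18) allows the ≤ 8 exclusion rule to
  be exercised.  Because the confounds are generated near-independent,
  target correlations with cognition are realized simply by using them as
  betas; achieved correlations are within ±0.08 of targets at n ≥ 500.
  Default emulation targets are r = −0.48 (age) and r = 0.40 (education).
  An optional `age_segregation_beta` couples age into the segregation
  offset so connectivity features can be made confound-driven.

What the generator does **not** emulate: haemodynamics, autocorrelated
noise, motion artefacts, atlas geometry, or any non-random missingness.
Passing tests therefore demonstrate correctness and calibration of the
pipeline's logic, not performance claims about real cohorts.

## Graph construction

Per subject: (i) Pearson correlation of every node pair; (ii) per-edge
significance against phase-randomized surrogates — the Fourier amplitude
spectrum of each node's series is kept, interior phases are replaced by
i.i.d. uniform draws (DC and Nyquist bins keep their real coefficients, so
the mean is preserved); the p-value is the add-one estimator
`p = (1 + #{|r_surr| ≥ |r_obs|}) / (n_surr + 1)` with 1,000 repeats by
default, two-sided; (iii) edges with p ≥ 0.05 set to zero; (iv) Fisher
r-to-z on the survivors, then a sign policy (`positive_only` default;
`abs_all` and `abs_negative_only` as variants).  No density or size
thresholding is ever applied; the diagonal is forced to zero so strength
sums exclude self-edges.

Two numerical choices matter.  Both series of an edge are independently
phase-randomized per draw (a symmetric null).  And surrogates are drawn
once per node per subject and reused across that subject's edges, making
the 1,000-repeat test O(P·n) instead of O(P²·n) randomizations; an exact
`per_edge` mode exists for small graphs.  Under the null the per-node
scheme rejects ~5% of edges at α = 0.05 (measured 5.0% over 20 seeds at
P = 10, T = 296).

## Strength features

Seven parameters per subject graph.  Nodal strength is the sum of incident
weights.  The within-network score of a node (or network) is the sum of
surviving same-network edge weights divided by the number of surviving
same-network edges — i.e. the mean surviving within-edge weight; the
inter-network score is the analogous mean over boundary-crossing edges;
the ratio within/inter indexes segregation.  Network-level sums count each
unordered edge once; "existing edges" is read as edges with nonzero weight
after thresholding, and the same surviving-edge denominator is used for
within and inter scores.  Any constant factor between alternative
denominator conventions is absorbed by the unit-variance scaling inside
the ML pipeline.  Zero denominators (a node or network with no surviving
edges of a kind) yield 0 and are logged, keeping the feature matrix
complete.

Four feature sets: `network_level` (3K), `strength_plus_network` (P + 3K),
`nodal_only` (3P), `all` (4P + 3K) — 21, 421, 1,200 and 1,621 columns at
P = 400, K = 7.  Feature order is fixed (nodal strength, nodal within,
nodal inter, nodal ratio, network within, network inter, network ratio).

## Cognitive targets

Screening drops subjects with a screening score ≤ 8, a missing screening
score, or more than three missing tests.  Remaining missing cells are
replaced by the median of that test within the subject's sex × age-band
cell (bands [55, 64], [65, 74], [75, 85]; ages outside the bands fall to
the nearest band).  Invert-flagged tests are negated, then every test is
z-scored (population-SD convention; sample-SD available).  The
Kaiser–Meyer–Olkin index is computed from the correlation and anti-image
partial-correlation matrices.

PCA runs on the test correlation matrix.  Retention is either
eigenvalue > 1 (domain components) or a forced single component (the
global cognition composite).  Varimax rotation is applied to loadings and
scores jointly for multicomponent solutions; signs are fixed so each
component's largest-magnitude loading is positive, and components are
ordered by explained variance.  Split-half stability re-fits the PCA on
random halves and reports the Pearson correlation of matched loadings;
matching uses the uncentered cosine (Tucker congruence) because centered
correlation cannot distinguish complementary block patterns.

Groups are a median split (ties assigned to "low", a fixed convention for
determinism) or extreme quartiles.  Propensity matching fits a logistic
model of group on age, sex and education, then greedily 1:1
nearest-neighbour matches on the logit without replacement with a caliper
of 0.2 logit-SD; the balance report carries standardized mean differences,
t-tests (age, education) and a chi-square test (sex) before and after.
These algorithmic details are common matching practice and are exposed in
the configuration.

## The benchmarking engine

A configuration names a task, algorithm (SVM linear/RBF/poly, KNN,
decision tree, Gaussian naive Bayes, LDA; SVR, kernel-ridge RVR
substitute, ridge, lasso, elastic net), feature-selection method, HPO
on/off, deconfounding mode, feature set, sample, and target.  Relevance
vector regression is represented by an RBF kernel ridge under the config
label `kernel_ridge_rvr_substitute`: the same kernel-regression family
without the sparse Bayesian solver, preserving the benchmark axis.

Evaluation is a repeated stratified 10-fold × 5-repeat outer CV (plain
k-fold for regression).  Per outer fold, in order: unit-variance scaling
fitted on the training block; confound regression (OLS on age, sex,
education with intercept, fitted on training data only) applied to
features and/or target per mode (nr / cr / nr-cr / cr-cr); feature
selection on the training block (ANOVA-F, mutual information or
correlation top-10% with a ceiling count; L1 linear-SVM sparsity; a hybrid
ANOVA-50% filter followed by sequential forward floating selection to
exactly 10 features; or embedded sparsity for lasso/elastic net); grid
search on an inner repeated 10 × 5 CV when HPO is on (grids: C over ten
log-spaced values 1e−4..1e1, ridge λ 1e−3..1e5, lasso/elastic λ
1e−1..1e2, elastic mixing 0..1 in ten steps, KNN neighbours 1..25 odd,
tree depth {4, 6, 8, 10, 20, 40, ∞} × {gini, entropy}; ties resolve
toward stronger regularization); then fit and predict.  A dummy reference
(majority train class / train mean) is fitted on every training fold, and
the fraction of folds where the model strictly beats the dummy (BAC for
classification, R² for regression) yields the robustness flag at the
> 80% level.  Metrics: sensitivity, specificity, BAC; MAE and test-fold
R² (which can be negative).

Every fitted transform is a function of the outer training fold only; a
unit test corrupts a test fold post hoc and asserts the fold's fitted
selection is unchanged.  An intentionally leaky mode (selection on the
full sample before CV) exists solely to demonstrate the inflation it
causes.

The engine enumerates its configuration space as a deterministic
Cartesian product minus invalid combinations (the correlation filter is
regression-only; embedded selection requires lasso/elastic net;
classification deconfounding is nr/cr, regression nr/nr-cr/cr-cr) and
reports its own count; no attempt is made to force a particular published
pipeline count, whose exact combinatorics are not enumerable.

## Calibration and recovery experiments

`netcog.experiments` runs the pipeline end to end at desk scale; the same
functions back `scripts/acceptance.py` and the acceptance tests.  Problem
sizes are the package's own choices:

- **Type-I calibration**: P = 10 white-noise nodes, T = 296, 1,000
  surrogates, 20 seeds; the fraction of edges with p < 0.05.
- **Null benchmark**: n = 200, P = 20, K = 4, no planted effect; mean BAC
  of the pure linear-SVM pipeline and the robust-flag rate over a
  20-config pure/filter grid.  Cohort-level experiments use 200 surrogate
  repeats (p-resolution 1/201, ample for the 5% threshold).
- **Signal recovery**: n = 300 with the planted segregation→cognition
  effect at R²_true = 0.5.  Classification uses the ANOVA-top-10% filter
  arm with a linear SVM; regression uses the HPO ridge arm — with ~90
  mutually correlated strength features a default-penalty fit underuses
  the signal, and exercising the FS/HPO arms is what the benchmark is
  for.
- **Leakage inflation**: 20 null cohorts (n = 60, P = 30) with
  `segregation_sd = 0`, so between-subject feature variance is pure
  finite-T estimation noise, independent across edges.  With a shared
  segregation factor the features collapse onto a few latent directions
  and whole-sample selection has little room to overfit; the independent
  regime is the one the leakage demonstration is about.
- **Deconfounding efficacy**: 20 cohorts where cognition is driven purely
  by age and features are age-coupled (`age_segregation_beta`);
  performance must drop from nr to cr (classification) and nr to
  nr-cr/cr-cr (regression).
- **PCA recovery/stability** (n = 800, 5% missingness) and **matching
  balance** (n = 500, planted age difference d ≈ 0.8) as described above.
- **SFFS correctness**: on separable toys (d = 8, k = 3) SFFS must return
  the exhaustive-search optimum; a constructed jointly-informative-pair
  problem shows the floating step recovering a pair where plain forward
  selection stalls.

## Known limitations

- The generator's white-noise timepoints understate the effective
  autocorrelation of real haemodynamic series; the surrogate test is
  calibrated for the data the generator produces.
- The per-node surrogate scheme reuses draws across a subject's edges;
  per-edge p-values are marginally correct but not mutually independent.
- Greedy caliper matching loses distribution tails even under identical
  group distributions (~10–25% of candidate pairs in practice).
- The RVR substitute is not a sparse Bayesian model; its config label is
  kept only to preserve the algorithm axis.
- Education is modelled as a 1–10 ordinal scale reproducing first and
  second moments only.
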