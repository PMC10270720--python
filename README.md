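# netcog

Can cognitive performance differences in older adults be classified or
predicted from the strength structure of resting-state functional
connectomes?  `netcog` is a tested, reusable implementation of the full
analysis chain behind that question, for methods researchers in network
neuroscience and neuroimaging-ML benchmarking:

1. **Graph construction** — per subject, Pearson correlations between
   parcellated node time series, per-edge significance against
   phase-randomized Fourier surrogates (1,000 repeats, edges with
   p ≥ 0.05 zeroed), Fisher r-to-z, positive weighting, and no density
   thresholding.
2. **Strength features** — node strength `s_i = Σ_j w_ij`, within- and
   inter-network connectivity (mean surviving edge weight inside a
   network vs across its boundary) and their segregation ratio, at nodal
   and network level; assembled into the four canonical feature sets
   (3K, P+3K, 3P, 4P+3K → 21, 421, 1,200, 1,621 at P=400, K=7).
3. **Cognitive targets** — screening, sex × age-band median imputation,
   inversion and z-scoring of a 14-test battery, KMO adequacy, PCA
   composites (eigenvalue > 1 or forced single component) with varimax
   rotation and split-half stability, median-split / extreme groups, and
   1:1 propensity matching with balance diagnostics.
4. **Leakage-safe ML benchmark** — repeated (nested) 10-fold × 5-repeat
   cross-validation over a grid of algorithms × feature selection × HPO ×
   deconfounding modes (nr / cr / nr-cr / cr-cr, with confound regression
   fitted on training folds only), with a dummy reference model per fold
   and a robustness flag requiring wins in > 80% of folds.

The study cohort the chain was designed around is not publicly deposited,
so the package includes a first-class synthetic-cohort generator with
planted ground truth (segregation→cognition effects, age/education
confounding, two-factor battery structure), making every downstream stage
testable end to end.  See `docs/methods.md` for the model and all
numerical conventions.

## Worked example

```python
import numpy as np
from netcog import synth, cognition, bench
from netcog.experiments import cohort_features, composite_target

# cohort with a planted segregation -> cognition effect (R²_true = 0.5)
parc = synth.make_parcellation(P=20, K=4)
spec = synth.CohortSpec(n_subjects=300, segregation_sd=0.08,
                        effect_beta=np.sqrt(0.5), seed=7)
cohort = synth.generate_cohort(parc, spec)

# graph -> strength features (92 features at P=20, K=4)
X = cohort_features(cohort, set_id="all", seed=7)

# global cognition composite and median-split groups
target = composite_target(cohort)
y = (cognition.make_groups(target).labels == "high").astype(int)

# leakage-safe benchmark: ANOVA top-10% filter + linear SVM, 10x5 CV
cfg = bench.PipelineConfig(task="classification", algorithm="svm_linear",
                           fs_method="anova_f_top10", seed=7)
res = bench.evaluate(cfg, X.to_numpy(), y.to_numpy())
print(f"mean BAC {res.aggregate['mean_bac']:.3f} "
      f"dummy wins {res.dummy_win_fraction:.0%} robust={res.robust}")
```

Output:

```
mean BAC 0.732 dummy wins 100% robust=True
```

A mean balanced accuracy of ~0.73 across the 50 outer folds, beating the
majority-class dummy in every one (> 80% ⇒ robust), is what a genuinely
planted effect of this size looks like through the full pipeline; on a
null cohort (`effect_beta=0`) the same pipeline sits at BAC ≈ 0.50 and the
robust flag stays off.

A CLI mirrors the stages (`netcog simulate | graph | features | cognition
| bench | report`), reading a YAML config with a mandatory master seed and
writing plain-text artifacts (TSV tables, JSON manifests).

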