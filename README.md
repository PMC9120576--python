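# mkfbn

Functional brain network classification from ROI time series with a
multi-kernel SVM over connection weights and graph-theory features.

`mkfbn` is aimed at researchers doing connectome-based case/control
classification — e.g. distinguishing a clinical group from controls
using resting-state fMRI parcellated into regions of interest.  It
implements the whole analysis as a reusable, tested pipeline:

1. **Network estimation.** For each subject with regional time series
   `x_1, …, x_n ∈ R^t`, the functional brain network is the Pearson
   matrix

   W_ij = (x_i − x̄_i)ᵀ(x_j − x̄_j) / ( ‖x_i − x̄_i‖ · ‖x_j − x̄_j‖ ).

2. **Proportional thresholding.** `W` is binarized over a sparsity grid
   (default 0.02–0.50, step 0.01 → 49 levels); at sparsity `s` exactly
   `round(s·n(n−1)/2)` of the strongest edges are kept, so the graphs are
   nested.

3. **Graph measurements.** On every binary graph: 11 global measures
   (characteristic path length L_p, clustering C_p, normalized λ and γ
   against degree-preserving rewired null networks, small-world
   σ = γ/λ, global/local efficiency, modularity Q, assortativity A_r,
   hierarchy H_r, synchronization S_r) and 5 nodal measures (degree,
   nodal efficiency, betweenness, shortest path length, nodal
   clustering).  Each metric curve is aggregated over the grid into one
   AUC feature (the sum of the per-threshold values).

4. **Multi-kernel SVM.** Three feature blocks — connection weights
   (n(n−1)/2 features), global AUCs (11) and nodal AUCs (5n) — each get a
   standardized linear kernel k_m; the classifier solves the soft-margin
   dual on Σ_m β_m k_m with β on the probability simplex and predicts
   sign( Σ_i y_i α_i Σ_m β_m k_m(x_i, x) + b ).

5. **Nested leave-one-out validation.** Each subject is held out once;
   t-test feature selection (p < 0.05), standardization, kernel
   normalization and the (C, β) grid search (C ∈ 2⁻⁵…2⁵) all use the
   remaining subjects only.  Performance is reported as accuracy,
   sensitivity, specificity and ROC AUC for seven configurations
   (C, G, N and their combinations); correlated AUCs are compared with
   DeLong's test.

6. **Group analysis.** Group-mean networks, hub tables (top fraction of
   regions by weighted degree or betweenness), consensus connections
   (edges selected in every validation fold), and per-metric group
   contrasts.

A synthetic-cohort generator (`simulate_cohort`) draws two groups of
multivariate-normal ROI time series whose population correlation
matrices differ on a configurable set of planted edges, so the entire
pipeline is exercisable — and its selection/validation machinery
falsifiable — without any imaging data.

## Worked example

```python
import mkfbn
from mkfbn.io import compute_cohort_features

spec = mkfbn.CohortSpec(
    n_regions=20, n_timepoints=170, n_group_pos=12, n_group_neg=12,
    planted_edges=((0, 5), (1, 6), (2, 7)), effect_size=0.35, seed=7,
)
cohort = mkfbn.simulate_cohort(spec)
grid = mkfbn.SparsityGrid(0.10, 0.50, 0.05)
features, matrices = compute_cohort_features(
    cohort, grid, mkfbn.NullModelConfig(n_nulls=10, seed=0)
)
result = mkfbn.loocv_run(
    features, mkfbn.MethodConfig("C+G+N"),
    mkfbn.HyperGrid(beta_step=0.2), inner_repeats=3, seed=0,
)
metrics = mkfbn.confusion_metrics(result)
roc = mkfbn.roc_auc(result.decision_values, result.true_labels)
print(f"accuracy    {100 * metrics['accuracy']:.2f}%")
print(f"ROC AUC     {roc.auc:.4f}")
consensus = mkfbn.consensus_connections(result.masks, features)
print(consensus.intersection[["region_i", "region_j", "frequency",
                              "direction", "max_p"]].head(4).to_string(index=False))
```

prints

```
accuracy    79.17%
ROC AUC     0.8889
region_i region_j  frequency direction        max_p
  ROI003   ROI008        1.0 increased 1.410381e-08
  ROI001   ROI006        1.0 increased 3.664373e-08
  ROI002   ROI007        1.0 increased 1.100913e-07
  ROI010   ROI016        1.0 decreased 7.446739e-03
```

The three planted edges (ROI001–ROI006, ROI002–ROI007, ROI003–ROI008)
are selected in every leave-one-out fold and correctly flagged as
*increased* in the positive group; the combined three-kernel classifier
separates the groups at 79% accuracy with an ROC area of 0.89 on this
24-subject cohort.

## Command line

```bash
mkfbn simulate --config cohort.yaml --out cohort/      # synthetic cohort
mkfbn estimate --manifest cohort/manifest.csv --out nets/
mkfbn run --config pipeline.yaml                       # full pipeline
```

`run` writes connectivity matrices, feature tables, per-fold records,
the seven-method summary, the pairwise DeLong matrix, consensus
connection tables, hub tables and group contrasts under the configured
output directory; every table carries the hash of the generating
configuration and identical config + seed reruns are byte-identical.

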