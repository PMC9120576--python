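# Methods

This note documents the models, conventions and numerical choices behind
`mkfbn`, what the synthetic-cohort generator does and does not emulate,
and the desk-scale problem sizes used in the test suite.

## Network estimation and thresholding

A subject's functional brain network is the Pearson correlation matrix
of their regional time series; the diagonal is set to exactly 1 and the
matrix is symmetrized to remove floating-point asymmetry.  No Fisher
z-transform is applied anywhere: connection features are the raw
correlations, which is what the classifier consumes.

Binarization is proportional: at sparsity `s` the `round(s·n(n−1)/2)`
edges with the largest **signed** correlations are kept (ranking by
absolute value is available via `absolute=True` / the
`absolute_ranking` config key).  Signed ranking means negative
correlations enter the binary graph only after every positive one —
at the default grid they effectively never do.  Rounding is
half-away-from-zero; ties at the cut are broken by ascending `(i, j)`
edge index so the stack is reproducible bit-for-bit.  Because all 49
graphs are cut from one global edge ranking, the stack is nested by
construction.

## Graph measurements

Global: characteristic path length `Lp` (mean shortest-path distance
over *reachable* unordered pairs — low-sparsity graphs are necessarily
disconnected and infinite distances are excluded), clustering `Cp`
(mean nodal clustering, degree-<2 nodes contributing 0), global
efficiency (mean of 1/d over all pairs, 1/∞ = 0), local efficiency
(mean over nodes of the global efficiency of the open neighborhood
subgraph), modularity `Q` (greedy agglomerative CNM partition),
assortativity `Ar` (Pearson correlation of endpoint degrees over both
orientations of every edge; undefined and flagged on degree-regular
graphs), hierarchy `Hr` (negated slope of the least-squares fit of
log C_i on log k_i over nodes with k_i ≥ 2 and C_i > 0; flagged when
fewer than two eligible distinct degrees exist), synchronization `Sr`
(Laplacian eigenratio λ₂/λ_max).

`γ = Cp / ⟨Cp_null⟩` and `λ = Lp / ⟨Lp_null⟩` normalize against an
ensemble of degree-preserving rewired graphs (default 100 nulls, 10
double-edge-swap attempts per edge, seeded).  A graph admitting no
valid swap (a lone triangle, a star) is its own ensemble, so γ = λ = 1.
When both the graph and its nulls have zero clustering the ratio is
likewise taken as 1.

Nodal: degree, nodal efficiency, betweenness (pair-dependency
accumulation, unordered pairs, endpoints excluded), shortest path
length (mean distance to reachable nodes; 0 for an isolated node),
nodal clustering.

**AUC aggregation.** Each per-threshold metric curve is reduced to a
single feature as the *sum* of its values over the grid (mode `"sum"`);
a step-weighted mode (`step × sum`, i.e. a rectangle rule) is available
because published per-metric magnitudes are sometimes only consistent
with step weighting.  Undefined global values (flagged `Ar`/`Hr` on
degenerate graphs) are imputed as 0 at aggregation with a warning; they
are rare outside adversarially small graphs.  Two reported metrics
deserve a caveat: modularity is bounded in [−0.5, 1] and the Laplacian
eigenratio in (0, 1]; published tables occasionally print values far
outside these ranges for identically named quantities, which cannot be
reproduced from the standard definitions used here — this package
reports the standard definitions only.

## Feature blocks and selection

Per subject: connection weights (upper triangle, lexicographic (i, j)
order; 4005 at 90 regions), global AUCs (11, fixed report order), nodal
AUCs (metric-major × region; 450 at 90 regions).  Within every
cross-validation fold each block is filtered by a two-sample
pooled-variance t-test at α = 0.05 on the training subjects only
(Welch optional).  No multiple-testing correction is applied at
selection, matching the uncorrected p < 0.05 convention; the group
tables additionally emit a Benjamini–Hochberg column.  If nothing in a
block survives, the whole block is kept unselected and the fold is
flagged: falling back to the single best feature would maximize the
winner's curse and measurably depresses held-out accuracy.

Consensus connections are reported two ways — the strict all-fold
intersection (the default table) and the union with per-edge selection
frequencies — because "selected during the entire validation process"
admits both readings.  Each edge is annotated with the sign of the
positive-minus-negative group mean difference; the most significant
consensus edge minimizes the worst-case (max over folds) p-value.

## Multi-kernel SVM

Per block: features are z-scored with training-fold statistics
(population σ; zero-variance features dropped), the linear Gram matrix
is divided by the mean of its training diagonal so blocks of very
different dimensionality are scale-commensurable, and test rows reuse
the training statistics and normalizer.  The combined kernel is
Σ β_m k_m with β ≥ 0, Σβ = 1.

The dual is solved by sequential minimal optimization with second-order
working-set selection — the classical libsvm scheme — stopping at a KKT
violation gap of 1e−6 (warm restarts with exact gradient recomputation
guard against incremental-rounding stalls on near-singular kernels; the
tolerance relaxes in two bounded steps before a convergence error is
raised).  The bias is the mean of the free support vectors' KKT
conditions, or the midpoint of the feasible interval if none is free.
`f = 0` is assigned to the negative class.  A vertex β reproduces the
single-kernel SVM exactly, which is how the single-block baselines are
computed.

**Hyperparameter search.** Exhaustive grid over C ∈ {2⁻⁵, …, 2⁵} and β
on the simplex (default step 0.1 → 66 candidates for three blocks),
scored by stratified inner cross-validation (5 folds, fixed seed;
`repeats` averages several shuffled splits).  Candidates are ranked by
the **mean per-fold ROC area of the inner decision values**, with ties
going to the most uniform β, then the C nearest 1 on the log scale,
then the smaller C.  Ranking by thresholded inner accuracy is unsafe
under leave-one-out: the training set is one subject short in the
held-out class, and a bias-dominated small-C model then earns a
guaranteed (n/2)/(n−1) > ½ accuracy from its intercept alone while
misclassifying nearly every held-out subject of a balanced cohort.  The
threshold-free ROC criterion values any constant or bias-dominated
model at ½ and so never prefers it to a candidate with genuine ranking
skill.

## Validation and comparison

Outer validation is leave-one-out; all training computation (selection,
scaling, kernel normalization, tuning) excludes the held-out subject.
Accuracy, sensitivity and specificity follow the usual confusion-matrix
definitions with the case-like group as positive; zero denominators
yield NaN rather than exceptions.  ROC curves are built from the
continuous decision values; the AUC equals the normalized Mann–Whitney
statistic.  DeLong's test uses the midrank formulation of the
structural components with a two-sided normal p-value; identical score
vectors give p = 1 by convention.  A paired-bootstrap oracle backs the
implementation in the test suite.

## Synthetic cohorts

`simulate_cohort` draws each subject's series from a zero-mean
multivariate normal with its group's population correlation matrix,
plus independent Gaussian noise on the series.  The shared base
structure is a random sparse symmetric matrix (default density 0.25,
weights U[0.2, 0.5]) repaired to positive definiteness by eigenvalue
flooring and re-standardization; the case-like group's matrix is
shifted by `effect_size` (or per-edge `planted_effects`) on the planted
edges and repaired again.  Defaults mirror a 90-region parcellation,
170 retained volumes and a 45/47 case/control split.  The base density
of 0.25 produces group-mean networks with realistic non-identity
structure without crowding out planted effects; the default noise SD of
0.5 attenuates all correlations by a factor 1/(1+0.25) = 0.8,
a mild, uniform measurement-noise analogue.

What the generator does **not** emulate: temporal autocorrelation,
band-pass structure, hemodynamics, motion artifacts, site effects, or
any noise process that differs between feature blocks.  One consequence
is worth stating plainly: in this generator every group difference
lives in the correlation matrix, which *is* the connection feature
block, and the graph features are deterministic functions of it.
Passing tests therefore demonstrate the integrity of the machinery
(no leakage, calibrated selection, correct solvers) — they do not
demonstrate that combining kernels beats the best single block on real
data, where complementary noise structure across blocks is the
plausible source of that advantage.  In our experiments the tuned
combination consistently tracked the best single block minus a small
model-selection cost (0.03–0.1 accuracy) across every scenario tried,
so the corresponding qualitative-ordering check is expected to fail
under simulation; the chance-level (zero-effect) calibration of all
seven configurations is the check the generator can and does support.

## Desk-scale problem sizes

The heavy nested-validation tests run at reduced scale chosen for
CI-sized budgets: 5-level sparsity grid (0.10–0.50 step 0.10), 3
rewired nulls, β step 0.2 with 3 repeated inner splits, cohorts of
30–40 subjects with 30–60 regions and 100–170 timepoints.  The null
calibration uses 10 seeds and the planted-effect comparison 20 seeds.
`scripts/acceptance.py` uses a 9-level grid, 5 nulls and a 30-subject
cohort and completes in about a minute.

## Known limitations

- Modularity uses deterministic greedy agglomeration; it can miss the
  optimal partition on adversarial graphs (the brute-force oracle in the
  tests covers the small-graph cases).
- `Hr` and `Ar` are undefined on degenerate graphs and imputed as 0 in
  AUC aggregation.
- The SMO solver targets cohort-scale problems (tens to hundreds of
  subjects); it makes no attempt at large-scale performance engineering.
- LOOCV at chance level is systematically slightly pessimistic (selection
  and exclusion effects); observed null accuracies center near 0.42–0.50,
  not exactly 0.5.
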