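# Methods

This note documents the models, procedures, numerical choices, and known
limitations behind `chemgroup`, in the spirit of a package methods appendix.

## Input handling and curation

Structures are parsed with RDKit. SDF records are delimited on `$$$$`; a
record whose mol-block RDKit cannot parse is flagged rather than silently
dropped, so the removed-rows report can enumerate every removal with a
reason (`unreadable_structure`, `missing_value`, `conflicting_duplicate`,
`duplicate`) and the conservation identity n_input = n_retained + n_removed
holds for every file. CSV/XLSX files must carry a column named `SMILES`
(case-insensitive); anything else requires an explicit `smiles_column`,
because silently guessing a structure column misreads data.

Labels are declared, not inferred: `binary` accepts {0,1} or exactly two
distinct strings mapped by sorted order (the mapping is recorded in the
manifest); `multiclass` maps distinct values to 0..C−1 the same way;
`continuous` coerces to float. Rows with missing structures or (in labeled
runs) missing labels are removed — no imputation. Continuous label
summaries use 10 equal-width histogram bins between the observed min and
max, a deliberately simple deterministic rule.

## Standardization

The standardizer re-implements the usual QSAR-ready preparation rules with
RDKit's `rdMolStandardize` primitives, in a fixed order: functional-group
normalization (nitro groups to the charge-separated form, valence
corrections), largest-organic-fragment selection (a structure with no
carbon-containing fragment fails with "no organic fragment"), charge
neutralization (balanced zwitterions such as nitro are left intact),
RDKit's canonical-tautomer scheme, stereochemistry removal, and a final
sanitization + canonical SMILES. The tautomer scheme is recorded in the
manifest (`rdkit-canonical`) because descriptor bit counts downstream are
mildly sensitive to the scheme choice.

Duplicates (identical canonical SMILES) collapse to the first occurrence.
When labels conflict within a duplicate group, *all* members are removed:
keeping either label would silently bias a supervised run, and the removal
is visible in the report. Standardization is on by default and can be
disabled per run.

## Descriptors and scaling

Fingerprints: Morgan (circular, default radius 3, 2048 bits), FeatMorgan
(same generator with pharmacophoric feature invariants), MACCS (the
166 informative keys; the implementation's padding bit 0 is stripped).
Continuous descriptors come from the RDKit 2-D descriptor engine in two
tiers — `compact` (physico-chemical descriptors, fragment counts excluded;
~125 columns) and `extended` (the full RDKit 2-D list; ~217 columns). The
backend name, version, and per-set descriptor count are recorded in the
manifest because column counts are version-sensitive. Columns containing
any non-finite value across the dataset are dropped entirely (a partial
column would corrupt every distance computation downstream); the drop list
is recorded.

Scaling is per column with parameters stored for exact replay on new data:
min–max to [0,1]; z-score with population sd; decimal scaling by the
smallest j ≥ 0 with max|x|/10^j ≤ 1, found by an exact integer loop rather
than logarithms to avoid floating-point edge cases at powers of ten.
Constant columns map to zeros under min–max/z-score (they are removed by
any variance filter anyway). Defaults: no scaling for binary fingerprints,
min–max for continuous descriptors — the 0–0.1 variance grid below is only
meaningful on a common scale, and whether variance should be computed on
raw or scaled descriptors is an open choice we fix as "scaled" and record.

## Dimensionality reduction

The low-variance filter uses population variance (divide by n) and removes
a column when variance ≤ threshold, so threshold 0 removes exactly the
constant columns. The correlation filter is a greedy ordered pass: for each
pair (i < j) with |Pearson r| above the threshold and both columns still
alive, the later column j is removed. The pass is order-dependent by
construction; keeping the earlier column is an arbitrary but deterministic
tie-break, which matters more here than the particular choice.

The automated threshold search evaluates a grid (default 0.00–0.10 in
steps of 0.01) exhaustively: filter, fit the chosen learner, score accuracy
(classification) or R² (regression) on a stratified 80/20 holdout or
5-fold CV, apply the best threshold to the full matrix, and keep the whole
trace. A grid point that removes every column is recorded in the trace with
a null score and skipped. **Caveat:** the 0–0.1 grid is sensible for
variance but, used as a *correlation* cutoff, removes nearly all features;
the grid is therefore configurable and the default should be raised (e.g.
0.80–0.99) for correlation filtering in practice.

## Supervised feature selection

All three selectors score candidate subsets by seeded, stratified
cross-validation; AUC for RFE/SA, accuracy for the GA, R² for regression.

- **RFE** refits the learner each iteration and drops the
  max(1, ⌊0.2·p_current⌋) least-important columns, refreshing the ranking
  every time; the best-scoring subset along the elimination path is
  returned. Importance source per family: native impurity importances for
  tree ensembles, |coefficients| for linear models, seeded permutation
  importance for KNN/SVM/naive Bayes (those expose no native ranking).
- **GA** evolves boolean column masks: tournament selection (size 3),
  uniform crossover with probability 0.5, and mutation applied to an
  offspring with probability 0.2, flipping each bit with probability 0.05.
  A two-level mutation rate (per-individual, then per-bit) keeps the
  expected perturbation at ~1% of bits per generation; flipping 20% of all
  bits every generation would destroy convergence. The best-ever mask is
  tracked elitistically, so the reported trace is non-decreasing, and
  fitness values are cached by mask.
- **SA** starts from a random half of the columns and proposes one move per
  iteration (add / replace / remove, uniform among feasible moves). Better
  subsets are always accepted; worse ones with Metropolis probability
  exp(Δ/T). The temperature cools geometrically by 0.95 per iteration and
  the run stops at 50 iterations or T < 0.01 (0.95⁵⁰ ≈ 0.077, so the
  iteration cap binds for the default schedule). The initial temperature
  defaults to min_temperature / 0.95⁵⁰ ≈ 0.13, chosen so the schedule
  spans the full iteration budget and ends exactly at the floor: since the
  objective deltas are cross-validated score changes of order 0.01, this
  makes early acceptance permissive and late acceptance selective, which
  is the standard way to scale an SA temperature to its objective.

## Grouping and tuning

The tuning objective is the mean silhouette coefficient
SI = (b − a)/max(a, b) with Euclidean distances, a = 0 for singleton
clusters (the standard convention), and noise points (label −1) excluded.
Trials that produce fewer than 2 effective clusters or more than 50% noise
score −1: without that penalty, density-based methods inflate their
silhouette by declaring most points noise. A brute-force double-loop
implementation of the same definition lives in the test suite and must
agree with the vectorized version to 1e−9.

Clusterers: K-means and agglomerative clustering via scikit-learn (the
hierarchical path consumes a precomputed Euclidean or Manhattan distance
matrix and cuts to a requested cluster count, making k tunable like the
other methods); DBSCAN and HDBSCAN via scikit-learn; K-medoids as an
in-package PAM-style alternating optimizer with k-medoids++ seeding —
medoids are always dataset points. Projections: PCA, UMAP, t-SNE, always
to 2-D, seeded.

Hyperparameters are searched with an in-package Tree-structured Parzen
Estimator: after a 10-trial random start-up, trials are split into the top
25% ("good") and the rest; each dimension is modeled independently by
Parzen mixtures (Gaussian kernels at the observations plus a uniform prior
component, bandwidth (high−low)/√(m+1)); 24 candidates drawn from the good
density are ranked by the good/bad density ratio. Integer dimensions round
and clip; categorical dimensions use Laplace-smoothed count ratios. In
discrete spaces the density ratio can converge onto an already-evaluated
configuration; since the objective is deterministic per configuration and
trial seed, such duplicate proposals are wasted trials and are replaced by
a random draw. The sampler maximizes and is fully determined by its seed
and history.

Two search modes: *projected* clustering tunes projection and clusterer
jointly, scoring the silhouette on each trial's 2-D embedding; the
non-projected mode first tunes the clusterer in full descriptor space,
then freezes those parameters and tunes the projection, re-clustering each
trial embedding. The returned labels come from the best embedding-space
trial (matching how the projected data is described as the clustering
input), while the full-space stage-1 labels are kept in the result for
comparison. Default ranges: k ∈ [2, 25], UMAP min_dist ∈ [0.01, 0.25] and
n_neighbors ∈ [2, 50], 50 trials. One master seed deterministically derives
per-trial seeds (`numpy.random.SeedSequence`); the winning trial's seed is
stored in the manifest so a rerun can reproduce the labels bit-for-bit
without repeating the search.

## SHAP attribution

Three computation routes by learner family:

- **Exact tree attributions** for LightGBM models via the booster's native
  per-feature contribution output: row sums plus the base value reproduce
  the raw margin to ~1e−14, which the tests assert at 1e−6.
- **Closed-form linear Shapley values** for logistic regression:
  φ_ij = w_j (x_ij − μ_j) against the background mean μ.
- **Permutation-sampling Shapley values** otherwise, against a fixed
  background sample (≤ 50 training rows) with a seeded permutation set.
  Because each permutation's contributions telescope to
  f(x) − f(background row), the efficiency axiom holds *exactly* per
  sample relative to the sampled background mean; symmetry holds only up
  to sampling noise (tested at 10% on duplicated features with 400
  permutations).

Binary classification keeps the positive-class block only; multiclass
problems concatenate per-class blocks column-wise (n × p·C, names suffixed
`__class{c}`) before clustering. The learner behind SHAP grouping and
interpretation is fitted on all rows — its use is explanatory, not
predictive, so no holdout is taken.

Cluster interpretation fits one multiclass classifier on cluster labels
(noise rows excluded) and ranks each cluster's descriptors by mean |SHAP|
of that cluster's one-vs-rest attribution block among its own members,
with the sign of the mean attribution reported as the direction. The text
summarizer's template backend is deterministic; an external backend (e.g.
a remote LLM) is an injection point with the same signature and falls back
to the template with a warning when unavailable — no remote calls are made
by the package itself.

## Manifest, replay, and report

The manifest is a schema-versioned JSON document holding the input
descriptor, every option and seed, and all stage results; content is
coerced to JSON-native types at insertion so save → load is an exact
round trip. Rerun mode replays a manifest on a (possibly new) dataset:
filters re-apply the stored thresholds, selection re-applies the stored
column list, and grouping runs a single shot with the stored winning
parameters and trial seed instead of a new search. View mode renders the
stored results without touching any compute stage (a stage counter makes
this assertable). Report bundles are byte-stable: CSVs use fixed %.6g
formatting, JSON keys are sorted, and SVGs use a fixed hash salt with no
embedded date.

## Synthetic generators and what they do (not) show

- `make_feature_blobs`: k unit-variance Gaussian blobs with centers a
  configurable number of standard deviations apart along random orthogonal
  directions — used for clustering/tuning recovery (at separation 20 the
  planted partition is unambiguous; at 0 the silhouette of the true labels
  is ≈ 0).
- `make_labeled_features`: standard-normal features where the first
  p_informative columns drive a logistic / softmax / linear-plus-noise
  label with alternating-sign coefficients of magnitude `effect`. The
  selector-recovery conditions follow the planted-fixture convention used
  throughout: n = 500, 5 informative among 50, effect 2.0.
- `make_smiles_families`: valid SMILES enumerated by decorating scaffold
  cores (benzene, cyclohexane, pyridine, naphthalene, THF, thiophene) with
  a curated substituent list — string templates guarantee chemical
  validity without a generative model — plus counterion-bearing and
  duplicated variants at stated fractions.

These fixtures establish algorithmic correctness (recovery of planted
structure, axiom satisfaction, replay fidelity). They do **not** emulate
real chemical datasets: descriptor correlation structure, activity cliffs,
class imbalance, assay noise, and scaffold diversity of real libraries are
absent, so passing tests say nothing about how well a particular clustering
of a real dataset reflects biology — that judgment remains with the user,
which is why every stage exposes its trace and interpretation output.

Test and acceptance-script problem sizes (n of a few hundred, tens of
trials, 512–1024-bit fingerprints) are chosen as the smallest sizes at
which the planted structure is unambiguous and recovery is stable across
seeds.

## Known limitations

- The continuous-descriptor backend is RDKit-only; column counts from
  other descriptor engines (Mordred, PaDEL) will differ, so published
  counts tied to those engines are not directly comparable.
- UMAP determinism is guaranteed only for a fixed seed on a fixed
  platform/version; cross-platform bit-identity of embeddings is not.
- The correlation filter's printed default grid is kept for fidelity but
  is rarely what you want (see above).
- K-medoids uses alternating optimization, not full PAM swap search; for
  small k the results coincide in practice, but the global optimum is not
  guaranteed (neither does PAM).
- Sampling SHAP cost grows as O(n · permutations · p) model evaluations;
  for large matrices prefer the LightGBM family, whose attributions are
  exact and fast.
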