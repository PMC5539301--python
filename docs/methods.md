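# Methods

## The inference model

MALANI treats network inference as a supervised feature-selection
problem in the space of pairwise expression products. Let
**M**<sub>G×S</sub> be the gene × sample intensity matrix after
per-sample normalization (each column divided by its total, so columns
sum to 1 and within-sample ratios are preserved), with binary labels
y ∈ {cancer, normal}. A pair (i, j) is *class-informative* when the
per-sample product x<sub>i</sub>·x<sub>j</sub> distinguishes the
classes even if neither marginal does — the situation produced by a
coordinator whose co-expression with a partner switches sign between
conditions: for jointly log-normal genes, cov(i, j) enters
E[x<sub>i</sub>x<sub>j</sub>] multiplicatively, so a correlation switch
shifts the product's class-conditional mean and variance.

The three stages (gene-wise scan → partner scan → ensemble vote) are a
computational funnel: the full G² pair space is never scored directly;
instead k·G·(1 + (G−1)/20) classifier fits reduce it to R ≤ 10·⌈0.05·G⌉
candidates before the five-method vote.

## Cross-validation and classifiers

Folds are class-stratified: within each class, seed-shuffled samples
are dealt round-robin into k portions (sizes differ by ≤1, every
portion holds both classes). Fold f tests portion (f−1) mod k — the
first training fold holds out the *last* portion — so fold rotation is
reproducible bit-for-bit from the seed.

The classifier contract (`ClassifierSpec`) defaults to C-classification
SVM with RBF kernel, cost 1 and gamma = 1/n_features, with per-feature
standardization estimated on each training fold (the default behaviour
of the reference R implementation of this SVM, which scales variables
unless told otherwise). Balanced accuracy is available for imbalanced
cohorts; plain accuracy is the default metric everywhere.

**Stage 1 defaults to the random-forest family** rather than the SVM.
The gene-wise matrix of a coordinator gene contains very few
class-informative rows (its own pair product, plus weaker linker
products) among G−1. An isotropic kernel dilutes a single informative
coordinate by 1/(G−1) inside the exponent, and we measured the
consequence directly during development: with G = 300 and 60 samples
the RBF-SVM's CV accuracy on coordinator gene-wise matrices is
indistinguishable from background (≈0.51 for both), whereas a bagged
random forest — which evaluates features axis-aligned and one at a
time — separates them cleanly (coordinators ≈0.87, background tail
≈0.8). Sparse-relevant-feature regimes are exactly where axis-aligned
ensembles are expected to dominate kernel methods, and the algorithm is
explicitly classifier-agnostic, so the pipeline uses the forest for the
gene-wise scan and keeps the RBF-SVM (cost 1, gamma = 1/F) for the
two-feature pair models and the product-matrix models, where it excels.
Both choices are configurable per stage.

The forest is LightGBM's bagged ("rf" boosting) mode: 50 trees,
bagging fraction 0.8, feature fraction 0.25 per tree, minimum leaf size
3, single-threaded and deterministic. Tree count and feature fraction
were chosen for ranking quality per CPU-second at the desk-scale study
size (thousands of fits per run); both are exposed on `ClassifierSpec`.
SVM fits go through scikit-learn's low-level libsvm bindings when
available (identical models; the test-suite asserts prediction
agreement with `SVC`), because the pair scan fits tens of thousands of
tiny models per run.

## The synthetic study

The generator emulates the minimal data-generating process the method
claims to resolve, with machine-readable ground truth:

* **Background genes**: i.i.d. log-normal; log-intensity mean 5.0 and
  standard deviation 1.0 (arbitrary units; per-gene log-sd of this
  magnitude is typical of cross-patient tumour cohorts).
* **Fold-change (class I) genes**: n_up = n_down = 10 genes with the
  cancer log-mean shifted by ±log(3).
* **Coordinator pairs (class II)**: each pair (a, b) shares a
  per-sample two-state latent z = ±1 (a pathway on/off switch). Gene a
  always loads +λz; gene b loads +λz in cancer and −λz in normals.
  Residual noise has sd 0.3 and λ = 0.3·√(0.9/0.1) = 0.9, fixing the
  within-class correlation magnitude at exactly ρ = 0.9. Both marginals
  are class-invariant by construction. The on/off states are drawn
  *balanced within each class* (equally many +1 and −1 samples up to
  rounding): this removes state-frequency drift from class means, so
  coordinator fold-change estimates stay near 1 at n = 30+30 (worst
  observed ratio 1.32 over 400 gene × seed draws, safely inside the 1.5
  DE criterion) while the product signal — which lives in the
  within-sample co-occurrence of states, not their frequency — is
  untouched. A Gaussian latent is available via `latent="gaussian"`.
* **Linker genes**: one per pair, loading the pair's latent with the
  same sign flip as gene b at a weaker loading (0.25) and the same
  small residual noise. This mirrors the biology the method targets —
  coordinators act through partners, not in isolation — and gives the
  fixed-loading gene a second informative product row. Linker marginals
  are likewise class-invariant; linkers are never mutated by the
  mutation generator, so they surface as additional class II genes.
* **PPI graph**: connected preferential-attachment (Barabási–Albert)
  graph over all genes, m = 2 edges per new node; the five
  highest-degree nodes are recorded as mediator candidates.
* **Mutation table**: a configurable fraction (default 15%) of genes
  receive 1–4 types from the ten-type vocabulary; coordinator and
  linker genes are excluded so the class II ground truth stays clean.

Calibration: λ = 0.9 is the smallest loading (on our grid) at which the
construction satisfies both marginal invisibility (per-gene two-sample
t-test at α = 0.01 rejected in 0 of 100 seeds) and product visibility
(pair-product t-test rejected in 99% of seeds at n = 30+30) — the two
defining properties of the planted signal.

**What the generator does not emulate**: probe-level measurement noise,
batch structure, correlated background co-expression modules,
tissue-specific signatures, or realistic mutation co-occurrence. Tests
passing on these data show the pipeline recovers the planted
differential-correlation mechanism under log-normal noise; they do not
certify performance on real cohorts, where background correlation makes
both the signal and the false-positive structure richer.

## Downstream definitions

* **DE status**: ratio of class means of normalized intensities;
  up if cancer/normal > 1.5, down if normal/cancer > 1.5 (threshold
  configurable; 1.0 turns any inequality into a call). Zero means are
  guarded by a 1e-12 pseudocount with a warning.
* **Class II** = in the MIN ∧ not DE ∧ no mutation record;
  **class I** = in the MIN ∧ (DE ∨ mutated); everything else is
  outside_network. The three labels partition the gene universe.
* **Hubs**: degree ≥ 6 ("connectivity higher than 5" read strictly).
* **PIE-MIN**: per MIN edge, one unweighted shortest PPI path (BFS;
  equal-length ties resolved to the lexicographically smallest node
  sequence, so outputs are deterministic). Node frequency counts
  pass-through (interior) nodes by default; endpoints switchable.
  Pairs with missing endpoints or disconnected components are recorded
  by status and skipped.
* **Landscape**: per-mutation-type gene counts over PIE-MIN genes and
  cumulative direct-neighbour counts (sum of PPI degrees, multiplicity
  kept); multi-type genes carry ≥3 distinct types. With per-gene
  p-values supplied, candidates (class II or DE genes in the PIE-MIN)
  above the candidates' third-quartile p-value induce the reported
  subnetwork — the parametric per-gene p-values from the evaluation
  module feed this filter.
* **Permutation test**: a permutation test of an adaptive pipeline is
  only calibrated if the *selection* is repeated under every permuted
  labelling — re-evaluating the model picked on the true labels
  produces α ≈ 0 even on pure noise (we measured exactly that during
  development). Re-running the full funnel per permutation is
  prohibitive, so the default statistic runs a fast surrogate of it,
  nested inside the cross-validation: per fold, every pair product is
  scored by its pooled-|t| on training samples only, anchors → partners
  → top-fraction cuts mirror the pipeline's theta/partner/vote
  fractions, and the classifier fitted on the selected training rows is
  scored on the held-out portion. The identical procedure is applied
  to observed and permuted labels (M = 20, each permutation with its
  own stratified folds), giving an honest generalisation estimate and
  a calibrated Monte-Carlo p. α = #{|permuted| ≥ |observed|}/M without
  smoothing, so α = 0 is possible and the CI α ± 1.96·√(α(1−α)/M) then
  collapses to [0, 0]. The fixed-pair statistic (CV accuracy of the
  final selected model's product rows) remains available for
  descriptive reporting.
* **Enrichment**: upper-tail hypergeometric P(X ≥ k) with Bonferroni
  correction across categories; the MIN filter keeps the top 10
  categories by raw p with ≥3 query genes, the PIE-MIN filter keeps
  adjusted p < 0.05 with ≥5 genes. Categories with r ≤ 1 are still
  reported, flagged as not enriched.

## Numerical and design notes

* "Dot product" matrices are per-sample (Hadamard) products — the only
  reading consistent with the (G−1)×S shape; true inner products would
  collapse the sample axis.
* |Θ| = ⌈0.05·G⌉ (ceiling, so Θ is never empty); ranking ties break by
  dataset gene order, making selection deterministic.
* Stage 2 partners include other Θ genes; symmetric duplicates merge
  before stage 3, so R = 10·|Θ| is an upper bound.
* The per-method "selection" feeding the 3-of-5 vote is an explicit
  top-⌈0.1·R⌉ cut per method (configurable `top_frac`); votes are
  monotone in both `top_frac` and `min_votes`.
* IG/SU use 10 equal-frequency bins (duplicate quantiles merged) and
  plug-in entropies in bits; Relief-F uses k = 10 neighbours, all
  samples, Manhattan distance on range-normalized features; SVM-RFE
  standardizes once and drops the lowest-|weight| 10% of remaining
  features per iteration until one survives.
* Per-gene p-values: pooled-variance two-sided t-test (Welch by flag);
  zero-variance genes get p = 1 with a warning.
* All randomness flows from one root seed through named substreams
  (generator) or stage-name-derived seeds (pipeline), so re-running any
  stage with the same config reproduces its outputs byte-for-byte.

## Problem sizes

The shipped study conditions are desk-scale: G = 300 genes, 30+30
samples, 5 coordinator pairs, 10+10 fold-change genes, k = 10 folds.
One full pipeline run fits ~3 000 forest models (stage 1), ~45 000
two-feature SVMs (stage 2) and ~150-row ensemble scoring (stage 3) in
about 80 s on one CPU. The genome-scale formula k·G·(1+(G−1)/20)
documents why the original analyses required cluster hardware; nothing
in the package assumes more than a laptop.

## Known limitations

* Stage-1 sensitivity to a coordinator depends on its informative
  product rows; a coordinator whose only signal is a single pair row
  sits at the detection floor of any gene-wise scan, and pairs whose
  both members miss Θ cannot be recovered downstream.
* The vote threshold `top_frac` is a surrogate for an unspecified
  per-method "selection" rule; results are reported with vote counts so
  other cuts can be re-derived from the score tables.
* Fisher's hub/class-II test conditions on the observed network; it is
  a descriptive association test, not a generative model of hub
  formation.
* Cohort-level numbers from real arrays (thousands of MIN genes,
  cross-cancer sharing counts) are outside the synthetic scope by
  design.
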