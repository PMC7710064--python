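# Methods

## Problem setting

`hierpheno` predicts, for each gene, a score in [0, 1] for every class of
a phenotype ontology, from the gene's (ancestor-closed) set of GO
annotations and optional per-tissue expression values. Both GO and HPO
are treated purely as `is_a` DAGs: annotation to a class implies
annotation to all its ancestors (true path rule), so every corpus is
propagated before counting, training or evaluation. Other relationship
types (e.g. `part_of`) are ignored with a warning — the phenotype
ontology is `is_a`-structured and nothing downstream consumes other
axioms. Obsolete terms are dropped at parse time; `alt_id` values resolve
to their primary id and `replaced_by` on an obsolete term is followed
once.

## The classifier

The network is `dense(reduction, ReLU) → dropout → concat(expression) →
dense(sigmoid, k classes)`, followed in hierarchical mode by the
classification layer `h(y)ᵢ = max { yⱼ : pⱼ ⊑ pᵢ }` computed with the
reflexive subclass indicator matrix. The layer is idempotent, monotone,
never decreases a score, and makes outputs ontology-consistent by
construction. During training the gradient of the loss flows through the
maximising descendant of each class (max-pooling routing).

Choices a practitioner may want to change, with defaults:

| parameter | default | rationale |
|---|---|---|
| hidden layers | one layer, 1024 units | inside the 250–4000 search grid; ample for desk-scale corpora |
| dropout | 0.5 | regularises the sparse GO block |
| optimiser / lr | Adam, 1e-3 | standard multi-label setting |
| batch size | 32 | small-corpus friendly |
| max epochs / patience | 150 / 5 | early stopping on validation loss; best weights restored |
| loss | mean binary cross-entropy over (gene, class) cells | natural for sigmoid multi-label output; in hierarchical mode it is computed on the post-layer scores, so the hierarchy constraint shapes training |
| seed | explicit everywhere | same seed + single-threaded run reproduces scores to ~1e-6; cross-platform bit-exactness is not promised |

A random-search helper samples layer widths from {250, 500, …, 4000},
dropout from {0.2, 0.5} and learning rate from {0.01, 0.001, 0.0001},
selecting by validation loss. Expression features join *after* the
reduction layer: the reduction is there to compress the very sparse GO
block, which the short dense expression vector does not need; the
concatenation point is configurable in principle by editing the feature
blocks.

The network itself is implemented directly on numpy with hand-written
gradients. At the corpus sizes this package targets (10²–10⁴ genes,
10²–10⁴ classes) this is fast, dependency-light and fully deterministic
under a seed.

Degenerate inputs: training aborts with an error if no class has a
positive label, and with diagnostics if the loss goes non-finite;
prediction rejects a feature matrix whose GO vocabulary or expression
width differs from training.

## Dataset construction

* Predictable classes: phenotype classes with ≥ 10 annotated genes in the
  *training* portion (configurable); ontology roots are excluded from the
  predictable set and from all metrics — a root is annotated to every
  gene after propagation and carries no information.
* Evaluation label space: the union of all truth classes and all
  predictable classes. Classes the model cannot predict count as false
  negatives; predictions outside the truth universe count against
  precision.
* GO evidence filtering (GAF input): the experimental/curated code list
  EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP;
  NOT-qualified rows are always dropped.
* Expression: per-gene z-score (mean 0, sd 1) across tissues, then
  missing values set to 0; genes without an expression record get an
  all-zero row; constant rows map to all zeros. "Normalise by genes" is
  deliberately interpreted as the z-score — it removes per-gene scale
  while keeping the tissue profile shape.
* Splits are by gene: a gene carries all its annotations into exactly one
  of train/validation/test. Defaults: 5 folds whose test blocks tile the
  gene list (20% each), 10% of the remaining genes as validation
  (72/8/20 on 100 genes).

## Metrics

Threshold grid t ∈ {0, 0.01, …, 1.00}; a class is predicted for a gene
when its score is **strictly** greater than t.

* Fmax: precision is averaged over the m(t) genes with ≥ 1 prediction,
  recall over all n genes; thresholds with m(t) = 0 are skipped and an
  all-zero predictor scores Fmax 0 by convention.
* Smin: min over t of √(ru(t)² + mi(t)²), with ru/mi the mean total
  parent-conditional IC of missed / wrongly predicted classes. The
  conditional IC of class c is −log Pr(c | all parents of c), the
  multi-parent denominator being the genes carrying *every* parent
  (set intersection). Zero-probability classes get IC 0 rather than ∞ so
  Smin stays finite; the log base (default 2) is configurable and scales
  Smin's magnitude.
* AUPR: trapezoidal area under the recall-sorted (AvgRc(t), AvgPr(t))
  grid points, anchored at recall 0 with the lowest-recall precision
  (so a perfect predictor scores 1.0); a micro-averaged variant over the
  flattened gene × class matrix is available behind a flag.
* Term-centric AUROC: per class with at least one positive and one
  negative gene, mid-rank tie handling (a constant score column scores
  exactly 0.5), unweighted mean over evaluable classes.

## Semantic similarity and disease ranking

Resnik similarity uses corpus-marginal IC, −log(n_c/n), computed by
default on the training-gene phenotype annotations; disease annotation
sets enter only as query sets. A class absent from the IC corpus falls
back to the maximum observed IC (the most conservative finite
specificity). BMA is the mean of the two directed best-match averages.
Candidate diseases are ranked per gene with mid-rank tie handling —
with heavily tied scores (e.g. identical naive annotation sets) the
mid-rank convention is what keeps the expected AUROC at 0.5. The
per-pair AUROC is (n_candidates − rank)/(n_candidates − 1), macro-averaged
over true pairs; Hits@k is the percentage of pairs ranked ≤ k.

## Interaction-overlap permutation test

For each phenotype, the statistic is the fraction of predicted-but-
unannotated (false positive) genes adjacent to at least one known gene
of that phenotype in the interaction network (edges kept at combined
score ≥ 0.7; STRING's 0–999 scale is auto-detected and rescaled). The
null replaces each predicted set by a uniform random gene set of equal
size from the gene universe; with 1,000 permutations the add-one rule
p = (1 + #{null ≥ observed})/(1 + N) avoids p = 0. Phenotypes with no
false positives or no known genes are skipped in the mean.

## Synthetic data

`gen_ontology` draws a single-rooted is_a DAG (each class picks 1..k
parents among earlier classes). `gen_planted` gives every leaf phenotype
a rule — a set of `rule_size` non-root GO classes — and labels a gene
with that phenotype iff its propagated GO set contains the whole rule;
labels are then flipped with probability `noise_rate` and closed under
ancestors. Genes acquire each rule's classes with probability 0.1 plus 5
random background classes, so leaf phenotypes end up with realistic
double-digit positive counts at the default 300-gene corpus. The
expression block is standard normal plus a fixed random unit direction
(length 1.0 sd) per phenotype a gene is labeled with, making expression
mildly informative.

What the generator does *not* emulate: the long-tailed class-frequency
spectrum of real HPO corpora, inter-annotation dependencies beyond the
planted rules, GTEx-like tissue covariance, and annotation
incompleteness (real "negatives" are unlabelled, not false). Passing the
planted-recovery tests therefore demonstrates that the machinery — 
propagation, feature building, training through the hierarchy layer,
evaluation — is correct, not that real-data performance will reach the
same numbers.

## Problem sizes in the shipped tests

The test suite trains on planted corpora of 120–500 genes with 40–100
phenotype classes and completes in well under a minute per training; the
oracle-equivalence suites use 100–200 random DAGs of up to 60 nodes.
These sizes were chosen as the smallest at which every behaviour under
test (class selection at the ≥ 10-gene threshold, early stopping,
threshold-grid effects) is actually exercised.

## Known limitations

* Only `is_a` structure is used; cross-ontology axioms and other
  relations are out of scope.
* The classifier cannot predict classes below the minimum-gene
  threshold; they are retained in evaluation as guaranteed misses.
* Training-time hierarchy enforcement routes gradients through a single
  maximising descendant per class and step, which can slow convergence
  on very deep ontologies.
* The numpy implementation is single-machine and CPU-bound; corpora of
  ~10⁵ genes × ~10⁴ classes would need minibatched sparse inputs and a
  GPU framework.
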