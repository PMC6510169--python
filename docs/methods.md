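# Methods

## The classification model

`chanpred` treats ion-channel annotation as a three-stage decision
procedure over fixed-length sequence descriptors. Stage 1 is a binary
channel / non-channel model; sequences called channels go to stage 2
(voltage- vs ligand-gated); voltage-gated calls go to stage 3 (K / Ca /
Na / anion). Each stage is an independent model with its own feature
configuration (encoder, optional MRMD selection, backend and
hyperparameters), trained only on the instances it would see at decision
time. Errors therefore compound down the cascade: a sequence misrouted at
stage 1 can never be recovered later. This mirrors how the decision is
made in practice and keeps each training problem small and
class-homogeneous.

Backends are scikit-learn's `SVC` (RBF kernel) and
`RandomForestClassifier`. The method's own contributions — the encoders,
the MRMD scoring, the cascade protocol, the pooled-confusion metrics — are
implemented here.

## The 188-D CTD descriptor

Block layout (fixed, exposed via `feature_names_188()`):

* 20 amino-acid composition percentages, residues in alphabetical order
  (ACDEFGHIKLMNPQRSTVWY);
* for each of eight physicochemical properties, 21 values:
  3 group-composition percentages, 3 transition percentages (group pairs
  (1,2), (1,3), (2,3), denominator L − 1), 15 distribution values (per
  group: scaled positions of the 1st, ⌈0.25m⌉-th, ⌈0.50m⌉-th, ⌈0.75m⌉-th
  and m-th occurrences, m = group occurrence count).

The three-group residue partitions per property are the classical CTD
assignments (hydrophobicity: polar RKEDQN / neutral GASTPHY / hydrophobic
CLVIMFW, and so on). They ship as `data/ctd_groups.tsv` — a plain table
(property, group1, group2, group3) — rather than constants in code, so they
are inspectable and the partition invariant (three disjoint groups covering
the alphabet) is validated at load time and in tests.

Numerical conventions, chosen once and fixed:

* **Quantile rule.** The 25/50/75% occurrence indices use the ceiling rule
  ⌈q·m⌉ (floor or rounding would be equally defensible; ceiling makes the
  five indices coincide at m = 1 and keeps the quintuple nondecreasing).
* **Empty group.** A property group with no occurrences contributes five
  zeros; this keeps vectors comparable across sequences.
* **Length-1 edge.** Transitions on a length-1 sequence are defined as 0
  rather than an error; sequence validation (minimum length, below)
  normally excludes such inputs anyway.

## The 400-D k-skip-2-gram descriptor

The positional distance between residues at positions i < j is
DT = j − i − 1 (the number of residues strictly between them). For gap a,
the pair set joins positions (i, i + a + 1) for every i with both ends in
range. The descriptor pools gaps a = 1..k into one multiset and normalizes
each ordered pair's count by the multiset size; pairs are directional
(AC ≠ CA), giving exactly 20² = 400 entries that sum to 1 whenever any
pair exists.

* **k** has no canonical value; the default is k = 2 and the value is
  recorded in every run config so experiments are reproducible.
* **Gap 0** (contiguous dipeptides) is excluded from the pooled union by
  default, matching the definition of the union over a = 1..k; some
  published skip-gram implementations include it, so a
  `include_zero_gap` flag is provided.
* Only n = 2 is supported; n ≥ 3 (20ⁿ features) is rejected with a clear
  configuration error.

## Sequence validation

Only the 20 standard residues are accepted. Ambiguity codes X, B, Z — and
likewise J, O, U — cause rejection, as does any other non-alphabet
character. Sequences shorter than 10 residues (configurable) are rejected
because the distribution quantiles degenerate on very short sequences.
Lower-case input is upper-cased rather than rejected. The FASTA reader is
permissive (duplicate ids pass through); strictness lives in the dataset
constructor, which enforces unique ids and scheme-conformant labels.

## MRMD feature selection

For feature f with column x_f and integer-encoded labels y (0..C−1 in
first-seen order):

* relevance MR_f = |Pearson r(x_f, y)|; a zero-variance column gets
  MR = 0 by convention;
* distance MD_f = mean over three metrics of f's average distance to every
  other column, computed on min-max-scaled columns so the metrics act on
  commensurate scales: Euclidean distance divided by √n_instances, cosine
  distance 1 − cos, and Tanimoto distance 1 − x·y/(|x|² + |y|² − x·y).
  Zero-vector conventions: two all-zero columns are identical (distance 0);
  a zero column against a nonzero one is maximally distant (distance 1).
* score_f = w_r·MR_f + w_d·MD_f with unit weights by default (the weights
  are exposed); ranking is by descending score with ties broken by
  original column order (stable).

How the three distances are combined is a genuinely open design point; the
arithmetic mean is used here, and the tests pin the whole computation
against an independent loop-based reimplementation to 1e-12. Encoding
multi-class labels as integers for a Pearson correlation is a known
semantic weakness of the method on the 4-way stage; it is retained as the
method's standard formulation rather than silently "fixed".

Subset size is either explicit (m) or automatic: nested prefixes of the
ranking on a 5%-of-features grid are scored by seeded cross-validated OA
with a random forest, and the smallest size within one standard error of
the best is kept (the one-SE rule trades a little accuracy for a smaller,
more robust feature set).

## Cross-validation and metrics

Stratified k-fold (default 10) with a seed; fold assignment is keyed on
instance ids sorted lexicographically, so shuffling the input rows cannot
change the pooled result. If the smallest class has fewer members than
folds, the fold count is reduced to it with a logged warning. Min-max
scaling and any MRMD selection are refitted inside each training split —
no statistic of held-out data reaches the model, and a regression test
verifies that this differs from a deliberately leaky variant on
outlier-dominated data.

Metrics are computed on the confusion matrix pooled over all folds:
Sn(i) = TP_i/(TP_i + FN_i)·100, OA = Σ TP_i/N·100, AA = mean of the
defined Sn(i). An empty true-class row has undefined sensitivity; it is
reported as NaN and excluded from AA with a warning. OA is algebraically
the row-total-weighted mean of the Sn values, which the tests check on
random matrices.

SVM hyperparameters (c, g) are found by an exhaustive grid search scored
by cross-validated OA; ties resolve to the smallest c, then the smallest
g, so the search is deterministic. The default grids span the LIBSVM
conventions c = 2⁻⁵..2¹⁵ and g = 2⁻¹⁵..2³ in powers-of-two steps of 2²
(the coarse grid; a finer step quadruples the search for little gain at
these data sizes). Grid search is an explicit, separate operation; the CV
evaluator scores a stated (c, g) pair, keeping runtime bounded and the
reported metric attached to a concrete parameter choice. Random forests
default to 100 seeded trees. Class imbalance in the subtype stage is left
as-is (no resampling), matching how per-class sensitivities are usually
reported for this task.

Model bundles (three stage models, scalers, selected feature names,
configs, package version) serialize with joblib; loading refuses bundles
written by a different major format version.

## The synthetic-data generator

`benchmark_like_profiles()` emulates the class structure of the curated
benchmark this method family is evaluated on: 81 K, 29 Ca, 12 Na, 26 anion,
150 ligand-gated and 300 non-channel sequences (598 total), lengths uniform
on [50, 500] — a range wide enough to exercise the distribution quantiles.
Each class's residue-frequency vector is a uniform base (0.05 per residue)
with extra mass δ on a class-specific disjoint triple of signature
residues; δ = 0.10 ("high" separation, every pair of profiles ≥ 0.3 apart
in total-variation distance) or δ = 0.02 ("low"). Sequences are drawn
i.i.d. from the class profile with lengths uniform on the range; the whole
dataset is a deterministic function of (profiles, seed).

What this emulates — and what it does not. The generator produces
compositionally distinct classes with realistic lengths and class sizes,
which is exactly what compositional encoders and the cascade need for
end-to-end verification and parameter-recovery tests. It has no positional
structure, no motifs, no transmembrane topology, and no homology/redundancy
structure; passing tests therefore demonstrate that the pipeline recovers
planted compositional signal, not that real channel classes are separable
at these accuracies. Accuracy figures on synthetic data (e.g. the
near-perfect OA in the README example) must not be read as estimates of
performance on real proteins. Redundancy removal of real datasets
(CD-HIT-style clustering) is out of scope and delegated to the external
tool.

## Problem sizes in the automated runs

The test suite and `scripts/acceptance.py` use the full 598-sequence
benchmark-like dataset for the stage-level cross-validation checks and
smaller draws (5–12 sequences per class, lengths 50–80) for cascade and
CLI round-trip checks; the normalization suite covers 1000 random
sequences and the oracle-equivalence suites a few hundred random cases.
These sizes were chosen so the whole verification cycle runs in well under
a minute each while keeping every statistical check comfortably powered.
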