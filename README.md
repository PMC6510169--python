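# chanpred

Sequence-based prediction of ion channels and their types.

Ion channels — membrane proteins that form gated pores for passive ion
transport — are major drug targets, and annotating a new protein sequence as
a channel (and as which kind of channel) is a recurring task in target
discovery. `chanpred` implements a hierarchical classifier for this task:

1. **Stage 1** — is the sequence an ion channel at all?
2. **Stage 2** — if so, is it voltage-gated or ligand-gated?
3. **Stage 3** — if voltage-gated, is it a K⁺, Ca²⁺, Na⁺, or anion channel?

Each stage is an ordinary supervised model (RBF-kernel SVM or random
forest) over fixed-length numeric descriptors of the protein sequence.

## The descriptors and the selection method

**188-D CTD descriptor.** The 20 amino-acid composition percentages
E_i = A_i / L × 100, followed by a 21-value block for each of eight
physicochemical properties (hydrophobicity, normalized van der Waals
volume, polarity, polarizability, charge, surface tension, secondary
structure, solvent accessibility). Each property partitions the 20 residues
into three groups; its block holds the three group **c**omposition
percentages, the three adjacent inter-group **t**ransition frequencies
T_{g,h} = (transitions between groups g and h) / (L − 1) × 100, and the
**d**istribution positions of the first, 25%, 50%, 75% and 100% occurrences
of each group, scaled by L. Total 20 + 8 × 21 = 188.

**400-D k-skip-2-gram descriptor.** All ordered residue pairs whose
positional distance DT(A_i, A_j) = j − i − 1 lies in 1..k are pooled into a
multiset T; the feature for pair p is N(p) / N(T). With 20² = 400 ordered
pairs this gives a 400-entry frequency vector (it sums to 1). The two
descriptors can be fused into a 588-column matrix.

**MRMD feature selection.** Each feature is scored by relevance (absolute
Pearson correlation with the class labels) plus distance (mean of
Euclidean, cosine and Tanimoto distances to the other feature columns, a
measure of non-redundancy); the top-scoring subset is kept.

**Evaluation.** Seeded stratified 10-fold cross-validation; per-class
sensitivity Sn(i) = TP_i / (TP_i + FN_i), overall accuracy
OA = Σ TP_i / N, and average accuracy AA = mean_i Sn(i), computed on the
pooled confusion matrix.

## Worked example

No curated channel benchmark is bundled; the `simulate` command generates a
synthetic dataset with the same six-class structure (81 K, 29 Ca, 12 Na,
26 anion, 150 ligand-gated, 300 non-channel sequences) and class-distinct
residue-frequency profiles, so the whole pipeline can be exercised
end to end:

```sh
chanpred simulate --out-dir demo --seed 7 --separation high
chanpred extract demo/sequences.fasta --out demo/ctd.tsv --encoder ctd188
chanpred evaluate demo/ctd.tsv demo/labels.tsv --out demo/report.tsv \
    --backend random-forest --folds 10 --seed 7
```

which prints

```
              method     Sn.Ca  Sn.K  Sn.Na  Sn.anion  Sn.ligand  Sn.non-ion        OA        AA
random-forest (188D) 96.551724 100.0  100.0     100.0      100.0       100.0 99.832776 99.425287
```

one row per (feature set, backend): the per-class sensitivities, the
overall accuracy (99.8% of the 598 sequences correctly classified across
all six classes) and the average of the per-class sensitivities. The
accuracies are near-perfect because the "high" separation setting plants
strongly class-distinct residue compositions — the point is pipeline
verification, not biological realism (see `docs/methods.md`).

A full cascade is trained and applied the same way:

```sh
chanpred train-cascade demo/sequences.fasta demo/labels.tsv --out demo/model.joblib
chanpred predict demo/sequences.fasta demo/model.joblib --out demo/predictions.tsv
```

`predictions.tsv` holds, per sequence, the final label and the per-stage
decision trail (e.g. `ion>voltage>K`; non-channels stop after stage 1).

Everything is also available as a library (`chanpred.extract_188`,
`chanpred.extract_kskip`, `chanpred.select_subset`, `chanpred.cross_validate`,
`chanpred.train_cascade`, ...).

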