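# Methods

## Problem and data model

The toolkit classifies candidate lysine glutarylation sites from local
sequence context alone. A sample is a window of 23 residues with the
candidate lysine at the center (11 residues of flank on each side); sites
closer than 11 residues to a protein terminus are padded with the unknown
symbol `X`. Labels are binary: glutarylated (1) or not (0). Benchmark
datasets of this kind are strongly imbalanced, roughly four negatives per
positive, and arrive pre-split into a training set and an independent test
set.

Window extraction uses 1-based site positions in user-facing I/O and
0-based indices internally. Non-standard residue codes (B, Z, U, O, J) are
mapped to `X` with a warning, keeping the alphabet closed at 20 letters
plus one pad symbol.

## Descriptors

All encoders exclude `X` from every count: it enters no numerator or
denominator, no adjacency (CTDT), and no correlation product (PAAC/APAAC);
positional descriptors (CTDD) index the `X`-stripped sequence. The
alternative — assigning fabricated property values to an unknown residue —
would silently distort exactly the terminal windows where padding occurs.

* **AAC** — frequency of each of the 20 residues, in the fixed order
  `ACDEFGHIKLMNPQRSTVWY`.
* **EAAC** — AAC computed inside each width-5 window sliding left to right
  over the *padded* sequence (so the number of windows, L−5+1 = 19, is the
  same for every sample); an all-`X` window contributes 20 zeros.
* **CTDC / CTDT / CTDD** — 13 physicochemical attributes each partition
  the alphabet into 3 groups. Composition is the group frequency;
  transition is the rate of adjacent inter-group switches,
  (N(rs)+N(sr))/(N−1) for each unordered pair; distribution records, per
  group, the position of the 1st, ⌈0.25k⌉-th, ⌈0.50k⌉-th, ⌈0.75k⌉-th and
  k-th occurrence divided by N (k = occurrence count; absent groups give
  five zeros; values are fractions in [0,1], not percentages). Three of
  the commonly reprinted group tables do not partition the alphabet; this
  package restores the canonical groupings: C belongs to the smallest
  van-der-Waals-volume group (normalized volume 2.43), polarizability
  group 2 is `CPNVEQIL`, and the solvent-accessibility "exposed" group is
  `RKQEND`. The corrected table is asserted at import time to be a
  partition.
* **PAAC (λ = 15, w = 0.05)** — the 20 frequencies extended with λ tier
  correlation factors τ_k, where τ_k averages over all residue pairs k
  apart the mean squared difference of Γ = 3 standardized scales
  (hydrophobicity, hydrophilicity, side-chain mass). All 20+λ entries
  share the denominator Σf + w Στ, so the vector sums to 1 and reduces
  exactly to AAC when w = 0 or λ = 0.
* **APAAC (λ = 15, w = 0.05)** — the amphiphilic variant: for each tier j,
  one factor averages products of standardized hydrophobicities and one of
  standardized hydrophilicities, giving 20+2λ entries. The tier-j
  denominator is L−j throughout, and even-indexed factors use the
  hydrophilicity scale — the alternating pattern of the definition.
* **Scales.** The numeric hydrophobicity (Eisenberg-normalized),
  hydrophilicity (Hopp–Woods) and side-chain-mass tables are the canonical
  ones used by standard descriptor suites, standardized to zero mean and
  unit population variance over the 20 residues before use. Different but
  reasonable scale choices shift PAAC/APAAC values slightly; the tables
  live in `encoders.PAAC_SCALES` and can be swapped.
* **λ = 15** is forced by the declared PAAC/APAAC widths (35 = 20+λ,
  50 = 20+2λ); **w = 0.05** is the conventional default of the descriptor
  literature.

Feature ordering is globally fixed — block order as given in the encoder
spec, then the intra-block orders above — so serialized matrices are
bit-stable, and every feature carries a block-qualified name
(`ctdd.Polarity.g2.q50`) that doubles as the model's input fingerprint.

## Embeddings

Protein language-model backends supply one embedding row per residue
(width 1024, or 4096 for ProtAlbert). Rows are pooled to a fixed-width
peptide vector by **column summation**; mean pooling exists behind a
switch but is off by default, summation being the convention this
pipeline follows. Special begin/end token rows, if a backend emits them,
are expected to be stripped before pooling so the row count equals the
peptide length. Pooled vectors are cached on disk keyed by (backend name,
sequence SHA-1). Real backends need the optional `transformers`/`torch`
stack and a model download; the deterministic `mock` backend — each row a
pure function of (residue identity, position, seed) — exercises the
identical pooling, caching and concatenation code without any download,
which is what the test suite uses.

## Imbalance handling and evaluation protocols

Random under-sampling discards randomly chosen majority-class samples
without replacement until both classes match the minority count; it
applies to whichever class is the majority. Every stochastic operation
takes an explicit seed, and repeated protocols derive per-repeat seeds as
`base_seed + repeat_index`, so the resampling randomness being averaged
over is enumerable and every reported mean is bit-exactly reproducible.

* **Cross-validation** (k = 10, 3 repeats): folds are disjoint, near-equal
  (sizes differ by at most 1) and reshuffled per repeat. The k−1 training
  folds are combined and *then* under-sampled; the held-out fold is never
  resampled, so reported metrics reflect the deployment class ratio. Folds
  are **stratified by class** by default — with ~19% positives,
  unstratified folds can degenerate to a single class — but stratification
  can be disabled (`stratified=False`) for strict random splitting. A
  hold-out fold with a single class has no defined AUC; such folds are
  excluded from the AUC mean with a warning.
* **Independent test** (5 repeats): per repeat, the full training set is
  under-sampled under a derived seed, a model is fitted and scored on the
  untouched test set; the mean over repeats is the result. Train/test
  sequence overlap is warned about, not rejected.

Metrics: Rec, Spe, Pre, Acc, MCC, F1 from the confusion matrix at
threshold 0.5, and AUC as the Mann–Whitney rank statistic with half
credit for ties — exactly the trapezoidal area under the threshold-swept
ROC curve, in O(n log n). Any 0/0 ratio (including the MCC denominator)
returns 0 with a warning, keeping aggregate means defined on degenerate
folds.

## Classifiers

Five interchangeable families: gradient-boosted trees (XGBoost), AdaBoost,
RBF-kernel SVM, random forest and MLP, all at library defaults with a
fixed seed — no hyperparameter search, since none of the grid's settings
are specified upstream and defaults are at least transparent. All expose
positive-class scores in [0,1]; the SVM's margins pass through a logistic
sigmoid rather than Platt scaling, keeping training deterministic while
preserving ranking (AUC) and the margin-sign decision at threshold 0.5.
Models persist with an embedded format version, spec echo and
feature-name fingerprint; prediction refuses matrices whose fingerprint
differs from training.

## Synthetic data generator

`simulate.generate_peptides` emulates the *structure* of a glutarylation
benchmark: length-23 windows, central `K`, binary labels, and a
controllable class signal. Negative flanking residues are uniform over the
20 letters (the simplest null, with analytic expectations); each positive
flanking residue comes with probability `bias_strength` from a
distribution concentrated on an enriched subset (`DE` by default) and
otherwise from the background. `bias_strength = 0` gives identically
distributed classes (CV AUC ≈ 0.5), `bias_strength = 1` with a small
subset gives near-perfect separability from composition alone, and the
empirical between-class AAC gap grows monotonically with the bias. The
default size, 100 positives to 425 negatives, mirrors a benchmark-like
~1:4.25 imbalance at a scale where full protocols run in seconds.

What the generator does **not** emulate: real glutarylation motifs,
position-specific conservation, homology structure between windows, or
any property embeddings could exploit beyond residue identity. Passing
tests therefore demonstrate that the pipeline's plumbing, protocols and
statistics are correct — not that any feature set predicts real
glutarylation at a particular level.

## Problem sizes used in checks

Protocol checks run at the benchmark's published composition — 2,103
training samples (400 positive / 1,703 negative, giving 10-fold sizes of
210–211 and a 400/400 under-sample) and 247 test samples (44/203) —
generated synthetically. Signal-recovery and null-calibration checks use
600-sample datasets (150/450) under 3×10-fold CV, sizes at which the
complete grid runs in well under a minute per model.

## Reproducing the published protocol on real data

The deposited benchmark (444 positive / 1,906 negative sites across the
train/test split above) and a multi-gigabyte ProtT5-XL-UniRef50 model are
required to reproduce the original headline numbers, and the original
classifier hyperparameters are unpublished, so exact cell values are not
claimed. The recipe: download the dataset's FASTA files, read them with
`read_peptide_table`; install `transformers`+`torch`, extract per-residue
embeddings from the last encoder layer (special tokens stripped), and
store them in the embedding cache; encode with
`EncoderSpec.parse("ctdd+eaac+prott5-xl-uniref50")`; then run
`cross_validate` (k = 10, 3 repeats) on the training set and
`independent_test` (5 repeats) against the test set with
`ModelSpec("gbt")` and random under-sampling.

## Known limitations

* PAAC/APAAC values depend on the scale tables; swap-in tables change
  third-decimal values.
* `probability`-style calibration is deliberately absent; scores are
  monotone in the learners' native outputs but not calibrated
  probabilities.
* The CTDD quantile index ⌈q·k⌉ (first-occurrence slot fixed at 1) is one
  of several conventions in circulation; alternatives shift values by at
  most one position.
* Threshold metrics use a fixed 0.5 cut; no threshold tuning is provided.
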