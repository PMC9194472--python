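# glutarkit

A toolkit for predicting **lysine glutarylation sites** from protein
sequence. Glutarylation is a post-translational modification in which a
glutaryl group attaches to a lysine residue; identifying modified sites
experimentally (mass spectrometry) is slow and costly, so sequence-based
classifiers are used to prioritize candidate sites. `glutarkit` provides
the full modelling pipeline for this problem as a reusable library plus a
thin CLI: peptide-window I/O, five classic descriptor families, pluggable
protein language-model embedding pooling, class-imbalance handling,
five classifier families, and resampling-aware evaluation protocols.

## The model

Each candidate site is a 23-residue window `R₁…R₁₁ K R₁₃…R₂₃` centered on
the lysine (terminal sites are padded with `X`). Windows are encoded by any
ordered combination of:

| Block | Width (L = 23) | Definition |
|---|---|---|
| AAC | 20 | residue frequencies f(t) = N(t)/N |
| EAAC | 380 | AAC within each width-5 sliding window, (L−5+1)·20 |
| CTDC | 39 | group frequencies over 13 physicochemical attributes × 3 groups |
| CTDT | 39 | adjacent inter-group transition rates (N(rs)+N(sr))/(N−1) |
| CTDD | 195 | positions of the 1st / 25% / 50% / 75% / 100% group occurrences, as fractions of N |
| PAAC | 20+λ | frequencies + λ tier correlation factors τ_k from standardized hydrophobicity/hydrophilicity/side-chain-mass scales (λ = 15) |
| APAAC | 20+2λ | frequencies + alternating hydrophobicity/hydrophilicity correlation products |
| embeddings | 1024 (4096 for ProtAlbert) | per-residue language-model embeddings summed over the sequence |

Training data is balanced by **random under-sampling** of the majority
class to 1:1. Classifiers: gradient-boosted trees (XGBoost), AdaBoost,
RBF-SVM, random forest, MLP. Evaluation follows two protocols with the
under-sampling *inside* the loop (the held-out data is never resampled):
10-fold cross-validation repeated 3×, and an independent test repeated 5×
over fresh under-samples. Seven metrics are reported: Rec, Spe, Pre, Acc,
MCC, F1 and ROC AUC (rank statistic, ties half-credited).

## Worked example

```bash
glutarkit simulate --n-pos 100 --n-neg 425 --bias-strength 0.6 --seed 1 \
    --out demo/train.fasta
glutarkit cv --data demo/train.fasta --encoder aac --model gbt \
    --k 10 --repeats 3 --seed 1 --out demo/cv.csv
```

The second command prints the mean over the 30 folds:

```json
{
  "mean": {
    "rec": 1.0,
    "spe": 0.9937430786267996,
    "pre": 0.9762626262626262,
    "acc": 0.9949322689888727,
    "mcc": 0.9848155750641842,
    "f1": 0.9874458874458875,
    "auc": 0.9996124031007751
  }
}
```

The simulated positives draw 60% of their flanking residues from an
enriched subset (`DE` by default), so a composition-based model separates
the classes almost perfectly — AUC ≈ 1 means a random positive outranks a
random negative essentially always, and specificity just under 1 means a
handful of negative windows happened to look acidic enough to cross the
0.5 threshold. At
`--bias-strength 0` the classes are identically distributed and the same
command reports AUC ≈ 0.5 (chance), which is the expected null behaviour.

The same machinery works as a library:

```python
import glutarkit as gk

ds = gk.read_peptide_table("demo/train.fasta")
result = gk.cross_validate(ds, gk.EncoderSpec.parse("ctdd+eaac"),
                           gk.ModelSpec("gbt", seed=1),
                           gk.ResampleSpec(seed=1), k=10, repeats=3, seed=1)
print(result.mean)
```

Real transformer embedding backends (ProtT5-XL-UniRef50, ProtBERT, ...)
are consumed through a width contract and an on-disk cache; they require
the optional `transformers`/`torch` stack and a model download. The
deterministic `mock` backend exercises the identical code path without
any download (`--encoder aac+mock:width=1024`).

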