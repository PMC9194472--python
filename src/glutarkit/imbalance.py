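"""Class-imbalance handling by random under-sampling.

The benchmark glutarylation dataset carries roughly four negatives per
positive; training on it directly biases classifiers toward the negative
class.  The strategy used here discards randomly chosen majority-class
samples (without replacement) until both classes are equal, leaving the
minority class untouched.  Every stochastic step takes an explicit seed
so repeated-evaluation protocols can enumerate their per-repeat seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide_io import Dataset


@dataclass(frozen=True)
class ResampleSpec:
    strategy: str = "random_undersample"
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("random_undersample", "none"):
            raise ValueError(
                f"unknown resampling strategy {self.strategy!r}; "
                "expected 'random_undersample' or 'none'")


def undersample_indices(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a 1:1 subset: all minority samples plus an equal-size
    random draw (without replacement) from the majority, shuffled."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("under-sampling needs both classes present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=len(minority), replace=False)
    idx = np.concatenate([minority, kept_majority])
    rng.shuffle(idx)
    return idx


def undersample(dataset: Dataset, spec: ResampleSpec) -> Dataset:
    """Balance a dataset according to the resampling spec.

    With strategy 'none' the dataset is returned unchanged; with
    'random_undersample' the majority class (whichever it is) is sampled
    down to the minority count and the result is deterministically
    shuffled under the spec's seed.
    """
    if spec.strategy == "none":
        return dataset
    labels = np.array([p.label for p in dataset])
    idx = undersample_indices(labels, spec.seed)
    return dataset.subset(idx.tolist())
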