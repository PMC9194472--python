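import numpy as np
import pytest

from glutarkit.peptide_io import ALPHABET, Peptide
from glutarkit.simulate import FixtureSpec, generate_peptides


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def window23(rng):
    """One random pipeline-ready window (length 23, central K)."""
    flanks = rng.choice(list(ALPHABET), size=22)
    seq = "".join(flanks[:11]) + "K" + "".join(flanks[11:])
    return Peptide(seq, label=1, center_index=11)


def random_sequences(rng, n, min_len=5, max_len=23, with_x=True):
    """Random residue strings, optionally salted with pad symbols."""
    letters = list(ALPHABET) + (["X"] * 3 if with_x else [])
    out = []
    while len(out) < n:
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(letters, size=length))
        if seq.strip("X"):  # at least one countable residue
            out.append(seq)
    return out


@pytest.fixture
def biased_dataset():
    """Separable synthetic dataset: positives drawn only from 'DE' flanks."""
    return generate_peptides(
        FixtureSpec(n_pos=150, n_neg=450, bias_residues="DE",
                    bias_strength=1.0, seed=11))


@pytest.fixture
def null_dataset():
    """Label-free null: identical class-conditional distributions."""
    return generate_peptides(
        FixtureSpec(n_pos=150, n_neg=450, bias_strength=0.0, seed=12))
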