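"""Sequence-window descriptor families and their ordered concatenation.

Five classic descriptor families are implemented over 23-residue
lysine-centered windows:

* **AAC** — global residue frequencies (20 values).
* **EAAC** — residue frequencies per sliding window of width 5
  (19 windows x 20 = 380 values on a length-23 peptide).
* **CTDC / CTDT / CTDD** — composition, transition and distribution
  descriptors over 13 physicochemical attributes, each partitioning the
  alphabet into three groups (39 / 39 / 195 values).
* **PAAC / APAAC** — pseudo and amphiphilic pseudo amino-acid
  composition: the 20 frequencies extended with lambda (resp. 2*lambda)
  sequence-order correlation factors built from standardized
  hydrophobicity, hydrophilicity and side-chain-mass scales.

The pad/unknown symbol 'X' is excluded everywhere: it contributes to no
count, no adjacency and no correlation term.  Feature ordering is fixed
(block order, then the canonical intra-block orders defined here) so
serialized matrices are bit-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .peptide_io import ALPHABET, PAD, Peptide

__all__ = [
    "FeatureVector", "EncoderSpec", "CTD_ATTRIBUTES", "PAAC_SCALES",
    "encode_aac", "encode_eaac", "encode_ctdc", "encode_ctdt", "encode_ctdd",
    "encode_paac", "encode_apaac", "concat_features", "encode_peptide",
    "encode_dataset",
]


@dataclass(frozen=True)
class FeatureVector:
    """An ordered numeric descriptor block with block-qualified names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"{len(self.values)} values but {len(self.names)} names"
            )

    def __len__(self) -> int:
        return len(self.values)


def _seq(pep: Peptide | str) -> str:
    return pep.sequence if isinstance(pep, Peptide) else pep


def _stripped(pep: Peptide | str) -> str:
    return _seq(pep).replace(PAD, "")


# ---------------------------------------------------------------------------
# AAC / EAAC
# ---------------------------------------------------------------------------

def encode_aac(pep: Peptide | str) -> FeatureVector:
    """Amino-acid composition: frequency of each residue, alphabet-ordered.

    'X' counts toward neither numerator nor denominator; an all-'X'
    sequence raises (zero denominator).
    """
    s = _stripped(pep)
    if not s:
        raise ValueError("cannot encode AAC: no countable residues (all 'X')")
    n = len(s)
    vals = np.array([s.count(a) / n for a in ALPHABET])
    return FeatureVector(vals, tuple(f"aac.{a}" for a in ALPHABET))


def encode_eaac(pep: Peptide | str, window: int = 5) -> FeatureVector:
    """Enhanced AAC: per-residue frequencies within each sliding window.

    Windows slide left to right over the full (padded) sequence; within a
    window 'X' is excluded from both counts and an all-'X' window yields
    20 zeros.  Output is (L - window + 1) blocks of 20, ordered by window
    start then alphabet.
    """
    seq = _seq(pep)
    L = len(seq)
    if not 1 <= window <= L:
        raise ValueError(f"window must be in [1, {L}], got {window}")
    vals, names = [], []
    for start in range(L - window + 1):
        chunk = seq[start:start + window].replace(PAD, "")
        denom = len(chunk)
        for a in ALPHABET:
            vals.append(chunk.count(a) / denom if denom else 0.0)
            names.append(f"eaac.w{start + 1}.{a}")
    return FeatureVector(np.array(vals), tuple(names))


# ---------------------------------------------------------------------------
# CTD: 13 physicochemical attributes, each a 3-way partition of the alphabet
# ---------------------------------------------------------------------------

# Canonical three-group divisions (Dubchak-style).  Three printed-source
# typos are corrected so every attribute partitions the alphabet exactly:
# vdW volume group 1 includes C (normalized volume 2.43), polarizability
# group 2 is CPNVEQIL, solvent-accessibility "exposed" is RKQEND.
CTD_ATTRIBUTES: dict[str, tuple[str, str, str]] = {
    "Hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "Hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "Hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "Hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "Hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "Hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "Hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "NormalizedVDWVolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "Polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "Polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "Charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "SecondaryStructure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "SolventAccessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

for _name, _groups in CTD_ATTRIBUTES.items():
    assert sorted("".join(_groups)) == sorted(ALPHABET), f"{_name} is not a partition"

# residue -> group index (0/1/2) per attribute, precomputed
_GROUP_OF: dict[str, dict[str, int]] = {
    attr: {res: gi for gi, grp in enumerate(groups) for res in grp}
    for attr, groups in CTD_ATTRIBUTES.items()
}


def _group_sequence(s: str, attr: str) -> list[int]:
    g = _GROUP_OF[attr]
    return [g[c] for c in s]


def encode_ctdc(pep: Peptide | str) -> FeatureVector:
    """Composition: per attribute, the fraction of residues in each group."""
    s = _stripped(pep)
    if not s:
        raise ValueError("cannot encode CTDC: no countable residues")
    n = len(s)
    vals, names = [], []
    for attr in CTD_ATTRIBUTES:
        gs = _group_sequence(s, attr)
        for gi in range(3):
            vals.append(gs.count(gi) / n)
            names.append(f"ctdc.{attr}.g{gi + 1}")
    return FeatureVector(np.array(vals), tuple(names))


def encode_ctdt(pep: Peptide | str) -> FeatureVector:
    """Transition: per attribute, the rate of adjacent inter-group switches.

    For each unordered group pair (r, s), T = (N(rs) + N(sr)) / (N - 1)
    where adjacency is taken on the 'X'-stripped sequence.
    """
    s = _stripped(pep)
    if len(s) < 2:
        raise ValueError("cannot encode CTDT: fewer than 2 countable residues")
    denom = len(s) - 1
    pairs = [(0, 1), (0, 2), (1, 2)]
    vals, names = [], []
    for attr in CTD_ATTRIBUTES:
        gs = _group_sequence(s, attr)
        counts = {p: 0 for p in pairs}
        for a, b in zip(gs, gs[1:]):
            if a != b:
                counts[(min(a, b), max(a, b))] += 1
        for (r, t) in pairs:
            vals.append(counts[(r, t)] / denom)
            names.append(f"ctdt.{attr}.g{r + 1}{t + 1}")
    return FeatureVector(np.array(vals), tuple(names))


def encode_ctdd(pep: Peptide | str) -> FeatureVector:
    """Distribution: positional quantiles of each group's occurrences.

    Per attribute x group, five values: the 1-based position (in the
    'X'-stripped sequence, divided by its length) of the first,
    ceil(25% k)-th, ceil(50% k)-th, ceil(75% k)-th and k-th occurrence,
    where k is the group's occurrence count.  Absent groups contribute
    five zeros.
    """
    s = _stripped(pep)
    if not s:
        raise ValueError("cannot encode CTDD: no countable residues")
    n = len(s)
    qlabels = ("first", "q25", "q50", "q75", "q100")
    vals, names = [], []
    for attr in CTD_ATTRIBUTES:
        gs = _group_sequence(s, attr)
        for gi in range(3):
            positions = [i + 1 for i, g in enumerate(gs) if g == gi]
            k = len(positions)
            if k == 0:
                block = [0.0] * 5
            else:
                idx = [1, math.ceil(0.25 * k), math.ceil(0.50 * k),
                       math.ceil(0.75 * k), k]
                block = [positions[max(j, 1) - 1] / n for j in idx]
            vals.extend(block)
            names.extend(f"ctdd.{attr}.g{gi + 1}.{q}" for q in qlabels)
    return FeatureVector(np.array(vals), tuple(names))


# ---------------------------------------------------------------------------
# PAAC / APAAC
# ---------------------------------------------------------------------------

# Canonical per-residue scales: Eisenberg-normalized hydrophobicity,
# Hopp-Woods hydrophilicity, and side-chain mass (Da).
PAAC_SCALES: dict[str, Mapping[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
    "hydrophilicity": {
        "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
        "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
        "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
        "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
    },
    "sidechain_mass": {
        "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0,
        "Q": 72.0, "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0,
        "L": 57.0, "K": 73.0, "M": 75.0, "F": 91.0, "P": 42.0,
        "S": 31.0, "T": 45.0, "W": 130.0, "Y": 107.0, "V": 43.0,
    },
}


def standardized_scale(raw: Mapping[str, float]) -> dict[str, float]:
    """Standardize a residue scale to zero mean, unit population variance."""
    v = np.array([raw[a] for a in ALPHABET])
    std = v.std()  # population (ddof=0), the Chou convention
    z = (v - v.mean()) / std
    return dict(zip(ALPHABET, z))


_STD_SCALES = {name: standardized_scale(tbl) for name, tbl in PAAC_SCALES.items()}
_PAAC_SCALE_NAMES = ("hydrophobicity", "hydrophilicity", "sidechain_mass")


def _check_lam(lam: int, L: int) -> None:
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if lam >= L:
        raise ValueError(f"lambda ({lam}) must be < sequence length ({L})")


def encode_paac(pep: Peptide | str, lam: int = 15, weight: float = 0.05) -> FeatureVector:
    """Pseudo amino-acid composition: 20 frequencies + lambda tier factors.

    The k-th tier correlation factor averages, over all residue pairs k
    apart, the mean squared difference of three standardized scales
    (hydrophobicity, hydrophilicity, side-chain mass).  All 20 + lambda
    entries share the denominator sum(f) + w * sum(tau), so they sum to 1.
    """
    s = _stripped(pep)
    L = len(s)
    if L == 0:
        raise ValueError("cannot encode PAAC: no countable residues")
    _check_lam(lam, L)
    f = np.array([s.count(a) / L for a in ALPHABET])

    scales = [_STD_SCALES[n] for n in _PAAC_SCALE_NAMES]
    taus = []
    for k in range(1, lam + 1):
        acc = 0.0
        for i in range(L - k):
            acc += sum((sc[s[i + k]] - sc[s[i]]) ** 2 for sc in scales) / len(scales)
        taus.append(acc / (L - k))
    taus = np.array(taus)

    denom = f.sum() + weight * taus.sum()
    vals = np.concatenate([f / denom, weight * taus / denom])
    names = tuple(f"paac.{a}" for a in ALPHABET) + tuple(
        f"paac.tau{k}" for k in range(1, lam + 1))
    return FeatureVector(vals, names)


def encode_apaac(pep: Peptide | str, lam: int = 15, weight: float = 0.05) -> FeatureVector:
    """Amphiphilic PAAC: 20 frequencies + 2*lambda amphiphilic factors.

    For each tier j, tau_{2j-1} averages products of standardized
    hydrophobicity and tau_{2j} products of standardized hydrophilicity
    over residue pairs j apart.
    """
    s = _stripped(pep)
    L = len(s)
    if L == 0:
        raise ValueError("cannot encode APAAC: no countable residues")
    _check_lam(lam, L)
    f = np.array([s.count(a) / L for a in ALPHABET])

    h1 = _STD_SCALES["hydrophobicity"]
    h2 = _STD_SCALES["hydrophilicity"]
    taus = []
    for j in range(1, lam + 1):
        t1 = sum(h1[s[i]] * h1[s[i + j]] for i in range(L - j)) / (L - j)
        t2 = sum(h2[s[i]] * h2[s[i + j]] for i in range(L - j)) / (L - j)
        taus.extend([t1, t2])
    taus = np.array(taus)

    denom = f.sum() + weight * taus.sum()
    vals = np.concatenate([f / denom, weight * taus / denom])
    names = tuple(f"apaac.{a}" for a in ALPHABET)
    for j in range(1, lam + 1):
        names += (f"apaac.tau{j}.h1", f"apaac.tau{j}.h2")
    return FeatureVector(vals, names)


# ---------------------------------------------------------------------------
# EncoderSpec and concatenation
# ---------------------------------------------------------------------------

_SEQUENCE_ENCODERS: dict[str, Callable] = {
    "aac": encode_aac,
    "eaac": encode_eaac,
    "ctdc": encode_ctdc,
    "ctdt": encode_ctdt,
    "ctdd": encode_ctdd,
    "paac": encode_paac,
    "apaac": encode_apaac,
}


@dataclass(frozen=True)
class BlockSpec:
    name: str
    params: Mapping[str, float] = field(default_factory=dict)

    def width(self, L: int = 23, backend_width: int | None = None) -> int:
        """Closed-form block width for a length-L peptide."""
        p = self.params
        if self.name == "aac":
            return 20
        if self.name == "eaac":
            return (L - int(p.get("window", 5)) + 1) * 20
        if self.name == "ctdc" or self.name == "ctdt":
            return 39
        if self.name == "ctdd":
            return 195
        if self.name == "paac":
            return 20 + int(p.get("lam", 15))
        if self.name == "apaac":
            return 20 + 2 * int(p.get("lam", 15))
        if backend_width is None:
            raise ValueError(f"unknown block {self.name!r} and no backend width given")
        return backend_width


@dataclass(frozen=True)
class EncoderSpec:
    """An ordered recipe of descriptor blocks, e.g. ``ctdd+eaac+prott5-xl-uniref50``.

    Blocks whose names are not sequence encoders are treated as embedding
    backends and must be resolved by the caller (see ``encode_dataset``).
    Parameters attach with a colon: ``eaac:window=5`` or
    ``paac:lam=15,weight=0.05``.
    """

    blocks: tuple[BlockSpec, ...]

    @classmethod
    def parse(cls, text: str) -> "EncoderSpec":
        blocks = []
        for tok in text.split("+"):
            tok = tok.strip().lower()
            if not tok:
                continue
            name, _, paramstr = tok.partition(":")
            params = {}
            for kv in filter(None, paramstr.split(",")):
                k, _, v = kv.partition("=")
                params[k.strip()] = float(v) if "." in v else int(v)
            blocks.append(BlockSpec(name, params))
        if not blocks:
            raise ValueError(f"empty encoder spec {text!r}")
        return cls(tuple(blocks))

    def sequence_blocks(self) -> list[BlockSpec]:
        return [b for b in self.blocks if b.name in _SEQUENCE_ENCODERS]

    def embedding_blocks(self) -> list[BlockSpec]:
        return [b for b in self.blocks if b.name not in _SEQUENCE_ENCODERS]

    def total_width(self, L: int = 23, backend_widths: Mapping[str, int] | None = None) -> int:
        bw = backend_widths or {}
        return sum(b.width(L, bw.get(b.name)) for b in self.blocks)


def _encode_block(pep: Peptide | str, block: BlockSpec) -> FeatureVector:
    fn = _SEQUENCE_ENCODERS[block.name]
    kw = dict(block.params)
    if block.name in ("paac", "apaac"):
        kw = {"lam": int(kw.get("lam", 15)), "weight": float(kw.get("weight", 0.05))}
    elif block.name == "eaac":
        kw = {"window": int(kw.get("window", 5))}
    else:
        kw = {}
    return fn(pep, **kw)


def concat_features(blocks: Sequence[FeatureVector],
                    spec: EncoderSpec | None = None) -> FeatureVector:
    """Concatenate descriptor blocks into a single named vector.

    If a spec is given, the block count must match its block count; widths
    of known sequence blocks are checked against the closed-form formulas.
    """
    if spec is not None:
        if len(blocks) != len(spec.blocks):
            raise ValueError(
                f"{len(blocks)} blocks given but spec declares {len(spec.blocks)}")
    if not blocks:
        return FeatureVector(np.empty(0), ())
    vals = np.concatenate([b.values for b in blocks])
    names = tuple(n for b in blocks for n in b.names)
    return FeatureVector(vals, names)


def encode_peptide(
    pep: Peptide | str,
    spec: EncoderSpec,
    embed_fn: Callable[[Peptide | str, BlockSpec], FeatureVector] | None = None,
) -> FeatureVector:
    """Encode one peptide under a full spec, resolving embedding blocks
    through ``embed_fn(peptide, block)`` when present."""
    parts = []
    for block in spec.blocks:
        if block.name in _SEQUENCE_ENCODERS:
            parts.append(_encode_block(pep, block))
        else:
            if embed_fn is None:
                raise ValueError(
                    f"block {block.name!r} is not a sequence encoder and no "
                    "embedding resolver was provided")
            parts.append(embed_fn(pep, block))
    return concat_features(parts, spec)


def encode_dataset(dataset, spec: EncoderSpec, embed_fn=None) -> list[FeatureVector]:
    """Encode every peptide in a dataset (see :func:`encode_peptide`)."""
    return [encode_peptide(p, spec, embed_fn) for p in dataset]


def feature_matrix(features: Sequence[FeatureVector]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack per-peptide feature vectors into an (n, d) array + names."""
    if not features:
        return np.empty((0, 0)), ()
    names = features[0].names
    for fv in features:
        if fv.names != names:
            raise ValueError("feature rows disagree on names/order")
    return np.vstack([fv.values for fv in features]), names
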