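"""Reading, writing and windowing of lysine-centered peptide datasets.

The atomic sample of the toolkit is a fixed-length residue window (23 by
default) centered on a candidate lysine, carrying a binary glutarylation
label.  Datasets travel as FASTA (label token in the header, ``>id|1``) or
as delimited text with ``sequence,label[,source_id]`` columns.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The fixed residue ordering used by every composition-style encoder.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Pad / unknown-residue symbol.  Encoders exclude it from all counts.
PAD = "X"

_VALID_CHARS = frozenset(ALPHABET) | {PAD}

# Ambiguity / non-standard codes collapsed to the unknown symbol.
_NONSTANDARD = {"B": PAD, "Z": PAD, "U": PAD, "O": PAD, "J": PAD}

#: Default window half-width: 11 residues up- and downstream of the lysine.
DEFAULT_FLANK = 11

#: Pipeline-ready window length, 2 * DEFAULT_FLANK + 1.
WINDOW_LENGTH = 2 * DEFAULT_FLANK + 1


class PeptideError(ValueError):
    """Raised for malformed peptide records or window requests."""


@dataclass(frozen=True)
class Peptide:
    """A fixed-length residue window centered on a candidate lysine.

    Parameters
    ----------
    sequence
        Residue string over the 20-letter alphabet plus the pad symbol 'X'.
    label
        1 (glutarylated), 0 (not) or None (unlabeled).
    center_index
        0-based position of the candidate lysine within the window.
    source_id
        Free-text provenance, typically ``<protein id>:<site position>``.
    """

    sequence: str
    label: int | None = None
    center_index: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise PeptideError(
                f"peptide {self.source_id or self.sequence!r} contains "
                f"invalid characters {sorted(bad)}"
            )
        if self.label not in (0, 1, None):
            raise PeptideError(f"label must be 0, 1 or None, got {self.label!r}")
        if self.center_index is not None:
            if not 0 <= self.center_index < len(self.sequence):
                raise PeptideError(
                    f"center_index {self.center_index} out of range for "
                    f"length-{len(self.sequence)} sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def stripped(self) -> str:
        """The sequence with pad symbols removed (used by all encoders)."""
        return self.sequence.replace(PAD, "")


@dataclass
class Dataset:
    """An ordered collection of peptides with cached class counts."""

    peptides: list[Peptide] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return sum(1 for p in self.peptides if p.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for p in self.peptides if p.label == 0)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.peptides[i])
        return self.peptides[i]

    def labels(self) -> list[int]:
        return [p.label for p in self.peptides]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.peptides[i] for i in indices])


def clean_sequence(seq: str) -> str:
    """Uppercase and map non-standard residues (B/Z/U/O/J) to 'X'."""
    seq = seq.strip().upper()
    if any(c in _NONSTANDARD for c in seq):
        logger.warning("non-standard residues in %r mapped to %s", seq, PAD)
        seq = "".join(_NONSTANDARD.get(c, c) for c in seq)
    return seq


def _validate_window(pep: Peptide, record_name: str, strict: bool) -> bool:
    """Return True if the peptide passes pipeline-readiness checks."""
    problems = []
    if len(pep) != WINDOW_LENGTH:
        problems.append(f"length {len(pep)} != {WINDOW_LENGTH}")
    elif pep.sequence[DEFAULT_FLANK] != "K":
        problems.append(f"center residue {pep.sequence[DEFAULT_FLANK]!r} is not 'K'")
    if not problems:
        return True
    msg = f"record {record_name}: " + "; ".join(problems)
    if strict:
        raise PeptideError(msg)
    logger.warning("%s (skipped)", msg)
    return False


def _parse_label(token: str, record_name: str) -> int:
    token = token.strip()
    if token in ("1", "pos", "positive"):
        return 1
    if token in ("0", "neg", "negative"):
        return 0
    raise PeptideError(f"record {record_name}: unknown label token {token!r}")


def read_peptide_table(
    path: str | Path,
    format: str | None = None,
    strict: bool = True,
) -> Dataset:
    """Read a labeled peptide dataset from FASTA or delimited text.

    FASTA headers carry the label as the last ``|``-separated token
    (``>P12345:17|1``).  Delimited files (comma or tab, sniffed) need
    ``sequence`` and ``label`` columns, optionally ``source_id``.

    With ``strict=False``, windows of the wrong length or without a central
    lysine are skipped with a warning instead of raising.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "delimited"
    if format == "fasta":
        records = _read_fasta(path)
    elif format == "delimited":
        records = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'delimited'")

    peptides = []
    for name, seq, label_token, source_id in records:
        seq = clean_sequence(seq)
        label = _parse_label(label_token, name)
        pep = Peptide(seq, label=label,
                      center_index=DEFAULT_FLANK if len(seq) == WINDOW_LENGTH else None,
                      source_id=source_id)
        if _validate_window(pep, name, strict):
            peptides.append(pep)
    return Dataset(peptides)


def _read_fasta(path: Path) -> Iterable[tuple[str, str, str, str]]:
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        if "|" not in header:
            raise PeptideError(f"FASTA record {i} ({header!r}): no '|label' token in header")
        source_id, _, label_token = header.rpartition("|")
        yield f"{i} ({header})", str(rec.seq), label_token, source_id


def _read_delimited(path: Path) -> Iterable[tuple[str, str, str, str]]:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if not sample.strip():
            return
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        cols = set(reader.fieldnames or ())
        if not {"sequence", "label"} <= cols:
            raise PeptideError(
                f"{path}: delimited input needs 'sequence' and 'label' columns, got {sorted(cols)}"
            )
        for i, row in enumerate(reader, start=2):
            yield f"line {i}", row["sequence"], row["label"], row.get("source_id", "") or ""


def write_peptide_table(dataset: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset as FASTA or delimited text (inverse of the reader)."""
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "delimited"
    if format == "fasta":
        with open(path, "w") as fh:
            for i, p in enumerate(dataset):
                sid = p.source_id or f"pep{i}"
                fh.write(f">{sid}|{p.label}\n{p.sequence}\n")
    elif format == "delimited":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sequence", "label", "source_id"])
            for p in dataset:
                w.writerow([p.sequence, p.label, p.source_id])
    else:
        raise ValueError(f"unknown format {format!r}")


def extract_windows(
    protein: str,
    site_positions: Sequence[int],
    flank: int = DEFAULT_FLANK,
    label: int | None = None,
    protein_id: str = "",
) -> list[Peptide]:
    """Extract fixed-length lysine-centered windows from a full protein.

    ``site_positions`` are 1-based and must each index a lysine.  Sites
    closer than ``flank`` to a terminus are padded with 'X' on the short
    side, so every window has length ``2 * flank + 1`` with the lysine at
    index ``flank``.
    """
    protein = clean_sequence(protein)
    out = []
    for pos in site_positions:
        if not 1 <= pos <= len(protein):
            raise PeptideError(f"site position {pos} outside protein of length {len(protein)}")
        i = pos - 1
        if protein[i] != "K":
            raise PeptideError(f"site position {pos} is {protein[i]!r}, not 'K'")
        left = protein[max(0, i - flank): i]
        right = protein[i + 1: i + 1 + flank]
        window = PAD * (flank - len(left)) + left + "K" + right + PAD * (flank - len(right))
        out.append(Peptide(window, label=label, center_index=flank,
                           source_id=f"{protein_id}:{pos}" if protein_id else str(pos)))
    return out


def write_feature_matrix(
    dataset: Dataset,
    features: Sequence["FeatureVector"],  # noqa: F821 - forward ref to encoders
    path: str | Path,
) -> None:
    """Write one feature row per peptide as delimited text with a label column.

    The header carries the block-qualified feature names; values round-trip
    losslessly through :func:`read_feature_matrix` at full float precision.
    """
    if len(features) != len(dataset):
        raise ValueError(f"{len(features)} feature rows for {len(dataset)} peptides")
    names = None
    for fv in features:
        if names is None:
            names = list(fv.names)
        elif list(fv.names) != names:
            raise ValueError("inconsistent feature names/widths across rows")
    df = pd.DataFrame([list(fv.values) for fv in features], columns=names or [])
    df["label"] = [p.label for p in dataset]
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    return pd.read_csv(path)
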