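"""Per-residue protein embeddings: backend contracts, pooling, caching.

Real protein language-model backends (ProtBERT, ProtT5, ...) produce one
embedding row per residue; this module consumes that contract, pools the
rows into a fixed-width peptide feature by column summation, and caches
pooled vectors on disk so repeated runs skip recomputation.  A
deterministic mock backend lets the whole pipeline run and be tested
without any model download.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoders import FeatureVector
from .peptide_io import Dataset, Peptide

logger = logging.getLogger(__name__)

#: Declared pooled widths of the named transformer backends.
BACKEND_WIDTHS: dict[str, int] = {
    "protbert": 1024,
    "protbert-bfd": 1024,
    "protalbert": 4096,
    "prott5-xl-uniref50": 1024,
    "prott5-xl-bfd": 1024,
    "protxlnet": 1024,
}


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding rows (length-of-sequence x width)."""

    rows: np.ndarray
    backend_name: str = "mock"

    def __post_init__(self):
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))
        if self.rows.ndim != 2:
            raise ValueError(f"embedding matrix must be 2-D, got {self.rows.ndim}-D")

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    @property
    def n_residues(self) -> int:
        return self.rows.shape[0]


@dataclass(frozen=True)
class BackendContract:
    """A named backend and its declared embedding width.

    The six real transformer backends have fixed widths (4096 for
    ProtAlbert, 1024 for the rest); the mock backend accepts any width
    and a seed making it a pure function of (residue, position, seed).
    """

    name: str
    width: int | None = None
    seed: int = 0

    def __post_init__(self):
        name = self.name.lower()
        object.__setattr__(self, "name", name)
        if name in BACKEND_WIDTHS:
            declared = BACKEND_WIDTHS[name]
            if self.width is not None and self.width != declared:
                raise ValueError(
                    f"backend {name!r} declares width {declared}, got {self.width}")
            object.__setattr__(self, "width", declared)
        elif name == "mock":
            if self.width is None:
                object.__setattr__(self, "width", 1024)
        else:
            raise ValueError(
                f"unknown backend {self.name!r}; known: "
                f"{sorted(BACKEND_WIDTHS) + ['mock']}")

    def embed(self, pep: Peptide | str) -> EmbeddingMatrix:
        if self.name == "mock":
            return mock_embed(pep, self.width, self.seed)
        raise RuntimeError(
            f"backend {self.name!r} requires the optional transformer stack "
            "(install the 'transformers' and 'torch' extras and point the "
            "provider at the downloaded model); only the 'mock' backend is "
            "available in a base install")


def pool_embeddings(mat: EmbeddingMatrix) -> FeatureVector:
    """Collapse a per-residue matrix to one vector by column summation."""
    if mat.n_residues == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    vals = mat.rows.sum(axis=0)
    names = tuple(f"{mat.backend_name}.e{i}" for i in range(mat.width))
    return FeatureVector(vals, names)


def mean_pool_embeddings(mat: EmbeddingMatrix) -> FeatureVector:
    """Mean pooling variant (off by default; summation is the standard here)."""
    if mat.n_residues == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    vals = mat.rows.mean(axis=0)
    names = tuple(f"{mat.backend_name}.e{i}" for i in range(mat.width))
    return FeatureVector(vals, names)


def mock_embed(pep: Peptide | str, width: int, seed: int) -> EmbeddingMatrix:
    """Deterministic stand-in embedding: one row per residue, each a pure
    function of (residue identity, position, seed)."""
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    seq = pep.sequence if isinstance(pep, Peptide) else pep
    rows = np.empty((len(seq), width))
    for i, res in enumerate(seq):
        rng = np.random.default_rng([seed, ord(res), i])
        rows[i] = rng.standard_normal(width)
    return EmbeddingMatrix(rows, backend_name="mock")


class EmbeddingProvider:
    """Pools backend embeddings per peptide, with an on-disk cache.

    Cache entries are keyed by (backend name, sequence sha1) and stored
    one vector per ``.npy`` file under ``cache_dir``; pass
    ``cache_dir=None`` to disable caching.
    """

    def __init__(self, backend: BackendContract, cache_dir: str | Path | None = None,
                 mean_pool: bool = False):
        self.backend = backend
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None
        self._pool = mean_pool_embeddings if mean_pool else pool_embeddings
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)

    def _cache_path(self, seq: str) -> Path:
        digest = hashlib.sha1(seq.encode()).hexdigest()
        return self.cache_dir / f"{self.backend.name}_{digest}.npy"

    def pooled(self, pep: Peptide | str) -> FeatureVector:
        seq = pep.sequence if isinstance(pep, Peptide) else pep
        names = tuple(f"{self.backend.name}.e{i}" for i in range(self.backend.width))
        if self.cache_dir is not None:
            path = self._cache_path(seq)
            if path.exists():
                logger.debug("embedding cache hit for %s", path.name)
                return FeatureVector(np.load(path), names)
        fv = self._pool(self.backend.embed(seq))
        fv = FeatureVector(fv.values, names)
        if self.cache_dir is not None:
            np.save(self._cache_path(seq), fv.values)
        return fv

    def embed_dataset(self, dataset: Dataset) -> list[FeatureVector]:
        """Pooled embedding vector for every peptide in the dataset."""
        return [self.pooled(p) for p in dataset]
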