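"""Protein-language-model contract: log-probabilities, embeddings, caching.

Real PLMs (ESM2 / ESMC family) are represented only through the
:class:`Embedder` contract — per-position amino-acid log-probabilities for
the wild type and a fixed-length mean-pooled embedding per sequence. The
synthetic oracle in :mod:`folde.synthetic` implements the same contract, so
no model download or GPU is required to run or test anything downstream;
a real-model adapter can be plugged in without touching downstream code.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import h5py
import numpy as np
import pandas as pd

from .landscape import AA_ALPHABET, AA_INDEX


@dataclasses.dataclass
class LogProbMatrix:
    """Per-position log-probabilities over the 20 canonical amino acids.

    ``values[p, a]`` is log P(amino acid a at position p+1 | wild type),
    with columns ordered by :data:`folde.landscape.AA_ALPHABET`. Each row
    must exponentiate and sum to 1 within 1e-6.
    """

    values: np.ndarray
    wild_type: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(AA_ALPHABET):
            raise ValueError(f"expected (L, 20) matrix, got {self.values.shape}")
        if self.values.shape[0] != len(self.wild_type):
            raise ValueError("log-prob matrix length does not match wild type")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite log-probabilities")
        sums = np.exp(self.values).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("rows do not exponentiate-sum to 1")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def logp(self, position: int, aa: str) -> float:
        """Log-probability of ``aa`` at 1-based ``position``."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return float(self.values[position - 1, AA_INDEX[aa]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(AA_ALPHABET),
                            index=np.arange(1, self.length + 1))

    @classmethod
    def from_csv(cls, path: str | Path, wild_type: str) -> "LogProbMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df[list(AA_ALPHABET)].to_numpy(dtype=float), wild_type)


@runtime_checkable
class Embedder(Protocol):
    """Contract standing in for a protein language model.

    Implementations must be deterministic: the same sequence always maps to
    the identical vector.
    """

    @property
    def dim(self) -> int:
        """Embedding length (960 for ESMC-300M mean-pooled hidden states)."""
        ...

    def embed(self, sequence: str) -> np.ndarray:
        """Fixed-length embedding of one sequence."""
        ...

    def embed_many(self, sequences: Sequence[str]) -> np.ndarray:
        """(n, dim) embeddings for a batch of sequences."""
        ...

    def logprobs(self, wild_type: str) -> LogProbMatrix:
        """Per-position amino-acid log-probabilities given the wild type."""
        ...


def sequence_key(sequence: str) -> str:
    """Stable cache key for a sequence."""
    return hashlib.sha1(sequence.encode("ascii")).hexdigest()


class EmbeddingCache:
    """On-disk embedding store keyed by sequence hash (HDF5 container).

    Shared between the synthetic oracle and real-PLM adapters so embeddings
    computed once (possibly on other hardware) can be replayed here.
    """

    def __init__(self, path: str | Path, mode: str = "a") -> None:
        self.path = Path(path)
        self._fh = h5py.File(self.path, mode)

    def __contains__(self, sequence: str) -> bool:
        return sequence_key(sequence) in self._fh

    def get(self, sequence: str) -> np.ndarray | None:
        key = sequence_key(sequence)
        if key not in self._fh:
            return None
        return np.asarray(self._fh[key][...], dtype=float)

    def put(self, sequence: str, vector: np.ndarray) -> None:
        key = sequence_key(sequence)
        if key in self._fh:
            del self._fh[key]
        self._fh.create_dataset(key, data=np.asarray(vector, dtype=float))

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "EmbeddingCache":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class CachedEmbedder:
    """Wrap an :class:`Embedder` with an :class:`EmbeddingCache`."""

    def __init__(self, base: Embedder, cache: EmbeddingCache) -> None:
        self.base = base
        self.cache = cache

    @property
    def dim(self) -> int:
        return self.base.dim

    def embed(self, sequence: str) -> np.ndarray:
        hit = self.cache.get(sequence)
        if hit is not None:
            return hit
        vec = self.base.embed(sequence)
        self.cache.put(sequence, vec)
        return vec

    def embed_many(self, sequences: Sequence[str]) -> np.ndarray:
        return np.stack([self.embed(s) for s in sequences])

    def logprobs(self, wild_type: str) -> LogProbMatrix:
        return self.base.logprobs(wild_type)


class PrecomputedEmbedder:
    """Embedder backed entirely by a cache file plus a log-prob CSV.

    Used to replay campaigns against embeddings exported from a real PLM;
    raises if a requested sequence is absent from the cache.
    """

    def __init__(self, cache: EmbeddingCache, logprob_csv: str | Path,
                 wild_type: str) -> None:
        self.cache = cache
        self._lp = LogProbMatrix.from_csv(logprob_csv, wild_type)
        self._dim: int | None = None

    @property
    def dim(self) -> int:
        if self._dim is None:
            raise RuntimeError("dim unknown until a first embedding is read")
        return self._dim

    def embed(self, sequence: str) -> np.ndarray:
        vec = self.cache.get(sequence)
        if vec is None:
            raise KeyError(f"sequence {sequence_key(sequence)} not in embedding cache")
        self._dim = len(vec)
        return vec

    def embed_many(self, sequences: Sequence[str]) -> np.ndarray:
        return np.stack([self.embed(s) for s in sequences])

    def logprobs(self, wild_type: str) -> LogProbMatrix:
        if wild_type != self._lp.wild_type:
            raise ValueError("wild type does not match the log-prob table")
        return self._lp
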