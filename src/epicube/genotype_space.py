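"""Canonical indexing of the binary genotype hypercube.

Every module in the package shares the conventions fixed here:

* A genotype over ``N`` biallelic positions is an integer index in
  ``[0, 2**N)``; bit ``k`` of the index encodes the allele at position
  ``k + 1`` (position 1 is the least-significant bit).
* Allele 0 is the first parent (blue, mTagBFP2-like); allele 1 is the
  second parent (red, mKate2-like).  The blue parent is index 0, the red
  parent is index ``2**N - 1``.
* Vectors "in binary order" are ordered by ascending genotype index.
* Genotype strings in files are length-``N`` strings over ``{0, 1}`` with
  the leftmost character at position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAX_POSITIONS",
    "Genotype",
    "PositionMap",
    "genotype_index",
    "index_bits",
    "genotype_string",
    "parse_genotype_string",
    "hamming_neighbors",
    "enumerate_space",
    "order_of_index",
    "layer_indices",
]

#: Largest number of positions enumerate_space will materialise (2**24 rows).
MAX_POSITIONS = 24


@dataclass(frozen=True)
class Genotype:
    """A vertex of the ``N``-dimensional genotype hypercube."""

    index: int
    n_positions: int

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError(f"n_positions must be >= 1, got {self.n_positions}")
        if not 0 <= self.index < (1 << self.n_positions):
            raise ValueError(
                f"index {self.index} out of range for N={self.n_positions}"
            )

    @property
    def bits(self) -> np.ndarray:
        return index_bits(self.index, self.n_positions)

    @property
    def order(self) -> int:
        """Number of derived (allele-1) positions: the Hamming layer."""
        return int(self.index).bit_count()

    def __str__(self) -> str:
        return genotype_string(self.index, self.n_positions)


@dataclass(frozen=True)
class PositionMap:
    """Ordered labels for the mutated positions and their two alleles.

    ``names[k]`` labels position ``k + 1`` (bit ``k``).  Defaults carry the
    generic allele characters used in two-letter FASTA export.
    """

    names: tuple[str, ...]
    allele0_labels: tuple[str, ...] = field(default=())
    allele1_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("position names must be unique")
        object.__setattr__(
            self, "allele0_labels", self.allele0_labels or ("B",) * len(self.names)
        )
        object.__setattr__(
            self, "allele1_labels", self.allele1_labels or ("K",) * len(self.names)
        )
        for lab in (self.allele0_labels, self.allele1_labels):
            if len(lab) != len(self.names):
                raise ValueError("allele label lists must match names in length")

    @property
    def n_positions(self) -> int:
        return len(self.names)

    def describe(self, g: Genotype) -> list[str]:
        """Names of the allele-1 positions carried by ``g``."""
        if g.n_positions != self.n_positions:
            raise ValueError("genotype/position-map dimension mismatch")
        return [self.names[k] for k in range(self.n_positions) if (g.index >> k) & 1]


def genotype_index(bits: Sequence[int] | np.ndarray) -> int:
    """Map a binary allele vector to its genotype index.

    ``bits[k]`` is the allele at position ``k + 1``; the index is
    ``sum_k bits[k] * 2**k`` so position 1 is the least-significant bit.
    """
    arr = np.asarray(bits)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("bits must be a non-empty 1-D sequence")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"non-binary allele in {list(arr)!r}")
    return int((arr.astype(np.int64) << np.arange(arr.size, dtype=np.int64)).sum())


def index_bits(index: int, n_positions: int) -> np.ndarray:
    """Inverse of :func:`genotype_index`: allele vector of an index."""
    if not 0 <= index < (1 << n_positions):
        raise ValueError(f"index {index} out of range for N={n_positions}")
    return (index >> np.arange(n_positions)) & 1


def genotype_string(index: int, n_positions: int) -> str:
    """File representation: leftmost character = position 1."""
    return "".join(str(b) for b in index_bits(index, n_positions))


def parse_genotype_string(s: str) -> tuple[int, int]:
    """Parse a 0/1 genotype string; returns ``(index, n_positions)``."""
    if not s or any(c not in "01" for c in s):
        raise ValueError(f"malformed genotype string {s!r}")
    return genotype_index([int(c) for c in s]), len(s)


def hamming_neighbors(g: Genotype) -> set[int]:
    """Indices of the ``N`` genotypes one substitution away from ``g``."""
    return {g.index ^ (1 << k) for k in range(g.n_positions)}


def enumerate_space(n_positions: int) -> list[Genotype]:
    """All ``2**N`` genotypes in ascending index (binary) order."""
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if n_positions > MAX_POSITIONS:
        raise ValueError(
            f"N={n_positions} exceeds the enumeration cap of {MAX_POSITIONS}"
        )
    return [Genotype(i, n_positions) for i in range(1 << n_positions)]


def order_of_index(indices: int | np.ndarray) -> np.ndarray | int:
    """Popcount, vectorised: interaction order / Hamming layer of indices."""
    if np.isscalar(indices):
        return int(indices).bit_count()
    arr = np.asarray(indices, dtype=np.uint64)
    return np.bitwise_count(arr).astype(np.int64)


def layer_indices(n_positions: int, k: int) -> np.ndarray:
    """Genotype indices in Hamming layer ``k`` (``C(N, k)`` of them)."""
    if not 0 <= k <= n_positions:
        raise ValueError(f"layer {k} out of range for N={n_positions}")
    idx = np.arange(1 << n_positions, dtype=np.uint64)
    out = np.asarray(idx[np.bitwise_count(idx) == k], dtype=np.int64)
    assert out.size == comb(n_positions, k)
    return out
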