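"""Epistasis estimated from the statistics of a functional alignment.

Selecting the genotypes whose phenotype exceeds a threshold and writing
them as a +1/-1 alignment (allele 0 -> +1, allele 1 -> -1) turns the
landscape into an ensemble of "functional sequences".  First- and
second-order background-averaged epistasis of the *indicator* landscape
``F(g) = 1{y(g) > threshold}`` can then be read off alignment statistics:

    omega_i^aln  = phi_i  * 2 * N_func / N_tot,       phi_i  = <x_i>
    omega_ij^aln = phi_ij * 4 * N_func / N_tot,       phi_ij = <x_i x_j>

where the averages run over the functional rows and ``N_tot`` is the total
number of genotypes in the combinatorial space.  With the -1 encoding of
allele 1, the raw character-basis coefficients differ from the weighted
Walsh-Hadamard terms by ``(-1)**order``; the convention-adjusted values
(default) multiply order-``o`` terms by that factor so the two modules
report the identical quantity — an exact identity, not an approximation,
checked term-by-term in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_space import PositionMap, genotype_index, index_bits
from .operators import Landscape

__all__ = [
    "AlignmentSet",
    "build_alignment",
    "alignment_epistasis_first",
    "alignment_epistasis_second",
    "write_alignment_fasta",
    "read_alignment_fasta",
]


@dataclass(frozen=True)
class AlignmentSet:
    """+1/-1 encoded functional sequences with the selection context.

    ``encoded`` has one row per functional genotype and one column per
    position; ``n_total`` is the size of the full combinatorial space the
    rows were selected from (an alignment alone does not determine it).
    """

    encoded: np.ndarray
    threshold: float
    n_total: int

    def __post_init__(self) -> None:
        enc = np.asarray(self.encoded, dtype=np.int8)
        object.__setattr__(self, "encoded", enc)
        if enc.ndim != 2 or enc.shape[0] == 0:
            raise ValueError("alignment must be a non-empty 2-D matrix")
        if not np.isin(enc, (-1, 1)).all():
            raise ValueError("alignment entries must be +1 or -1")
        if self.n_func > self.n_total:
            raise ValueError("more functional sequences than the total space")

    @property
    def n_func(self) -> int:
        return self.encoded.shape[0]

    @property
    def n_positions(self) -> int:
        return self.encoded.shape[1]


def build_alignment(landscape: Landscape, threshold: float) -> AlignmentSet:
    """Alignment of all genotypes with phenotype strictly above ``threshold``.

    Encoding: allele 0 (first parent) -> +1, allele 1 (second parent) -> -1.
    """
    functional = np.flatnonzero(landscape.phenotypes > threshold)
    if functional.size == 0:
        raise ValueError(
            f"no genotype exceeds threshold {threshold}; empty alignment"
        )
    n = landscape.n_positions
    bits = (functional[:, None] >> np.arange(n)[None, :]) & 1
    return AlignmentSet(
        encoded=(1 - 2 * bits).astype(np.int8),
        threshold=float(threshold),
        n_total=landscape.size,
    )


def alignment_epistasis_first(
    aln: AlignmentSet, convention_adjusted: bool = True
) -> np.ndarray:
    """First-order terms from per-column means.

    ``convention_adjusted`` applies the ``(-1)**1`` factor so the result
    equals the background-averaged first-order transform of the indicator
    landscape; without it the raw printed formula is returned.
    """
    phi = aln.encoded.mean(axis=0)
    raw = phi * 2.0 * aln.n_func / aln.n_total
    return -raw if convention_adjusted else raw


def alignment_epistasis_second(
    aln: AlignmentSet, convention_adjusted: bool = True
) -> np.ndarray:
    """Pairwise terms from joint column expectations (upper triangle).

    Returns an ``N x N`` matrix with entries above the diagonal; the
    ``(-1)**2`` convention factor is the identity, so both modes agree.
    """
    x = aln.encoded.astype(float)
    phi = (x.T @ x) / aln.n_func
    terms = phi * 4.0 * aln.n_func / aln.n_total
    return np.triu(terms, k=1)


# --- FASTA round trip over a two-letter alphabet ---------------------------

def write_alignment_fasta(
    aln: AlignmentSet,
    path: str | Path,
    positions: PositionMap | None = None,
    chars: tuple[str, str] = ("B", "K"),
) -> None:
    """Write the alignment as two-letter FASTA (+1 -> chars[0], -1 -> chars[1]).

    ``n_total`` and the threshold go in a leading ``;`` comment, because the
    sequences alone do not determine them.
    """
    with open(path, "w") as fh:
        fh.write(f";n_total={aln.n_total}\tthreshold={aln.threshold}\n")
        for r, row in enumerate(aln.encoded):
            seq = "".join(chars[0] if v == 1 else chars[1] for v in row)
            fh.write(f">seq{r}\n{seq}\n")


def read_alignment_fasta(
    path: str | Path, chars: tuple[str, str] = ("B", "K")
) -> AlignmentSet:
    """Read an alignment written by :func:`write_alignment_fasta`."""
    n_total = None
    threshold = np.nan
    rows: list[list[int]] = []
    seq_parts: list[str] = []

    def _flush() -> None:
        if seq_parts:
            seq = "".join(seq_parts)
            bad = set(seq) - set(chars)
            if bad:
                raise ValueError(f"unexpected characters {bad} in alignment FASTA")
            rows.append([1 if c == chars[0] else -1 for c in seq])
            seq_parts.clear()

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(";"):
            for tok in line[1:].split():
                key, _, val = tok.partition("=")
                if key == "n_total":
                    n_total = int(val)
                elif key == "threshold":
                    threshold = float(val)
        elif line.startswith(">"):
            _flush()
        else:
            seq_parts.append(line)
    _flush()
    if not rows:
        raise ValueError(f"no sequences found in {path}")
    if n_total is None:
        raise ValueError(f"{path} lacks the ';n_total=...' sidecar header")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    enc = np.asarray(rows, dtype=np.int8)
    return AlignmentSet(encoded=enc, threshold=threshold, n_total=n_total)
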