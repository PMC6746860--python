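"""Topology of the functional genotype network.

Thresholding the landscape gives a subgraph of the hypercube whose nodes
are the functional genotypes (phenotype strictly above threshold) and whose
edges connect functional single-mutation neighbors.  The ``m``-th power of
that adjacency matrix counts functional ``m``-step trajectories (walks;
for antipodal endpoints at ``m`` = Hamming distance, walks coincide with
direct paths, each differing position flipped exactly once).  Counts are
computed by sparse per-step propagation in exact Python-integer arithmetic
— the full 13-cube antipodal count is 13! = 6,227,020,800, already beyond
what float or int32 matrix powers handle safely.

Also here: the connectogram (connected components of the functional
subgraph), per-layer direct-path connectivity between antipodal parents,
and the magnitude/sign/reciprocal-sign classification of pairwise
epistasis in a fixed background.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from math import comb

import networkx as nx
import numpy as np

from .genotype_space import Genotype, order_of_index
from .operators import Landscape

__all__ = [
    "FunctionalAdjacency",
    "TrajectoryReport",
    "EpistasisClass",
    "PairClass",
    "functional_adjacency",
    "count_paths",
    "count_direct_paths",
    "connectogram",
    "step_connectivity",
    "classify_pairwise",
    "classify_pair_over_backgrounds",
]

#: Default brightness threshold: the red-parent phenotype in the study system.
DEFAULT_THRESHOLD = 0.73


@dataclass(frozen=True)
class FunctionalAdjacency:
    """Functional node set of the thresholded hypercube.

    Edges are implicit (XOR single-bit neighbors within the node set);
    ``graph()`` materialises them as a networkx object when needed.
    """

    n_positions: int
    threshold: float
    functional_indices: frozenset[int]

    def __post_init__(self) -> None:
        if not self.functional_indices:
            raise ValueError("no functional genotypes above threshold")

    def is_functional(self, index: int) -> bool:
        return index in self.functional_indices

    def neighbors(self, index: int) -> list[int]:
        return [
            index ^ (1 << k)
            for k in range(self.n_positions)
            if (index ^ (1 << k)) in self.functional_indices
        ]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.functional_indices)
        for u in self.functional_indices:
            for v in self.neighbors(u):
                if u < v:
                    g.add_edge(u, v)
        return g


@dataclass(frozen=True)
class TrajectoryReport:
    """Path-count and connectivity summary between two genotypes."""

    source: int
    target: int
    step_counts: dict[int, int]
    layer_fractions: np.ndarray | None = None
    components: tuple[frozenset[int], ...] = ()


class EpistasisClass(str, enum.Enum):
    NO_EPISTASIS = "no_epistasis"
    MAGNITUDE = "magnitude"
    SIGN = "sign"
    RECIPROCAL_SIGN = "reciprocal_sign"


@dataclass(frozen=True)
class PairClass:
    pair: tuple[int, int]
    background: int
    epistasis_class: EpistasisClass


def functional_adjacency(
    landscape: Landscape, threshold: float = DEFAULT_THRESHOLD
) -> FunctionalAdjacency:
    """Binarize the landscape: keep genotypes with ``y > threshold``."""
    functional = np.flatnonzero(landscape.phenotypes > threshold)
    if functional.size == 0:
        raise ValueError(f"no genotype exceeds threshold {threshold}")
    return FunctionalAdjacency(
        n_positions=landscape.n_positions,
        threshold=float(threshold),
        functional_indices=frozenset(int(i) for i in functional),
    )


def count_paths(
    adj: FunctionalAdjacency, source: Genotype | int, target: Genotype | int, m: int
) -> int:
    """Exact number of functional ``m``-step walks from source to target.

    Equals the (source, target) entry of the ``m``-th adjacency power,
    computed by propagating an integer indicator vector ``m`` times through
    the functional edge set (Python integers: no overflow at 13! scale).
    Walks may revisit nodes when ``m`` exceeds the Hamming distance.
    """
    s = source.index if isinstance(source, Genotype) else int(source)
    t = target.index if isinstance(target, Genotype) else int(target)
    if m < 0:
        raise ValueError("m must be nonnegative")
    for name, g in (("source", s), ("target", t)):
        if not adj.is_functional(g):
            raise ValueError(f"{name} genotype {g} is not functional")
    counts: dict[int, int] = {s: 1}
    for _ in range(m):
        nxt: dict[int, int] = {}
        for node, c in counts.items():
            for nbr in adj.neighbors(node):
                nxt[nbr] = nxt.get(nbr, 0) + c
        counts = nxt
        if not counts:
            return 0
    return counts.get(t, 0)


def _direct_path_dp(adj: FunctionalAdjacency, source: int) -> dict[int, int]:
    """Functional monotone-path counts from ``source`` to every genotype.

    Monotone: each step flips one position in which the genotype still
    agrees with ``source``, so paths from ``source`` to ``g`` have length
    Hamming(source, g) and each differing bit flips exactly once.
    """
    n = adj.n_positions
    if not adj.is_functional(source):
        return {}
    counts = {source: 1}
    frontier = {source: 1}
    for _ in range(n):
        nxt: dict[int, int] = {}
        for node, c in frontier.items():
            delta = node ^ source
            for k in range(n):
                bit = 1 << k
                if delta & bit:
                    continue  # already flipped on this path
                nbr = node ^ bit
                if adj.is_functional(nbr):
                    nxt[nbr] = nxt.get(nbr, 0) + c
        frontier = nxt
        counts.update(nxt)
        if not frontier:
            break
    return counts


def count_direct_paths(
    adj: FunctionalAdjacency, source: Genotype | int, target: Genotype | int
) -> int:
    """Functional direct paths source -> target (length = Hamming distance)."""
    s = source.index if isinstance(source, Genotype) else int(source)
    t = target.index if isinstance(target, Genotype) else int(target)
    return _direct_path_dp(adj, s).get(t, 0)


def connectogram(adj: FunctionalAdjacency, max_steps: int | None = None) -> TrajectoryReport:
    """Connectivity structure of the functional subgraph.

    Components are reported in block (descending-size) order; when
    ``max_steps`` is at least the subgraph diameter this equals full
    reachability, matching the summed-adjacency-power construction.
    """
    g = adj.graph()
    if max_steps is not None and max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if max_steps is None:
        comps = [frozenset(c) for c in nx.connected_components(g)]
    else:
        seen: set[int] = set()
        comps = []
        for node in sorted(adj.functional_indices):
            if node in seen:
                continue
            reach = {node} | {
                v
                for v, d in nx.single_source_shortest_path_length(
                    g, node, cutoff=max_steps
                ).items()
            }
            comps.append(frozenset(reach))
            seen |= reach
    comps.sort(key=lambda c: (-len(c), min(c)))
    return TrajectoryReport(
        source=-1, target=-1, step_counts={}, components=tuple(comps)
    )


def step_connectivity(
    adj: FunctionalAdjacency, source: Genotype | int, target: Genotype | int
) -> np.ndarray:
    """Fraction of each Hamming layer lying on a functional direct path.

    For antipodal ``source``/``target``, layer ``k`` (distance ``k`` from
    the source) contains ``C(N, k)`` genotypes; the fraction counts those
    with at least one functional direct source->g path AND one functional
    direct g->target path, via two dynamic-programming passes.  The
    denominator is the full layer size, not only its functional members.
    """
    s = source.index if isinstance(source, Genotype) else int(source)
    t = target.index if isinstance(target, Genotype) else int(target)
    n = adj.n_positions
    if s ^ t != (1 << n) - 1:
        raise ValueError("step connectivity requires an antipodal source/target pair")
    fwd = _direct_path_dp(adj, s)
    bwd = _direct_path_dp(adj, t)
    on_path = [
        g for g in fwd if bwd.get(g, 0) > 0 and fwd[g] > 0
    ]
    layers = np.zeros(n + 1, dtype=np.int64)
    for g in on_path:
        layers[int(g ^ s).bit_count()] += 1
    denom = np.array([comb(n, k) for k in range(n + 1)], dtype=float)
    return layers / denom


def classify_pairwise(
    landscape: Landscape,
    i: int,
    j: int,
    background: Genotype | int = 0,
    tol: float = 1e-9,
) -> PairClass:
    """Classify the 2x2 sub-square at positions ``i``, ``j`` (1-based).

    With ``a1 = y(10) - y(00)``, ``a2 = y(11) - y(01)`` (effect of mutating
    ``i`` without/with ``j``) and ``b1``, ``b2`` the analogues for ``j``:
    reciprocal sign epistasis if both effects flip sign, sign epistasis if
    exactly one does, magnitude epistasis if neither flips but ``a1 != a2``,
    and no epistasis if the square is additive (within ``tol``).
    """
    n = landscape.n_positions
    if not (1 <= i <= n and 1 <= j <= n and i != j):
        raise ValueError("positions must be distinct and in 1..N")
    bg = background.index if isinstance(background, Genotype) else int(background)
    bi, bj = 1 << (i - 1), 1 << (j - 1)
    if bg & (bi | bj):
        raise ValueError("background must have positions i and j in the 0 state")
    y = landscape.phenotypes
    y00, y10 = y[bg], y[bg | bi]
    y01, y11 = y[bg | bj], y[bg | bi | bj]
    a1, a2 = y10 - y00, y11 - y01
    b1, b2 = y01 - y00, y11 - y10

    def flips(u: float, v: float) -> bool:
        return (u > tol and v < -tol) or (u < -tol and v > tol)

    if flips(a1, a2) and flips(b1, b2):
        cls = EpistasisClass.RECIPROCAL_SIGN
    elif flips(a1, a2) or flips(b1, b2):
        cls = EpistasisClass.SIGN
    elif abs(a1 - a2) > tol:
        cls = EpistasisClass.MAGNITUDE
    else:
        cls = EpistasisClass.NO_EPISTASIS
    return PairClass(pair=(i, j), background=bg, epistasis_class=cls)


def classify_pair_over_backgrounds(
    landscape: Landscape, i: int, j: int, tol: float = 1e-9
) -> dict[str, object]:
    """Aggregate the pairwise class over all ``2**(N-2)`` backgrounds.

    Returns the per-class background fractions and the modal class (ties
    broken toward the more severe class: reciprocal sign > sign >
    magnitude > none).
    """
    n = landscape.n_positions
    bi, bj = 1 << (i - 1), 1 << (j - 1)
    counts = {c: 0 for c in EpistasisClass}
    for bg in range(1 << n):
        if bg & (bi | bj):
            continue
        counts[classify_pairwise(landscape, i, j, bg, tol).epistasis_class] += 1
    total = sum(counts.values())
    severity = [
        EpistasisClass.RECIPROCAL_SIGN,
        EpistasisClass.SIGN,
        EpistasisClass.MAGNITUDE,
        EpistasisClass.NO_EPISTASIS,
    ]
    modal = max(severity, key=lambda c: (counts[c], -severity.index(c)))
    return {
        "pair": (i, j),
        "fractions": {c.value: counts[c] / total for c in EpistasisClass},
        "modal_class": modal,
    }
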