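"""Epistasis operators on complete binary genotype landscapes.

Epistasis is a linear change of basis: a vector of ``2**N`` phenotypes in
binary order maps to a vector of ``2**N`` interaction terms,

    omega = Omega @ y,

where the *order* of term ``i`` is the popcount of ``i``.  Two operator
forms are supported:

* **background-averaged** — ``Omega = V @ H``, a weighted Walsh-Hadamard
  transform whose order-``o`` terms average an interaction over all
  ``2**(N-o)`` genetic backgrounds; the order-0 term is the landscape mean.
* **single-reference** — ``Omega = V @ X.T @ H``, the local (Taylor-like)
  expansion around one reference genotype (index 0 by convention; other
  references via :func:`rereference`); the order-0 term is the reference
  phenotype.

The generators are defined by the 2x2 block recursions (most-significant
bit indexes the outer block, ``V0 = H0 = X0 = 1``)::

    V_{n+1} = [[V_n/2, 0 ], [0,   -V_n]]
    H_{n+1} = [[H_n,   H_n], [H_n, -H_n]]
    X_{n+1} = [[X_n,   0 ], [X_n,  X_n]]

so each operator is the N-fold Kronecker power of its 2x2 block, which
gives both a dense construction and an O(N 2**N) in-place butterfly
(:func:`fast_transform`).  All entries are dyadic rationals, exactly
representable in binary floating point; inverses are built analytically
(``Omega_ba^-1 = H V^-1 / 2**N``; the single-reference inverse is ``X``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype_space import Genotype, order_of_index

__all__ = [
    "Form",
    "EpistasisOperator",
    "Landscape",
    "EpistasisSpectrum",
    "FitMetrics",
    "build_operator",
    "epistasis_transform",
    "fast_transform",
    "inverse_fast_transform",
    "reconstruct",
    "goodness_of_fit",
    "rank_terms",
    "rereference",
]


class Form(str, enum.Enum):
    """Which expansion of the landscape an operator/spectrum uses."""

    BACKGROUND_AVERAGED = "background_averaged"
    SINGLE_REFERENCE = "single_reference"

    @classmethod
    def coerce(cls, value: "Form | str") -> "Form":
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown epistasis form {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


# 2x2 Kronecker blocks, MSB-outer convention.
_V1 = np.array([[0.5, 0.0], [0.0, -1.0]])
_H1 = np.array([[1.0, 1.0], [1.0, -1.0]])
_X1 = np.array([[1.0, 0.0], [1.0, 1.0]])


def _kron_power(block: np.ndarray, n: int) -> np.ndarray:
    out = np.array([[1.0]])
    for _ in range(n):
        out = np.kron(out, block)
    return out


@dataclass(frozen=True)
class Landscape:
    """A complete phenotype vector over the ``2**N`` genotypes.

    ``noise_sd``, when present, holds an independent measurement SD per
    variant (used by error propagation in :mod:`epicube.significance`).
    """

    n_positions: int
    phenotypes: np.ndarray
    noise_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.phenotypes, dtype=float)
        object.__setattr__(self, "phenotypes", y)
        size = 1 << self.n_positions
        if y.shape != (size,):
            raise ValueError(
                f"phenotype vector has shape {y.shape}, expected ({size},) "
                f"for N={self.n_positions}"
            )
        if not np.isfinite(y).all():
            raise ValueError("phenotypes must be finite")
        if self.noise_sd is not None:
            sd = np.asarray(self.noise_sd, dtype=float)
            object.__setattr__(self, "noise_sd", sd)
            if sd.shape != (size,):
                raise ValueError("noise_sd must match the phenotype vector")
            if not (np.isfinite(sd).all() and (sd >= 0).all()):
                raise ValueError("noise_sd must be finite and nonnegative")

    @property
    def size(self) -> int:
        return 1 << self.n_positions


@dataclass(frozen=True)
class EpistasisSpectrum:
    """Interaction terms of all orders for one landscape.

    ``terms[i]`` is the term with participating-position set given by the
    bits of ``i``; ``order(i) = popcount(i)``.
    """

    n_positions: int
    form: Form
    terms: np.ndarray
    reference_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.terms, dtype=float)
        object.__setattr__(self, "terms", t)
        object.__setattr__(self, "form", Form.coerce(self.form))
        if t.shape != (1 << self.n_positions,):
            raise ValueError("terms length must be 2**N")

    @property
    def orders(self) -> np.ndarray:
        return order_of_index(np.arange(self.terms.size))


@dataclass(frozen=True)
class FitMetrics:
    """Reconstruction quality: R^2 = 1 - SSE/SST and GoP = 1/(1 + SSE/SST).

    R^2 may be negative (a fit worse than the mean); GoP maps the same
    error ratio into (0, 1].
    """

    sse: float
    sst: float

    @property
    def r_squared(self) -> float:
        return 1.0 - self.sse / self.sst

    @property
    def gop(self) -> float:
        return 1.0 / (1.0 + self.sse / self.sst)


@dataclass(frozen=True)
class EpistasisOperator:
    """Dense operator Omega with its generators and analytic inverse."""

    n_positions: int
    form: Form
    V: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    matrix: np.ndarray = field(repr=False)
    inverse: np.ndarray = field(repr=False)

    def order_selector(self, max_order: int) -> np.ndarray:
        """Diagonal 0/1 selector S retaining terms of order <= max_order."""
        orders = order_of_index(np.arange(1 << self.n_positions))
        return np.diag((orders <= max_order).astype(float))


def build_operator(n_positions: int, form: Form | str) -> EpistasisOperator:
    """Construct the dense operator for ``N`` positions in either form."""
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    form = Form.coerce(form)
    V = _kron_power(_V1, n_positions)
    H = _kron_power(_H1, n_positions)
    X = _kron_power(_X1, n_positions)
    size = 1 << n_positions
    v_inv_diag = 1.0 / np.diag(V)
    if form is Form.BACKGROUND_AVERAGED:
        matrix = V @ H
        # H @ H = 2**N I and V is diagonal, so the inverse is closed-form.
        inverse = H * v_inv_diag[np.newaxis, :] / size
    else:
        matrix = V @ X.T @ H
        inverse = X  # (V X^T H)^-1 = X: Kronecker power of [[1,0],[1,1]]
    return EpistasisOperator(
        n_positions=n_positions, form=form, V=V, H=H, X=X,
        matrix=matrix, inverse=inverse,
    )


def epistasis_transform(
    landscape: Landscape,
    form: Form | str,
    reference: Genotype | int = 0,
) -> EpistasisSpectrum:
    """Forward transform: interaction terms of a complete landscape.

    For the single-reference form, a non-zero ``reference`` is handled by
    XOR-relabelling the cube so the reference sits at index 0
    (:func:`rereference`), then applying the index-0 operator.
    """
    form = Form.coerce(form)
    ref_index = reference.index if isinstance(reference, Genotype) else int(reference)
    if form is Form.SINGLE_REFERENCE and ref_index != 0:
        landscape = rereference(landscape, ref_index)
    elif not 0 <= ref_index < landscape.size:
        raise ValueError(f"reference index {ref_index} out of range")
    terms = fast_transform(landscape.phenotypes, landscape.n_positions, form)
    return EpistasisSpectrum(
        n_positions=landscape.n_positions,
        form=form,
        terms=terms,
        reference_index=ref_index if form is Form.SINGLE_REFERENCE else 0,
    )


def _butterfly(values: np.ndarray, n: int, block: np.ndarray) -> np.ndarray:
    """Apply the N-fold Kronecker power of a 2x2 block in O(N 2**N)."""
    out = values.astype(float).copy()
    a, b, c, d = block.ravel()
    for bit in range(n):
        shaped = out.reshape(-1, 2, 1 << bit)
        lo = shaped[:, 0, :].copy()
        hi = shaped[:, 1, :]
        shaped[:, 0, :] = a * lo + b * hi
        shaped[:, 1, :] = c * lo + d * hi
    return out


_FORWARD_BLOCK = {
    Form.BACKGROUND_AVERAGED: _V1 @ _H1,            # [[1/2, 1/2], [-1, 1]]
    Form.SINGLE_REFERENCE: _V1 @ _X1.T @ _H1,       # [[1, 0], [-1, 1]]
}
_INVERSE_BLOCK = {
    Form.BACKGROUND_AVERAGED: np.array([[1.0, -0.5], [1.0, 0.5]]),
    Form.SINGLE_REFERENCE: _X1,
}


def fast_transform(
    phenotypes: np.ndarray | Landscape, n_positions: int | None = None,
    form: Form | str = Form.BACKGROUND_AVERAGED,
) -> np.ndarray:
    """Butterfly evaluation of ``Omega @ y``; equals the dense route."""
    if isinstance(phenotypes, Landscape):
        n_positions = phenotypes.n_positions
        phenotypes = phenotypes.phenotypes
    y = np.asarray(phenotypes, dtype=float)
    if n_positions is None or y.shape != (1 << n_positions,):
        raise ValueError("phenotype vector length must be 2**N")
    return _butterfly(y, n_positions, _FORWARD_BLOCK[Form.coerce(form)])


def inverse_fast_transform(
    terms: np.ndarray, n_positions: int, form: Form | str = Form.BACKGROUND_AVERAGED
) -> np.ndarray:
    """Butterfly evaluation of ``Omega^-1 @ omega``."""
    t = np.asarray(terms, dtype=float)
    if t.shape != (1 << n_positions,):
        raise ValueError("term vector length must be 2**N")
    return _butterfly(t, n_positions, _INVERSE_BLOCK[Form.coerce(form)])


def reconstruct(
    spectrum: EpistasisSpectrum, keep: Iterable[int] | np.ndarray | None = None
) -> Landscape:
    """Invert the transform using only the terms in ``keep``.

    ``y_hat = Omega^-1 @ omega_kept`` with terms outside ``keep`` zeroed.
    ``keep=None`` keeps every term (exact round trip); an empty ``keep``
    returns the all-zero landscape.
    """
    terms = spectrum.terms
    if keep is not None:
        keep_idx = np.asarray(sorted(set(int(i) for i in keep)), dtype=np.int64)
        if keep_idx.size and (keep_idx[0] < 0 or keep_idx[-1] >= terms.size):
            raise ValueError("keep contains out-of-range term indices")
        masked = np.zeros_like(terms)
        masked[keep_idx] = terms[keep_idx]
        terms = masked
    y = inverse_fast_transform(terms, spectrum.n_positions, spectrum.form)
    return Landscape(spectrum.n_positions, y)


def goodness_of_fit(y: Landscape | np.ndarray, yhat: Landscape | np.ndarray) -> FitMetrics:
    """Score a reconstruction: SSE, SST, R^2 and GoP.

    SST is the total sum of squares of ``y`` about its mean; a constant
    target leaves R^2 undefined and raises.
    """
    yv = y.phenotypes if isinstance(y, Landscape) else np.asarray(y, dtype=float)
    yh = yhat.phenotypes if isinstance(yhat, Landscape) else np.asarray(yhat, dtype=float)
    if yv.shape != yh.shape:
        raise ValueError("y and yhat must have equal length")
    sse = float(np.sum((yv - yh) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: target landscape is constant (SST = 0)")
    return FitMetrics(sse=sse, sst=sst)


def term_contributions(spectrum: EpistasisSpectrum) -> np.ndarray:
    """Exact SSE contribution of each background-averaged term.

    The columns of ``Omega^-1`` are mutually orthogonal with squared norm
    ``2**(N - 2*order)``, so dropping term ``i`` adds exactly
    ``terms[i]**2 * 2**(N - 2*order(i))`` to the reconstruction SSE and the
    contributions are additive over any kept/dropped split.
    """
    if spectrum.form is not Form.BACKGROUND_AVERAGED:
        raise ValueError("term ranking is defined for the background-averaged form")
    orders = spectrum.orders
    col_sq_norm = np.exp2(spectrum.n_positions - 2.0 * orders)
    return spectrum.terms**2 * col_sq_norm


def rank_terms(spectrum: EpistasisSpectrum) -> np.ndarray:
    """Term indices by descending explained-variance contribution.

    Ties broken by ascending order, then ascending index, so the ranking is
    deterministic and the R^2 of a top-``k`` reconstruction is
    non-decreasing in ``k``.
    """
    contrib = term_contributions(spectrum)
    orders = spectrum.orders
    idx = np.arange(contrib.size)
    return np.asarray(
        sorted(idx, key=lambda i: (-contrib[i], orders[i], i)), dtype=np.int64
    )


def rereference(landscape: Landscape, new_reference: Genotype | int) -> Landscape:
    """Relabel the cube so ``new_reference`` becomes index 0.

    Phenotypes are permuted by ``index XOR new_reference``; the
    single-reference transform of the result is the expansion around the
    new reference.  An involution: applying twice is the identity.
    """
    ref = new_reference.index if isinstance(new_reference, Genotype) else int(new_reference)
    if not 0 <= ref < landscape.size:
        raise ValueError(f"reference index {ref} out of range")
    perm = np.arange(landscape.size) ^ ref
    sd = landscape.noise_sd[perm] if landscape.noise_sd is not None else None
    return Landscape(landscape.n_positions, landscape.phenotypes[perm], sd)
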