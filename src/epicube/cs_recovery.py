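"""Compressed-sensing recovery of sparse epistasis from few phenotypes.

Because the background-averaged interaction spectrum of a real landscape is
sparse, it can be estimated from phenotypes of a small random subset of
genotypes by L1-norm minimization (basis pursuit):

    min ||omega||_1   subject to   ||A @ omega - y_obs||_2 <= noise_bound,

where ``A`` holds the sampled rows of ``Omega^-1`` (each observed phenotype
is a linear functional of the full spectrum).  Column norms of the weighted
basis scale with interaction order; columns are normalised to unit norm
before solving (and the scaling undone on output) so that sparsity is not
biased by order — a raw-basis mode is available.

Solvers: the noiseless case is the classical basis-pursuit linear program
(solved with scipy's HiGHS); the noisy case is solved on the lasso path
(scikit-learn coordinate descent) by bisecting the penalty to the smallest
value whose residual meets ``noise_bound`` — the basis-pursuit-denoising
solution lies on that path.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .operators import (
    EpistasisSpectrum,
    FitMetrics,
    Form,
    Landscape,
    goodness_of_fit,
    inverse_fast_transform,
    reconstruct,
)
from .genotype_space import order_of_index

__all__ = [
    "SamplingDesign",
    "SolverStatus",
    "CsSolution",
    "sample_design",
    "sensing_matrix",
    "cs_estimate",
    "evaluate_prediction",
    "support",
]


@dataclass(frozen=True)
class SamplingDesign:
    """A random subset of genotype indices whose phenotypes are observed."""

    n_positions: int
    sampled_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.sampled_indices, dtype=np.int64)
        object.__setattr__(self, "sampled_indices", idx)
        size = 1 << self.n_positions
        if idx.size == 0 or idx.min() < 0 or idx.max() >= size:
            raise ValueError("sampled indices out of range")
        if np.unique(idx).size != idx.size:
            raise ValueError("sampled indices must be distinct")

    @property
    def fraction(self) -> float:
        return self.sampled_indices.size / (1 << self.n_positions)


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    MAX_ITER = "max_iter"
    INFEASIBLE = "infeasible"


@dataclass(frozen=True)
class CsSolution:
    """An L1-recovered spectrum with solver diagnostics."""

    spectrum: EpistasisSpectrum
    residual_norm: float
    solver_status: SolverStatus
    regularization: float
    design: SamplingDesign = field(repr=False)


def sample_design(n_positions: int, fraction: float, seed: int) -> SamplingDesign:
    """Uniform sample without replacement of ``round(fraction * 2**N)`` genotypes."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    size = 1 << n_positions
    n_sample = int(round(fraction * size))
    if n_sample < n_positions + 1:
        warnings.warn(
            f"sampling {n_sample} genotypes is fewer than N+1={n_positions + 1}; "
            "even additive effects are underdetermined",
            stacklevel=2,
        )
        n_sample = max(n_sample, 1)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(size, size=n_sample, replace=False))
    return SamplingDesign(n_positions=n_positions, sampled_indices=idx, seed=seed)


def sensing_matrix(design: SamplingDesign) -> np.ndarray:
    """Sampled rows of ``Omega^-1``: maps a spectrum to observed phenotypes.

    Row for genotype ``g``: ``Omega^-1[g, i] = (-1/2)**order(i) * [i AND NOT g
    empty] * 2**order(i) ...`` — built here column-block-free via the closed
    form ``Omega^-1 = H V^-1 / 2**N`` using bit arithmetic.
    """
    n = design.n_positions
    size = 1 << n
    g = design.sampled_indices[:, None].astype(np.uint64)
    i = np.arange(size, dtype=np.uint64)[None, :]
    # H[g, i] = (-1)^popcount(g & i); (V^-1)_ii = (-1)^o * 2^(N - o), o = order(i)
    h_sign = 1.0 - 2.0 * (np.bitwise_count(g & i) % 2).astype(float)
    o = order_of_index(np.arange(size))
    v_inv = ((-1.0) ** o) * np.exp2(n - o)
    return h_sign * v_inv[None, :] / size


def _basis_pursuit_lp(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, SolverStatus]:
    """Noiseless basis pursuit as the standard LP split omega = u - v, u,v >= 0."""
    m, p = A.shape
    c = np.ones(2 * p)
    res = linprog(
        c,
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=[(0, None)] * (2 * p),
        method="highs",
    )
    if res.status == 0:
        status = SolverStatus.OPTIMAL
    elif res.status == 2:
        status = SolverStatus.INFEASIBLE
    else:
        status = SolverStatus.MAX_ITER
    x = res.x if res.x is not None else np.zeros(2 * p)
    return x[:p] - x[p:], status


def _bpdn_lasso_path(
    A: np.ndarray, y: np.ndarray, eps: float
) -> tuple[np.ndarray, float, SolverStatus]:
    """Smallest-penalty lasso solution whose residual norm is <= eps.

    The lasso residual norm is nondecreasing in the penalty, so bisection
    on log(alpha) locates the basis-pursuit-denoising solution.
    """
    m = A.shape[0]
    alpha_max = np.abs(A.T @ y).max() / m
    if np.linalg.norm(y) <= eps:  # zero spectrum already feasible
        return np.zeros(A.shape[1]), alpha_max, SolverStatus.OPTIMAL
    lo, hi = alpha_max * 1e-6, alpha_max
    best: np.ndarray | None = None
    best_alpha = hi
    model = Lasso(fit_intercept=False, max_iter=100_000, tol=1e-8, warm_start=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        while hi / lo > 1.01:
            alpha = float(np.sqrt(lo * hi))
            model.set_params(alpha=alpha)
            model.fit(A, y)
            resid = float(np.linalg.norm(y - A @ model.coef_))
            if resid <= eps:
                best, best_alpha = model.coef_.copy(), alpha
                lo = alpha  # feasible: a larger penalty may still be feasible
            else:
                hi = alpha
        if best is None:
            # even the least-penalised endpoint missed eps: report it
            model.set_params(alpha=lo, max_iter=300_000)
            model.fit(A, y)
            return model.coef_.copy(), lo, SolverStatus.MAX_ITER
    return best, best_alpha, SolverStatus.OPTIMAL


def cs_estimate(
    observed: np.ndarray,
    design: SamplingDesign,
    noise_bound: float = 0.0,
    normalize_columns: bool = True,
) -> CsSolution:
    """Recover a background-averaged spectrum from sampled phenotypes.

    ``observed[k]`` is the phenotype of genotype ``design.sampled_indices[k]``.
    With ``noise_bound = 0`` and full sampling this reproduces the exact
    transform (a determined linear system); with partial sampling it is
    basis pursuit; with ``noise_bound > 0`` basis-pursuit denoising.
    """
    y = np.asarray(observed, dtype=float)
    if y.shape != design.sampled_indices.shape:
        raise ValueError("observed values must align with the design indices")
    if noise_bound < 0:
        raise ValueError("noise_bound must be nonnegative")
    A = sensing_matrix(design)
    scale = np.linalg.norm(A, axis=0) if normalize_columns else np.ones(A.shape[1])
    scale[scale == 0] = 1.0
    An = A / scale[None, :]

    if noise_bound == 0.0:
        coef, status = _basis_pursuit_lp(An, y)
        alpha = 0.0
    else:
        coef, alpha, status = _bpdn_lasso_path(An, y, noise_bound)
    omega = coef / scale
    resid = float(np.linalg.norm(A @ omega - y))
    spectrum = EpistasisSpectrum(
        n_positions=design.n_positions, form=Form.BACKGROUND_AVERAGED, terms=omega
    )
    return CsSolution(
        spectrum=spectrum,
        residual_norm=resid,
        solver_status=status,
        regularization=float(alpha),
        design=design,
    )


def support(solution: CsSolution | EpistasisSpectrum, rtol: float = 0.02) -> np.ndarray:
    """Indices of recovered nonzero terms.

    Magnitudes are compared in the unit-column (observation) basis — each
    term weighted by its basis-column norm ``2**((N - 2*order)/2)`` — so
    that "nonzero" means "contributes to the measured phenotypes", not
    "large on the raw order-inflated scale".  A term is in the support when
    its weighted magnitude exceeds ``rtol`` times the largest one.
    """
    if isinstance(solution, CsSolution):
        spec = solution.spectrum
    else:
        spec = solution
    weight = np.exp2((spec.n_positions - 2.0 * spec.orders) / 2.0)
    c = np.abs(spec.terms) * weight
    scale = c.max()
    if scale == 0:
        return np.asarray([], dtype=np.int64)
    return np.flatnonzero(c > rtol * scale).astype(np.int64)


def evaluate_prediction(
    solution: CsSolution, truth: Landscape, heldout_only: bool = False
) -> FitMetrics:
    """Reconstruct all phenotypes from the recovered spectrum and score them.

    With ``heldout_only`` the score is restricted to genotypes outside the
    sampling design (pure prediction).
    """
    yhat = inverse_fast_transform(
        solution.spectrum.terms, truth.n_positions, Form.BACKGROUND_AVERAGED
    )
    if heldout_only:
        mask = np.ones(truth.size, dtype=bool)
        mask[solution.design.sampled_indices] = False
        return goodness_of_fit(truth.phenotypes[mask], yhat[mask])
    return goodness_of_fit(truth.phenotypes, yhat)
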