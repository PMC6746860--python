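"""Noise propagation and selection of significant epistatic terms.

Measurement noise on the phenotypes is propagated linearly through the
epistasis operator: with independent per-variant SDs ``sigma_j``,

    sd(term i) = sqrt( sum_j Omega_ij**2 * sigma_j**2 ).

For homoscedastic noise ``sigma`` and the background-averaged operator
(|Omega_ij| = (1/2)**(N - order)), this collapses to the closed form
``sigma * 2**(order - N/2)``: higher-order terms average fewer backgrounds
and are noisier.  Terms are tested with normal-theory two-sided p-values
at a raw threshold (default p < 0.01, no multiple-testing correction; an
optional Benjamini-Hochberg mode is provided).  The order-0 term is the
landscape mean (or the reference phenotype), not an interaction, and is
never tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .operators import EpistasisOperator, EpistasisSpectrum, Form, _butterfly

__all__ = [
    "SignificanceTable",
    "propagate_noise",
    "significant_terms",
    "order_distribution",
]


@dataclass(frozen=True)
class SignificanceTable:
    """Per-term values, propagated SDs, z/p statistics and selection flags."""

    n_positions: int
    values: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    threshold_p: float
    corrected: bool = False

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def orders(self) -> np.ndarray:
        from .genotype_space import order_of_index

        return order_of_index(np.arange(self.values.size))


def propagate_noise(
    op: EpistasisOperator | int,
    noise_sd: np.ndarray,
    form: Form | str = Form.BACKGROUND_AVERAGED,
) -> np.ndarray:
    """Per-term SDs from independent per-variant phenotype SDs.

    Accepts a dense operator or just ``N`` (the elementwise-squared
    operator is itself a Kronecker power, so large ``N`` never needs the
    dense matrix).
    """
    sd = np.asarray(noise_sd, dtype=float)
    if (sd < 0).any() or not np.isfinite(sd).all():
        raise ValueError("noise_sd must be finite and nonnegative")
    if isinstance(op, EpistasisOperator):
        if sd.shape != (1 << op.n_positions,):
            raise ValueError("noise_sd length must be 2**N")
        return np.sqrt((op.matrix**2) @ sd**2)
    n = int(op)
    if sd.shape != (1 << n,):
        raise ValueError("noise_sd length must be 2**N")
    from .operators import _FORWARD_BLOCK

    block_sq = _FORWARD_BLOCK[Form.coerce(form)] ** 2
    return np.sqrt(_butterfly(sd**2, n, block_sq))


def significant_terms(
    spectrum: EpistasisSpectrum,
    term_sd: np.ndarray,
    threshold_p: float = 0.01,
    benjamini_hochberg: bool = False,
) -> SignificanceTable:
    """Select terms with |value|/sd exceeding the normal-theory threshold.

    ``z = value / sd``; ``p`` is the two-sided normal tail probability;
    a term is selected iff ``p < threshold_p``.  A term with ``sd == 0``
    but nonzero value is noiseless and trivially significant (p = 0); a
    zero-value, zero-sd term gets p = 1.
    """
    values = spectrum.terms
    sd = np.asarray(term_sd, dtype=float)
    if sd.shape != values.shape:
        raise ValueError("term_sd must match the spectrum length")
    if (sd < 0).any():
        raise ValueError("term_sd must be nonnegative")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, values / np.where(sd > 0, sd, 1.0), np.inf * np.sign(values))
    z[(sd == 0) & (values == 0)] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[np.isinf(z)] = 0.0

    testable = np.ones_like(p, dtype=bool)
    testable[0] = False  # order-0 term is the mean/reference, not an interaction
    if benjamini_hochberg:
        p_adj = p.copy()
        p_adj[testable] = stats.false_discovery_control(p[testable], method="bh")
        p = p_adj
    selected = testable & (p < threshold_p)
    return SignificanceTable(
        n_positions=spectrum.n_positions,
        values=values.copy(),
        sd=sd.copy(),
        z=z,
        p=p,
        selected=selected,
        threshold_p=float(threshold_p),
        corrected=benjamini_hochberg,
    )


def order_distribution(table: SignificanceTable) -> np.ndarray:
    """Histogram of selected terms by interaction order (length N + 1)."""
    orders = table.orders
    counts = np.zeros(table.n_positions + 1, dtype=np.int64)
    np.add.at(counts, orders[table.selected], 1)
    return counts
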