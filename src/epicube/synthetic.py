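"""Synthetic landscapes and FACS-seq count tables with known ground truth.

Two generators mirror the statistical structure the analysis assumes:

* sparse interaction spectra (few nonzero terms, unimodal over orders with
  a peak at order 3-4) inverted to phenotypes plus additive Gaussian
  measurement noise — ground truth for the transform, significance and
  compressed-sensing stages;
* a sorting-and-sequencing simulator: per-cell fluorescence log-normal
  around the allele brightness, top-percentile gating per channel,
  multinomial read sampling over many uniqueness barcodes per allele,
  Poisson output counts, and injected outlier barcodes — ground truth for
  the preprocessing stage.

A third generator produces two-parent landscapes of tunable ruggedness for
connectivity analyses (both antipodal parents functional; intermediate
genotypes pruned at random).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_space import genotype_string, order_of_index
from .operators import EpistasisSpectrum, Form, Landscape, inverse_fast_transform

__all__ = [
    "SyntheticSpec",
    "CountsSimSpec",
    "CountsSimTruth",
    "default_order_weights",
    "simulate_sparse_landscape",
    "simulate_counts_experiment",
    "simulate_two_parent_landscape",
]


def default_order_weights(n_positions: int) -> np.ndarray:
    """Unimodal order profile peaking at order 3-4.

    Discretised triangular weights over orders 1..N with the mode at
    ``min(3.5, N/2)``; mirrors the empirically observed shape of
    significant-term counts without copying any dataset.
    """
    orders = np.arange(1, n_positions + 1, dtype=float)
    mode = min(3.5, n_positions / 2.0)
    width = max(n_positions - mode, mode)
    w = np.clip(1.0 - np.abs(orders - mode) / width, 0.05, None)
    return w


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a sparse-spectrum landscape.

    ``order_weights[o-1]`` is proportional to the probability that a
    planted term has order ``o``; magnitudes are drawn from
    ``magnitude_distribution`` in {fixed, normal, laplace} at ``scale``.
    """

    n_positions: int
    n_terms: int
    order_weights: np.ndarray | None = None
    magnitude_distribution: str = "normal"
    scale: float = 1.0
    noise_sd: float = 0.0
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms > (1 << self.n_positions) - 1:
            raise ValueError("n_terms exceeds the number of nonzero-order terms")
        if self.n_terms < 0 or self.noise_sd < 0 or self.scale <= 0:
            raise ValueError("invalid synthetic spec")
        w = (
            np.asarray(self.order_weights, dtype=float)
            if self.order_weights is not None
            else default_order_weights(self.n_positions)
        )
        if w.shape != (self.n_positions,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("order_weights must be N nonnegative values, sum > 0")
        object.__setattr__(self, "order_weights", w)
        if self.magnitude_distribution not in ("fixed", "normal", "laplace"):
            raise ValueError(
                f"unknown magnitude distribution {self.magnitude_distribution!r}"
            )


def simulate_sparse_landscape(
    spec: SyntheticSpec,
) -> tuple[Landscape, EpistasisSpectrum]:
    """Draw a planted sparse spectrum and its (noisy) phenotype landscape.

    The noiseless transform of the returned landscape equals the returned
    truth spectrum exactly (round-trip property).  The order-0 term is set
    to ``spec.intercept``.
    """
    rng = np.random.default_rng(spec.seed)
    size = 1 << spec.n_positions
    orders = order_of_index(np.arange(size))
    # per-index sampling probability proportional to its order's weight,
    # flat within an order
    w_of_order = np.concatenate([[0.0], spec.order_weights])
    probs = w_of_order[orders].astype(float)
    probs[0] = 0.0
    probs /= probs.sum()
    chosen = rng.choice(size, size=spec.n_terms, replace=False, p=probs)

    terms = np.zeros(size)
    if spec.magnitude_distribution == "fixed":
        mags = np.full(spec.n_terms, spec.scale) * rng.choice([-1, 1], spec.n_terms)
    elif spec.magnitude_distribution == "normal":
        mags = rng.normal(0.0, spec.scale, spec.n_terms)
    else:
        mags = rng.laplace(0.0, spec.scale, spec.n_terms)
    terms[chosen] = mags
    terms[0] = spec.intercept

    truth = EpistasisSpectrum(
        n_positions=spec.n_positions, form=Form.BACKGROUND_AVERAGED, terms=terms
    )
    y = inverse_fast_transform(terms, spec.n_positions, Form.BACKGROUND_AVERAGED)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size)
    sd = np.full(size, spec.noise_sd) if spec.noise_sd > 0 else None
    return Landscape(spec.n_positions, y, sd), truth


@dataclass(frozen=True)
class CountsSimSpec:
    """Recipe for a two-channel sorting-and-sequencing experiment.

    ``gate_fraction`` is the sorted top quantile of the pooled per-cell
    brightness distribution in each channel (the study gated the top 1%);
    ``percell_lognormal_sd`` is the SD of log per-cell fluorescence around
    the allele mean; outlier barcodes have their expected output count
    multiplied by ``outlier_multiplier``.
    """

    barcodes_per_allele: int = 20
    total_input_reads: int = 1_000_000
    gate_fraction: float = 0.01
    percell_lognormal_sd: float = 0.8
    outlier_rate: float = 0.0
    outlier_multiplier: float = 100.0
    chromophore_bit: int = 2
    co_required_bits: tuple[int, ...] = (4,)
    background_brightness: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gate_fraction < 1.0:
            raise ValueError("gate_fraction must be in (0, 1)")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.barcodes_per_allele < 1 or self.total_input_reads < 1:
            raise ValueError("invalid counts simulation spec")


@dataclass(frozen=True)
class CountsSimTruth:
    """Ground truth of a simulated sorting experiment.

    ``alleles``: per (allele, channel) brightness, gate pass probability
    and true enrichment.  ``barcodes``: per (allele, uniqueness barcode,
    channel) planted-outlier flag and the clean expected output count.
    """

    alleles: pd.DataFrame
    barcodes: pd.DataFrame


def _channel_brightness(
    landscape: Landscape, spec: CountsSimSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split brightness into blue/red channels by the color convention.

    A genotype fluoresces red iff the chromophore bit and all co-required
    bits carry allele 1 (a fixture convention imitating a chromophore
    mutation that is necessary but not sufficient for the color switch);
    otherwise it fluoresces blue.  The off channel keeps a small residual.
    """
    idx = np.arange(landscape.size)
    required = (1 << spec.chromophore_bit) | sum(
        1 << b for b in spec.co_required_bits
    )
    is_red = (idx & required) == required
    y = np.clip(landscape.phenotypes, 0.0, None)
    resid = spec.background_brightness
    blue = np.where(is_red, resid * y, y)
    red = np.where(is_red, y, resid * y)
    return blue, red, is_red


def simulate_counts_experiment(
    landscape: Landscape, spec: CountsSimSpec
) -> tuple[pd.DataFrame, "CountsSimTruth"]:
    """Simulate the two-channel sort-and-sequence experiment.

    Returns ``(counts, truth)``: a counts table with one row per
    (allele, uniqueness barcode, channel), and the simulator ground truth
    — per-allele channel brightness / gate pass probabilities, and a
    per-barcode table flagging planted outliers with their clean expected
    output (an outlier on a barcode whose clean expectation is ~0 produces
    no anomalous reads and is statistically invisible).  Phenotypes must
    be nonnegative.
    """
    if (landscape.phenotypes < -1e-12).any():
        raise ValueError("counts simulation requires nonnegative phenotypes")
    rng = np.random.default_rng(spec.seed)
    size = landscape.size
    n_bc = spec.barcodes_per_allele
    blue, red, is_red = _channel_brightness(landscape, spec)

    # clone abundances: one Dirichlet draw over all (allele, barcode) clones
    abundance = rng.dirichlet(np.full(size * n_bc, 5.0)).reshape(size, n_bc)
    floor = 1e-6  # zero-brightness cells still scatter into the log domain

    rows = []
    truth_records = []
    barcode_records: list[dict] = []
    for channel, channel_bright in (("blue", blue), ("red", red)):
        mu = np.log(np.maximum(channel_bright, floor))
        sd = spec.percell_lognormal_sd
        # population gate: top gate_fraction of pooled per-cell brightness,
        # located by Monte-Carlo over the clone-abundance mixture
        n_mc = 200_000
        alle = rng.choice(size, size=n_mc, p=abundance.sum(axis=1))
        cells = rng.normal(mu[alle], sd)
        gate = np.quantile(cells, 1.0 - spec.gate_fraction)
        # per-allele pass probability = upper tail mass beyond the gate
        from scipy.stats import norm

        p_pass = norm.sf(gate, loc=mu, scale=sd)

        n_in = rng.multinomial(spec.total_input_reads, abundance.ravel()).reshape(
            size, n_bc
        )
        outlier = rng.random((size, n_bc)) < spec.outlier_rate
        # output reads scaled so that a pass-everything allele enriches to
        # ~1/gate_fraction with equal sequencing depth in and out
        expected_out = n_in * p_pass[:, None] / spec.gate_fraction
        expected_out = np.where(outlier, expected_out * spec.outlier_multiplier, expected_out)
        n_out = rng.poisson(expected_out)

        for g in range(size):
            gstr = genotype_string(g, landscape.n_positions)
            for k in range(n_bc):
                rows.append(
                    (gstr, f"bc{k:03d}", channel, int(n_in[g, k]), int(n_out[g, k]))
                )
                barcode_records.append(
                    {
                        "allele_barcode": gstr,
                        "uniqueness_barcode": f"bc{k:03d}",
                        "channel": channel,
                        "is_outlier": bool(outlier[g, k]),
                        "clean_expected_out": float(
                            n_in[g, k] * p_pass[g] / spec.gate_fraction
                        ),
                    }
                )
        for g in range(size):
            truth_records.append(
                {
                    "allele_barcode": genotype_string(g, landscape.n_positions),
                    "channel": channel,
                    "brightness": channel_bright[g],
                    "is_red": bool(is_red[g]),
                    "p_pass": float(p_pass[g]),
                    "true_enrichment": float(p_pass[g] / spec.gate_fraction),
                    "n_outlier_barcodes": int(outlier[g].sum()),
                }
            )
    counts = pd.DataFrame(
        rows, columns=["allele_barcode", "uniqueness_barcode", "channel", "n_in", "n_out"]
    )
    truth = CountsSimTruth(
        alleles=pd.DataFrame.from_records(truth_records),
        barcodes=pd.DataFrame.from_records(barcode_records),
    )
    return counts, truth


def simulate_two_parent_landscape(
    n_positions: int, ruggedness: float, seed: int = 0, threshold: float = 0.73
) -> Landscape:
    """A landscape whose antipodal parents are bright, intermediates pruned.

    ``ruggedness`` in [0, 1] interpolates from a smooth additive ridge
    (every genotype functional) to a heavily pruned dumbbell in which a
    fraction ~``ruggedness`` of intermediate genotypes falls below the
    threshold.  The two parents always stay above threshold; connectivity
    between them is NOT guaranteed at high ruggedness.
    """
    if not 0.0 <= ruggedness <= 1.0:
        raise ValueError("ruggedness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    size = 1 << n_positions
    orders = np.asarray(order_of_index(np.arange(size)), dtype=float)
    # symmetric ridge: brightest at the parents, shallow dip in the middle
    depth = 0.15
    ridge = 1.0 - depth * np.sin(np.pi * orders / n_positions)
    pruned = rng.random(size) < ruggedness
    y = np.where(pruned, threshold * rng.uniform(0.0, 0.9, size), ridge)
    y[0] = ridge[0]
    y[size - 1] = ridge[size - 1]
    return Landscape(n_positions, y)
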