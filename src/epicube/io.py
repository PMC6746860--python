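"""Tabular file formats binding the pipeline stages together.

Canonical dialect: tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments.  Genotypes appear as 0/1 strings (leftmost
character = position 1); term indices are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_space import genotype_string, parse_genotype_string
from .operators import EpistasisSpectrum, Form, Landscape
from .significance import SignificanceTable

__all__ = [
    "read_landscape",
    "write_landscape",
    "read_spectrum",
    "write_spectrum",
    "read_counts",
    "write_counts",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"genotype": str,
                                                           "term_bits": str,
                                                           "allele_barcode": str,
                                                           "uniqueness_barcode": str})


def read_landscape(path: str | Path) -> Landscape:
    """Read a complete landscape TSV (columns: genotype, phenotype[, sd]).

    Validates completeness: every genotype of the inferred ``N`` must
    appear exactly once; offenders are listed in the error.
    """
    df = _read_tsv(path)
    for col in ("genotype", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    parsed = [parse_genotype_string(s) for s in df["genotype"]]
    lengths = {n for _, n in parsed}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged genotype strings (lengths {sorted(lengths)})")
    n = lengths.pop()
    size = 1 << n
    indices = np.array([i for i, _ in parsed])
    counts = np.bincount(indices, minlength=size)
    dups = np.flatnonzero(counts > 1)
    if dups.size:
        names = ", ".join(genotype_string(int(i), n) for i in dups[:5])
        raise ValueError(f"{path}: duplicate genotypes ({names})")
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        names = ", ".join(genotype_string(int(i), n) for i in missing[:5])
        more = "" if missing.size <= 5 else f" and {missing.size - 5} more"
        raise ValueError(f"{path}: incomplete landscape, missing {names}{more}")
    y = np.empty(size)
    y[indices] = df["phenotype"].to_numpy(float)
    sd = None
    if "sd" in df.columns:
        sd = np.empty(size)
        sd[indices] = df["sd"].to_numpy(float)
    return Landscape(n, y, sd)


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    n = landscape.n_positions
    df = pd.DataFrame(
        {
            "genotype": [genotype_string(i, n) for i in range(landscape.size)],
            "phenotype": landscape.phenotypes,
        }
    )
    if landscape.noise_sd is not None:
        df["sd"] = landscape.noise_sd
    df.to_csv(path, sep="\t", index=False)


def write_spectrum(
    spectrum: EpistasisSpectrum,
    path: str | Path,
    significance: SignificanceTable | None = None,
) -> None:
    """Write a spectrum TSV in ascending term-index order.

    Columns: term_index, term_bits, order, value, and when a significance
    table is supplied: sd, z, p, selected.
    """
    n = spectrum.n_positions
    size = spectrum.terms.size
    df = pd.DataFrame(
        {
            "term_index": np.arange(size),
            "term_bits": [genotype_string(i, n) for i in range(size)],
            "order": spectrum.orders,
            "value": spectrum.terms,
        }
    )
    if significance is not None:
        if significance.values.size != size:
            raise ValueError("significance table does not match the spectrum")
        df["sd"] = significance.sd
        df["z"] = significance.z
        df["p"] = significance.p
        df["selected"] = significance.selected
    with open(path, "w") as fh:
        fh.write(f"# form={spectrum.form.value}\treference={spectrum.reference_index}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_spectrum(path: str | Path) -> tuple[EpistasisSpectrum, pd.DataFrame]:
    """Read a spectrum TSV; returns the spectrum and the full table."""
    form = Form.BACKGROUND_AVERAGED
    reference = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if key == "form":
                form = Form.coerce(val)
            elif key == "reference":
                reference = int(val)
    df = _read_tsv(path)
    df = df.sort_values("term_index").reset_index(drop=True)
    size = len(df)
    n = int(size).bit_length() - 1
    if 1 << n != size:
        raise ValueError(f"{path}: spectrum length {size} is not a power of two")
    spectrum = EpistasisSpectrum(
        n_positions=n,
        form=form,
        terms=df["value"].to_numpy(float),
        reference_index=reference,
    )
    return spectrum, df


def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    from .facs import COUNT_COLUMNS

    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: counts table lacks columns {sorted(missing)}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)
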