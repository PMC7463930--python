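"""Z-scale encoding and auto-cross covariance (ACC) descriptors.

Each amino acid is described by the three Hellberg z-scales — principal
components of 29 measured physico-chemical properties, reflecting
hydrophobicity (z1), side-chain bulk (z2) and electronic properties (z3).
A peptide of length N is then summarised by auto- and cross-covariance terms

    ACC(i, j, l) = sum_{n=1..N-l} z_i[n] * z_j[n+l] / (N - l)

over all 9 ordered z-scale pairs (i, j) and lags l = 1..4, i.e. 36 ACC terms
per peptide. The 4-residue lag window mimics one alpha-helix turn (3.6
residues). Note the formula averages raw products: there is no within-peptide
mean subtraction (a ``centered=True`` variant subtracts per-peptide z-scale
means first and is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peptide_io import STANDARD_AA, Peptide, PeptideError

#: AAindex-style accessions for the packaged z-scale columns.
ZSCALE_SOURCE = "Hellberg z-scales (AAindex HELL* set, as distributed via protr)"

_LAGS_DEFAULT = (1, 2, 3, 4)


def _load_table(name: str, value_cols: Sequence[str]) -> dict[str, tuple[float, ...]]:
    with resources.files("peptraits.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    table = {row["aa"]: tuple(float(row[c]) for c in value_cols) for _, row in df.iterrows()}
    if set(table) != STANDARD_AA:
        raise ValueError(f"{name}: expected exactly the 20 standard amino acids")
    return table


def load_zscales(path: str | Path | None = None) -> dict[str, tuple[float, float, float]]:
    """Load a 20×3 z-scale table; the packaged Hellberg table by default.

    A user table must be TSV with columns ``aa, z1, z2, z3`` covering all 20
    standard amino acids.
    """
    if path is None:
        return _load_table("zscales_hellberg.tsv", ("z1", "z2", "z3"))
    df = pd.read_csv(path, sep="\t")
    table = {r["aa"]: (float(r["z1"]), float(r["z2"]), float(r["z3"])) for _, r in df.iterrows()}
    if set(table) != STANDARD_AA:
        raise ValueError(f"{path}: z-scale table must cover exactly the 20 standard amino acids")
    return table


@dataclass(frozen=True)
class DescriptorConfig:
    """ACC configuration: lags and whether to mean-center z-values per peptide."""

    lags: tuple[int, ...] = _LAGS_DEFAULT
    centered: bool = False

    def __post_init__(self) -> None:
        if not self.lags or any(l < 1 for l in self.lags):
            raise ValueError("lags must be positive integers")

    @property
    def n_terms(self) -> int:
        return 9 * len(self.lags)

    def term_names(self) -> list[str]:
        return [
            f"ACC_z{i}_z{j}_lag{l}"
            for i in (1, 2, 3)
            for j in (1, 2, 3)
            for l in self.lags
        ]


def zscale_encode(
    peptide: Peptide, table: dict[str, tuple[float, float, float]] | None = None
) -> np.ndarray:
    """Encode a peptide as an N×3 matrix of per-residue z-scale values."""
    if table is None:
        table = load_zscales()
    try:
        return np.array([table[aa] for aa in peptide.sequence], dtype=float)
    except KeyError as exc:
        raise PeptideError(
            f"peptide {peptide.id!r}: residue {exc.args[0]!r} missing from z-scale table"
        ) from exc


def acc_terms(
    peptide: Peptide,
    table: dict[str, tuple[float, float, float]] | None = None,
    config: DescriptorConfig = DescriptorConfig(),
) -> np.ndarray:
    """Compute the ACC descriptor vector (36 values by default) for one peptide.

    Ordered scale pairs are kept distinct — ACC(i,j,l) != ACC(j,i,l) in
    general, because the product pairs residue n on scale i with residue n+l
    on scale j. Raises :class:`PeptideError` when the peptide is not longer
    than the largest lag.
    """
    z = zscale_encode(peptide, table)
    n = z.shape[0]
    max_lag = max(config.lags)
    if n <= max_lag:
        raise PeptideError(
            f"peptide {peptide.id!r}: length {n} <= max lag {max_lag}; cannot compute ACC"
        )
    if config.centered:
        z = z - z.mean(axis=0)
    out = np.empty(config.n_terms)
    pos = 0
    for i in range(3):
        for j in range(3):
            for l in config.lags:
                out[pos] = z[: n - l, i] @ z[l:, j] / (n - l)
                pos += 1
    return out


def acc_table(
    peptides: Sequence[Peptide],
    table: dict[str, tuple[float, float, float]] | None = None,
    config: DescriptorConfig = DescriptorConfig(),
) -> pd.DataFrame:
    """ACC descriptors for a peptide collection, indexed by peptide id."""
    if table is None:
        table = load_zscales()
    values = np.vstack([acc_terms(p, table, config) for p in peptides])
    return pd.DataFrame(values, index=[p.id for p in peptides], columns=config.term_names())


def standardize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Mean-center and scale each descriptor column to unit sample variance.

    Returns ``(standardized, means, scales)``; the parameters can be re-applied
    to held-out peptides with :func:`apply_standardization`. Columns with zero
    variance are an error (they carry no information and break scaling).
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 peptides")
    means = table.mean(axis=0)
    scales = table.std(axis=0, ddof=1)
    dead = list(table.columns[scales == 0.0])
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (table - means) / scales, means, scales


def apply_standardization(
    table: pd.DataFrame, means: pd.Series, scales: pd.Series
) -> pd.DataFrame:
    """Apply previously fitted standardization parameters to new peptides."""
    return (table - means) / scales
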