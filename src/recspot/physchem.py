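"""Physicochemical property scales for the 20 amino acids.

Six properties per residue — hydrophobicity, hydrophilicity, side-chain
mass, pK1 (alpha-COOH), pK2 (NH3) and isoelectric point (PI) — drive the
pseudo-composition correlation function.  Before use each column is
standardized to zero mean and unit *sample* standard deviation (n-1
denominator) over the 20 amino acids; standardization is idempotent.

The raw hydrophobicity scale happens to already have zero mean and unit
sample SD, which pins down the n-1 convention: only with it does the
standardized column equal the raw one.

Two variants of the standardized table are exposed: the freshly computed
(unrounded) values, used by default downstream, and the conventional
2-decimal rounded rendition kept for cross-checks against published work.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Union

import pandas as pd

from recspot.translate import AMINO_ACIDS

PROPERTY_COLUMNS = (
    "hydrophobicity",
    "hydrophilicity",
    "side_chain_mass",
    "pK1",
    "pK2",
    "PI",
)

# Original (raw) property values, one row per amino acid.
_RAW = {
    #      hphob  hphil  mass   pK1    pK2    PI
    "A": ( 0.62, -0.5,    15,  2.35,  9.87,  6.11),
    "C": ( 0.29, -1.00,   47,  1.71, 10.78,  5.02),
    "D": (-0.90,  3.00,   59,  1.88,  9.60,  2.98),
    "E": (-0.74,  3.00,   73,  2.19,  9.67,  3.08),
    "F": ( 1.19, -2.50,   91,  2.58,  9.24,  5.91),
    "G": ( 0.48,  0.00,    1,  2.34,  9.60,  6.06),
    "H": (-0.40, -0.50,   82,  1.78,  8.97,  7.64),
    "I": ( 1.38, -1.80,   57,  2.32,  9.76,  6.04),
    "K": (-1.50,  3.00,   73,  2.20,  8.90,  9.47),
    "L": ( 1.06, -1.80,   57,  2.36,  9.60,  6.04),
    "M": ( 0.64, -1.30,   75,  2.28,  9.21,  5.74),
    "N": (-0.78,  0.20,   58,  2.18,  9.09, 10.76),
    "P": ( 0.12,  0.00,   42,  1.99, 10.60,  6.30),
    "Q": (-0.85,  0.20,   72,  2.17,  9.13,  5.65),
    "R": (-2.53,  3.00,  101,  2.18,  9.09, 10.76),
    "S": (-0.18,  0.30,   31,  2.21,  9.15,  5.68),
    "T": (-0.05, -0.40,   45,  2.15,  9.12,  5.60),
    "V": ( 1.08, -1.50,   43,  2.29,  9.74,  6.02),
    "W": ( 0.81, -3.40,  130,  2.38,  9.39,  5.88),
    "Y": ( 0.26, -2.30,  107,  2.20,  9.11,  5.63),
}

# Standardized values rounded to 2 decimals, as conventionally published.
_ROUNDED = {
    "A": ( 0.62, -0.15, -1.55,  0.78,  0.77, -0.10),
    "C": ( 0.29, -0.41, -0.52, -2.27,  2.57, -0.64),
    "D": (-0.90,  1.67, -0.13, -1.46,  0.24, -1.65),
    "E": (-0.74,  1.67,  0.33,  0.01,  0.37, -1.61),
    "F": ( 1.19, -1.19,  0.91,  1.87, -0.48, -0.20),
    "G": ( 0.48,  0.11, -2.00,  0.73,  0.24, -0.13),
    "H": (-0.40, -0.15,  0.62, -1.94, -1.01,  0.65),
    "I": ( 1.38, -0.82, -0.19,  0.63,  0.55, -0.14),
    "K": (-1.50,  1.67,  0.33,  0.06, -1.15,  1.56),
    "L": ( 1.06, -0.82, -0.19,  0.82,  0.24, -0.14),
    "M": ( 0.64, -0.56,  0.39,  0.44, -0.54, -0.29),
    "N": (-0.78,  0.22, -0.16, -0.03, -0.77,  2.20),
    "P": ( 0.12,  0.11, -0.68, -0.94,  2.21, -0.01),
    "Q": (-0.85,  0.22,  0.29, -0.08, -0.69, -0.33),
    "R": (-2.53,  1.67,  1.23, -0.03, -0.77,  2.20),
    "S": (-0.18,  0.27, -1.03,  0.11, -0.65, -0.32),
    "T": (-0.05, -0.10, -0.58, -0.18, -0.71, -0.36),
    "V": ( 1.08, -0.67, -0.65,  0.49,  0.51, -0.15),
    "W": ( 0.81, -1.65,  2.17,  0.92, -0.18, -0.22),
    "Y": ( 0.26, -1.08,  1.43,  0.06, -0.73, -0.34),
}


@dataclass(frozen=True)
class PropertyTable:
    """A 20x6 amino acid property table, raw or standardized."""

    values: pd.DataFrame
    standardized: bool

    def __post_init__(self):
        df = self.values
        if sorted(df.index) != sorted(AMINO_ACIDS):
            raise ValueError("table must have exactly one row per native amino acid")
        if tuple(df.columns) != PROPERTY_COLUMNS:
            raise ValueError(f"columns must be {PROPERTY_COLUMNS}")

    def value(self, amino_acid: str, column: str) -> float:
        return float(self.values.at[amino_acid, column])

    def to_tsv(self, sink: Union[str, Path]) -> None:
        """Export with fixed column order for inspection."""
        self.values.to_csv(sink, sep="\t", index_label="amino_acid")


def _frame(data: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(PROPERTY_COLUMNS), dtype=float
    ).loc[list(AMINO_ACIDS)]


def raw_table() -> PropertyTable:
    """The original (unstandardized) six-property table."""
    return PropertyTable(values=_frame(_RAW), standardized=False)


def standardize(table: PropertyTable) -> PropertyTable:
    """Column-wise standardization: (x - mean) / sample SD (n-1 denominator).

    Idempotent: applying it to an already standardized table returns the
    same values (to machine precision).

    Raises
    ------
    ValueError
        If a column is constant (zero SD).
    """
    df = table.values
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"cannot standardize constant column(s): {bad}")
    return PropertyTable(values=(df - df.mean()) / sd, standardized=True)


@lru_cache(maxsize=None)
def _standardized_cached(rounded: bool) -> PropertyTable:
    if rounded:
        return PropertyTable(values=_frame(_ROUNDED), standardized=True)
    return standardize(raw_table())


def standardized_table(rounded: bool = False) -> PropertyTable:
    """The standardized property table.

    Parameters
    ----------
    rounded : bool
        If True, return the 2-decimal rounded rendition instead of freshly
        computed full-precision values.  Default False: downstream formulas
        gain nothing from rounding, so full precision is the default.
    """
    return _standardized_cached(rounded)
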