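"""Packaged reference tables: gene catalog, published result tables, IC30 weights.

The ion-channel catalog is a reconstruction of the 280-gene universe from
standard HGNC nomenclature (24 channel families); the published per-family
breakdown is followed wherever the nomenclature supplies enough members.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

_DATA = importlib.resources.files("ionsig") / "data"


class FixtureError(ValueError):
    """A packaged reference table failed its integrity checks."""


def _read_packaged(name: str) -> pd.DataFrame:
    with importlib.resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_catalog_frame() -> pd.DataFrame:
    """Catalog as a two-column frame (symbol, family)."""
    df = _read_packaged("ion_channel_catalog.tsv")
    if list(df.columns) != ["symbol", "family"]:
        raise FixtureError("catalog columns must be (symbol, family)")
    if len(df) != 280 or df["symbol"].duplicated().any():
        raise FixtureError("catalog must hold 280 unique gene symbols")
    if df["family"].nunique() != 24:
        raise FixtureError("catalog must span 24 channel families")
    return df


@dataclass(frozen=True)
class PaperFixtures:
    """The three published result tables, as printed.

    table2: p53 mutant vs wild-type differential expression (22 genes,
        fold change mutant/wild-type).
    table3: ER positive vs negative differential expression (24 genes,
        fold change positive/negative).
    table4: Spearman correlation between expression and histological
        grade (30 genes; these are the IC30 signature with rho weights).

    Adjusted P-values are kept verbatim (strings such as "<0.001").
    """

    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame


def load_fixtures() -> PaperFixtures:
    """Load and validate the packaged published tables."""
    t2 = _read_packaged("table2_p53_diffexp.tsv")
    t3 = _read_packaged("table3_er_diffexp.tsv")
    t4 = _read_packaged("table4_grade_corr.tsv")
    for df, n, value_col in ((t2, 22, "fold_change"), (t3, 24, "fold_change"), (t4, 30, "rho")):
        if len(df) != n:
            raise FixtureError(f"expected {n} rows, found {len(df)}")
        if df["symbol"].duplicated().any() or (df["symbol"] != df["symbol"].str.upper()).any():
            raise FixtureError("symbols must be unique and uppercase")
        df[value_col] = df[value_col].astype(float)
    if not ((t2["fold_change"] > 0).all() and (t3["fold_change"] > 0).all()):
        raise FixtureError("fold changes must be positive ratios")
    if not t4["rho"].between(-1, 1).all():
        raise FixtureError("correlation coefficients must lie in [-1, 1]")
    return PaperFixtures(table2=t2, table3=t3, table4=t4)


def load_ic30_frame() -> pd.DataFrame:
    """IC30 weight table (symbol, weight) = the grade-correlation table."""
    df = _read_packaged("ic30_signature.tsv")
    df["weight"] = df["weight"].astype(float)
    if len(df) != 30 or not df["weight"].between(-1, 1).all():
        raise FixtureError("IC30 weight table must hold 30 weights in [-1, 1]")
    return df
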