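"""Cohort data model and the preprocessing filters applied to expression matrices.

An :class:`ExpressionCohort` couples a log2 expression matrix (genes x samples)
with one clinical record per sample. Readers accept delimited text (TSV or CSV,
sniffed from the extension); unknown clinical values are encoded as missing,
never as zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .resources import load_catalog_frame

logger = logging.getLogger("ionsig")

CLINICAL_COLUMNS = (
    "p53_status",
    "er_status",
    "pr_status",
    "grade",
    "age_years",
    "node_status",
    "size_class",
    "time",
    "event",
)

_CATEGORICAL_LEVELS = {
    "p53_status": {"mutant", "wildtype"},
    "er_status": {"positive", "negative"},
    "pr_status": {"positive", "negative"},
    "node_status": {"positive", "negative"},
    "size_class": {"lt_T3", "ge_T3"},
}


class CohortError(ValueError):
    """Raised when cohort inputs violate the data-model invariants."""


@dataclass(frozen=True)
class GeneCatalog:
    """Ion-channel gene universe: unique uppercase symbols with family labels."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.entries]
        if not symbols:
            raise CohortError("catalog is empty")
        if any(not s for s in symbols):
            raise CohortError("catalog contains an empty symbol")
        if any(s != s.upper() for s in symbols):
            raise CohortError("catalog symbols must be uppercase")
        if len(set(symbols)) != len(symbols):
            raise CohortError("catalog symbols must be unique")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.entries)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted({f for _, f in self.entries}))

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, fam in self.entries:
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneCatalog":
        return cls(tuple((str(s).upper(), str(f)) for s, f in zip(df["symbol"], df["family"])))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        if not {"symbol", "family"} <= set(df.columns):
            raise CohortError("catalog file needs columns: symbol, family")
        return cls.from_frame(df)

    @classmethod
    def default(cls) -> "GeneCatalog":
        """The packaged 280-gene ion-channel catalog."""
        return cls.from_frame(load_catalog_frame())


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical annotation; ``None`` marks an unknown field."""

    sample_id: str
    p53_status: str | None = None
    er_status: str | None = None
    pr_status: str | None = None
    grade: int | None = None
    age_years: float | None = None
    node_status: str | None = None
    size_class: str | None = None
    time: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        for fld, levels in _CATEGORICAL_LEVELS.items():
            val = getattr(self, fld)
            if val is not None and val not in levels:
                raise CohortError(f"{self.sample_id}: {fld}={val!r} not in {sorted(levels)}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise CohortError(f"{self.sample_id}: grade must be 1, 2 or 3")
        if self.age_years is not None and self.age_years < 0:
            raise CohortError(f"{self.sample_id}: negative age")
        if self.time is not None:
            if self.time < 0:
                raise CohortError(f"{self.sample_id}: negative survival time")
            if self.event not in (0, 1):
                raise CohortError(f"{self.sample_id}: event must be 0/1 when time present")


@dataclass(frozen=True)
class ExpressionCohort:
    """Log2 expression matrix plus aligned clinical annotation for one cohort.

    ``values`` is a genes x samples DataFrame (unique uppercase gene index);
    ``clinical`` is indexed by sample_id in the same order as the matrix
    columns. ``presence`` optionally carries detection calls for the
    present-in-a-third filter.
    """

    cohort_id: str
    values: pd.DataFrame
    clinical: pd.DataFrame
    presence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate gene symbols: {dupes}")
        if self.values.columns.duplicated().any():
            raise CohortError("duplicate sample ids in expression matrix")
        if list(self.clinical.index) != list(self.values.columns):
            raise CohortError("clinical rows must align 1:1 with expression columns")
        if self.presence is not None and self.presence.shape != self.values.shape:
            raise CohortError("presence matrix shape must match expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def clinical_records(self) -> list[ClinicalRecord]:
        records = []
        for sid, row in self.clinical.iterrows():
            kwargs = {}
            for fld in CLINICAL_COLUMNS:
                val = row.get(fld)
                if pd.isna(val):
                    kwargs[fld] = None
                elif fld == "grade":
                    kwargs[fld] = int(val)
                elif fld in ("age_years", "time"):
                    kwargs[fld] = float(val)
                elif fld == "event":
                    kwargs[fld] = int(val)
                else:
                    kwargs[fld] = str(val)
            records.append(ClinicalRecord(sample_id=str(sid), **kwargs))
        return records

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionCohort":
        keep = [g for g in self.genes if g in set(genes)]
        presence = self.presence.loc[keep] if self.presence is not None else None
        return replace(self, values=self.values.loc[keep], presence=presence)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _normalize_clinical(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in CLINICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[list(CLINICAL_COLUMNS)]
    for col, levels in _CATEGORICAL_LEVELS.items():
        vals = out[col].astype("string").str.strip()
        vals = vals.where(vals.notna() & (vals != ""), pd.NA)
        bad = vals.dropna()[~vals.dropna().isin(levels)]
        if len(bad):
            raise CohortError(f"clinical column {col}: unknown level(s) {sorted(set(bad))}")
        out[col] = vals
    for col in ("grade", "age_years", "time", "event"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    return out


def read_cohort(
    expr_path: str | Path, clinical_path: str | Path, cohort_id: str
) -> ExpressionCohort:
    """Read an expression matrix and clinical table into a cohort.

    The expression file has a gene/probe first column and sample-id header;
    the clinical file is keyed by ``sample_id``. The cohort is restricted to
    samples present in both files, in expression-header order.
    """
    expr = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0)
    expr.index = expr.index.astype(str).str.upper()
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise CohortError(f"{expr_path}: duplicate gene rows: {dupes}")
    for col in expr.columns:
        bad = pd.to_numeric(expr[col], errors="coerce")
        if bad.isna().any() and not expr[col].isna().any():
            row = expr.index[bad.isna()][0]
            raise CohortError(f"{expr_path}: non-numeric value at row {row!r}, column {col!r}")
        expr[col] = bad
    clin = pd.read_csv(clinical_path, sep=_sep_for(clinical_path), dtype=str)
    if "sample_id" not in clin.columns:
        raise CohortError(f"{clinical_path}: missing sample_id column")
    if clin["sample_id"].duplicated().any():
        raise CohortError(f"{clinical_path}: duplicate sample ids")
    clin = clin.set_index("sample_id")

    shared = [s for s in expr.columns if s in set(clin.index)]
    if not shared:
        raise CohortError("no overlapping samples between expression and clinical files")
    dropped = expr.shape[1] - len(shared)
    if dropped:
        logger.info("%s: dropped %d expression sample(s) without clinical records",
                    cohort_id, dropped)
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=expr[shared].astype(float),
        clinical=_normalize_clinical(clin.loc[shared]),
    )


def write_cohort(
    cohort: ExpressionCohort, expr_path: str | Path, clinical_path: str | Path
) -> None:
    """Write a cohort back to the delimited-text interchange format."""
    out = cohort.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep=_sep_for(expr_path), float_format="%.6g")
    clin = cohort.clinical.copy()
    clin.index.name = "sample_id"
    clin.to_csv(clinical_path, sep=_sep_for(clinical_path))


def filter_by_presence(
    cohort: ExpressionCohort, min_fraction: float = 1.0 / 3.0
) -> ExpressionCohort:
    """Keep genes detected present in at least ``min_fraction`` of samples.

    The bound is inclusive: a gene present in exactly a third of samples is
    retained.
    """
    if cohort.presence is None:
        raise CohortError(
            "cohort has no presence matrix; skip the presence filter for this input"
        )
    frac = cohort.presence.astype(bool).mean(axis=1)
    keep = frac[frac >= min_fraction].index.tolist()
    removed = cohort.n_genes - len(keep)
    logger.info("%s: presence filter removed %d of %d genes",
                cohort.cohort_id, removed, cohort.n_genes)
    return cohort.subset_genes(keep)


def collapse_and_clean(
    cohort: ExpressionCohort, annotation: Mapping[str, tuple[str, str]]
) -> ExpressionCohort:
    """Map probe rows to gene symbols, dropping ambiguous and sex-chromosome probes.

    ``annotation`` maps probe id -> (gene symbol, chromosome). Probes without
    a single unambiguous symbol (missing, empty, or '///'-delimited multi-gene
    annotations) are dropped, as are probes on chromosomes X and Y. When
    several probes remain for one gene, the probe with the highest mean
    expression represents it.
    """
    rows: dict[str, list[str]] = {}
    n_unannotated = n_ambiguous = n_sex = 0
    for probe in cohort.values.index:
        if probe not in annotation:
            n_unannotated += 1
            logger.warning("%s: probe %s has no annotation; dropped", cohort.cohort_id, probe)
            continue
        symbol, chrom = annotation[probe]
        symbol = (symbol or "").strip()
        if not symbol or "///" in symbol:
            n_ambiguous += 1
            continue
        if str(chrom).upper().lstrip("CHR") in ("X", "Y"):
            n_sex += 1
            continue
        rows.setdefault(symbol.upper(), []).append(probe)

    keep_probes, symbols = [], []
    for symbol, probes in rows.items():
        if len(probes) > 1:
            means = cohort.values.loc[probes].mean(axis=1)
            best = means.idxmax()
            logger.info("%s: gene %s represented by max-mean probe %s (of %d)",
                        cohort.cohort_id, symbol, best, len(probes))
        else:
            best = probes[0]
        keep_probes.append(best)
        symbols.append(symbol)

    logger.info(
        "%s: collapse dropped %d unannotated, %d ambiguous, %d chrX/Y probes",
        cohort.cohort_id, n_unannotated, n_ambiguous, n_sex,
    )
    values = cohort.values.loc[keep_probes]
    values.index = pd.Index(symbols, name=cohort.values.index.name)
    values = values.sort_index()
    presence = None
    if cohort.presence is not None:
        presence = cohort.presence.loc[keep_probes]
        presence.index = values.index
    return replace(cohort, values=values, presence=presence)


def subset_ion_channels(cohort: ExpressionCohort, catalog: GeneCatalog) -> ExpressionCohort:
    """Restrict the cohort to catalog genes (case-insensitive symbol match)."""
    catalog_set = set(catalog.symbols)
    keep = [g for g in cohort.genes if g.upper() in catalog_set]
    if not keep:
        raise CohortError("no catalog genes found in cohort")
    unavailable = sorted(catalog_set - {g.upper() for g in keep})
    if unavailable:
        logger.info("%s: %d catalog genes unavailable in cohort: %s",
                    cohort.cohort_id, len(unavailable), ", ".join(unavailable[:10]) + ("..." if len(unavailable) > 10 else ""))
    sub = cohort.subset_genes(keep)
    values = sub.values.copy()
    values.index = values.index.str.upper()
    presence = None
    if sub.presence is not None:
        presence = sub.presence.copy()
        presence.index = values.index
    return replace(sub, values=values, presence=presence)
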