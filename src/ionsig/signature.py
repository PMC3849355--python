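"""Correlation-weighted risk scoring and the strict median split.

The risk score of a patient is

    s = sum_i rho_i * (e_i - mu_i) / tau_i

where rho_i is the Spearman correlation of gene i with grade in the
discovery cohort (the weight), e_i the patient's log2 expression, and mu_i,
tau_i the mean and sample standard deviation of gene i across **all samples
of the cohort being scored** — standardization is always cohort-internal,
which is what makes the cohort median of s sit near zero everywhere. A
patient is signature-positive when their score strictly exceeds the cohort
median; scores tied at the median are negative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .resources import load_ic30_frame

logger = logging.getLogger("ionsig")


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureModel:
    """Ordered gene symbols with correlation weights in [-1, 1]."""

    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1 or len(self.genes) != len(self.weights):
            raise SignatureError("signature needs >=1 gene with one weight each")
        if len(set(self.genes)) != len(self.genes):
            raise SignatureError("signature genes must be unique")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(np.abs(w) > 1):
            raise SignatureError("weights must be finite correlations in [-1, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.genes), name="weight")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"symbol": self.genes, "weight": self.weights})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "SignatureModel":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            name=name or Path(path).stem,
            genes=tuple(str(s).upper() for s in df["symbol"]),
            weights=tuple(float(w) for w in df["weight"]),
        )

    @classmethod
    def ic30(cls) -> "SignatureModel":
        """The packaged 30-gene grade-correlation signature."""
        df = load_ic30_frame()
        return cls(name="IC30", genes=tuple(df["symbol"]), weights=tuple(df["weight"]))


@dataclass(frozen=True)
class RiskScoreResult:
    """Per-sample risk scores plus the standardization used to compute them."""

    scores: pd.Series
    standardization: pd.DataFrame  # index: genes used; columns: mu, tau
    genes_used: tuple[str, ...]
    threshold: float | None = None
    labels: pd.Series | None = None  # "positive" / "negative"
    degenerate: bool = False


def build_signature(records: pd.DataFrame, name: str = "IC30") -> SignatureModel:
    """Turn a grade-screen table into a signature from its selected rows.

    Weights are the selected genes' rho values, carried unchanged; genes are
    ordered by symbol.
    """
    sel = records[records["selected"]].sort_values("symbol")
    if sel.empty:
        raise SignatureError("no genes selected; cannot build a signature")
    return SignatureModel(
        name=name, genes=tuple(sel["symbol"]), weights=tuple(sel["rho"])
    )


def risk_scores(model: SignatureModel, cohort: ExpressionCohort) -> RiskScoreResult:
    """Score every sample of a cohort with cohort-internal standardization.

    Signature genes absent from the cohort are skipped without reweighting
    (the score is the sum over available genes); genes with zero expression
    variance are likewise dropped, with a warning either way.
    """
    weights = model.as_series()
    available = [g for g in model.genes if g in set(cohort.genes)]
    if not available:
        raise SignatureError(
            f"none of the {len(model.genes)} signature genes found in cohort "
            f"{cohort.cohort_id!r}"
        )
    missing = [g for g in model.genes if g not in set(available)]
    if missing:
        logger.warning("%s: %d signature gene(s) unavailable: %s",
                       cohort.cohort_id, len(missing), ", ".join(missing))
    expr = cohort.values.loc[available]
    mu = expr.mean(axis=1)
    tau = expr.std(axis=1, ddof=1)
    zero = tau[tau == 0].index.tolist()
    if zero:
        logger.warning("%s: dropping zero-variance signature gene(s): %s",
                       cohort.cohort_id, ", ".join(zero))
        available = [g for g in available if g not in set(zero)]
        if not available:
            raise SignatureError("all available signature genes have zero variance")
        expr, mu, tau = expr.loc[available], mu.loc[available], tau.loc[available]
    if len(available) < 0.8 * len(model.genes):
        logger.warning("%s: only %d/%d signature genes available (<80%%)",
                       cohort.cohort_id, len(available), len(model.genes))
    z = expr.sub(mu, axis=0).div(tau, axis=0)
    scores = z.mul(weights.loc[available], axis=0).sum(axis=0)
    scores.name = "risk_score"
    return RiskScoreResult(
        scores=scores,
        standardization=pd.DataFrame({"mu": mu, "tau": tau}),
        genes_used=tuple(available),
    )


def median_split(result: RiskScoreResult) -> RiskScoreResult:
    """Label samples positive iff their score strictly exceeds the cohort median."""
    scores = result.scores
    if len(scores) < 2:
        raise SignatureError("median split needs at least 2 samples")
    threshold = float(scores.median())
    labels = pd.Series(
        np.where(scores > threshold, "positive", "negative"),
        index=scores.index,
        name="ic30_label",
    )
    degenerate = bool(scores.nunique() == 1)
    if degenerate:
        logger.warning("all risk scores identical; every sample labeled negative")
    return replace(result, threshold=threshold, labels=labels, degenerate=degenerate)
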