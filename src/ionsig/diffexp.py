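"""Two-group differential expression and the enrichment/overlap statistics.

A gene is called differentially expressed when its Benjamini-Hochberg adjusted
two-tailed t-test P-value is below ``alpha`` and its linear fold change
deviates from 1 by more than the threshold in either direction (the published
gene lists contain down-regulated genes with fold change < 1, so the
magnitude criterion is symmetric: FC > 1.25 or FC < 1/1.25).
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort

logger = logging.getLogger("ionsig")


class DiffExpError(ValueError):
    pass


def fold_change(values_ref: Sequence[float], values_int: Sequence[float]) -> float:
    """Ratio of geometric means (interest / reference) from log2 expression.

    Equals ``2 ** (mean(values_int) - mean(values_ref))``.
    """
    ref = np.asarray(values_ref, dtype=float)
    interest = np.asarray(values_int, dtype=float)
    if ref.size == 0 or interest.size == 0:
        raise DiffExpError("fold change needs both groups non-empty")
    return float(2.0 ** (interest.mean() - ref.mean()))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DiffExpError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    cohort: ExpressionCohort,
    grouping: str,
    reference: str,
    interest: str,
    alpha: float = 0.05,
    fc_threshold: float = 1.25,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two levels of a clinical field.

    Samples whose ``grouping`` field is unknown are excluded. Fold change is
    oriented interest/reference. BH adjustment runs over exactly the genes
    tested in this call. Set ``equal_var=True`` for the pooled-variance
    Student's t variant.

    Returns a DataFrame with one row per gene: symbol, mean_log2_ref,
    mean_log2_int, fold_change, t_stat, p_raw, p_adj, is_de.
    """
    status = cohort.clinical[grouping]
    ref_ids = status.index[status == reference]
    int_ids = status.index[status == interest]
    if len(ref_ids) < 2 or len(int_ids) < 2:
        raise DiffExpError(
            f"need >=2 samples per group; got {len(ref_ids)} {reference!r}, "
            f"{len(int_ids)} {interest!r}"
        )
    logger.info(
        "%s: DE on %s (%s n=%d vs %s n=%d), %d unknown excluded",
        cohort.cohort_id, grouping, reference, len(ref_ids), interest, len(int_ids),
        int(status.isna().sum()),
    )
    a = cohort.values[ref_ids].to_numpy()
    b = cohort.values[int_ids].to_numpy()
    mean_ref, mean_int = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    undefined = ~np.isfinite(p_raw)
    if undefined.any():
        for g in np.asarray(cohort.genes)[undefined]:
            logger.warning("%s: gene %s has zero variance in both groups; p set to 1",
                           cohort.cohort_id, g)
        p_raw = np.where(undefined, 1.0, p_raw)
        t_stat = np.where(undefined, np.nan, t_stat)
    fc = 2.0 ** (mean_int - mean_ref)
    p_adj = benjamini_hochberg(p_raw)
    is_de = (p_adj < alpha) & ((fc > fc_threshold) | (fc < 1.0 / fc_threshold))
    return pd.DataFrame(
        {
            "symbol": cohort.genes,
            "mean_log2_a": mean_ref,
            "mean_log2_b": mean_int,
            "fold_change": fc,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_de": is_de,
        }
    ).reset_index(drop=True)


def fisher_enrichment(
    n_de_ic: int, n_ic: int, n_de_all: int, n_all: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test for ion-channel enrichment among DE genes.

    The 2x2 table crosses catalog membership with DE status over a universe of
    ``n_all`` genes. Two-sided rule: sum of table probabilities no larger than
    the observed table's.
    """
    if not (0 <= n_de_ic <= min(n_ic, n_de_all) and n_ic <= n_all and n_de_all <= n_all
            and n_de_all - n_de_ic <= n_all - n_ic):
        raise DiffExpError("inconsistent 2x2 counts")
    table = [
        [n_de_ic, n_ic - n_de_ic],
        [n_de_all - n_de_ic, (n_all - n_ic) - (n_de_all - n_de_ic)],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def overlap_test(
    list_a: Sequence[str], list_b: Sequence[str], universe_size: int
) -> tuple[int, float]:
    """Overlap of two gene sets with a cumulative hypergeometric tail P.

    Returns (observed overlap, P(X >= overlap)) for X hypergeometric with
    ``universe_size`` genes, |a| draws, |b| successes.
    """
    a, b = set(list_a), set(list_b)
    if max(len(a), len(b)) > universe_size:
        raise DiffExpError("universe smaller than a gene list")
    k = len(a & b)
    if len(a) == 0 or len(b) == 0:
        return k, 1.0
    p_ge = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p_ge, 1.0)
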