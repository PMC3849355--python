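"""Spearman screen of gene expression against ordinal histological grade."""
from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionCohort
from .diffexp import benjamini_hochberg

logger = logging.getLogger("ionsig")


class GradeError(ValueError):
    pass


def spearman_rho(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Tie-aware Spearman correlation with a two-sided P-value.

    rho is the Pearson correlation of midranks. The P-value uses the
    t-approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of
    freedom, which is the standard reference for tied data at moderate n.
    ``exact=True`` switches to full permutation enumeration (n <= 9 only),
    where P is the fraction of permutations with |rho| at least as large.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise GradeError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GradeError("rho undefined: zero variance input")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if x.size > 9:
            raise GradeError("exact permutation p only supported for n <= 9")
        return rho, _exact_perm_p(rx, ry, abs(rho))
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    rhos = (pc @ rxc) / np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
    return float(np.mean(np.abs(rhos) >= observed - 1e-12))


def grade_screen(cohort: ExpressionCohort, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate every gene with histological grade; select at BH ``alpha``.

    Samples with unknown grade are excluded; genes with zero expression
    variance are dropped from the screen (not testable) with a warning.
    Returns one row per tested gene: symbol, rho, p_raw, p_adj, selected,
    with the selected set fully determined by p_adj < alpha.
    """
    grade = cohort.clinical["grade"]
    keep = grade.notna()
    if keep.sum() < 3:
        raise GradeError("need at least 3 samples with known grade")
    g = grade[keep].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise GradeError("all grades identical; screen undefined")
    n_unknown = int((~keep).sum())
    if n_unknown:
        logger.info("%s: grade screen excluded %d samples with unknown grade",
                    cohort.cohort_id, n_unknown)
    expr = cohort.values.loc[:, keep.index[keep]]

    symbols, rhos, praws = [], [], []
    for symbol, row in expr.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            logger.warning("%s: gene %s constant; excluded from grade screen",
                           cohort.cohort_id, symbol)
            continue
        rho, p = spearman_rho(vals, g)
        symbols.append(symbol)
        rhos.append(rho)
        praws.append(p)
    p_adj = benjamini_hochberg(praws)
    out = pd.DataFrame(
        {"symbol": symbols, "rho": rhos, "p_raw": praws, "p_adj": p_adj}
    )
    out["selected"] = out["p_adj"] < alpha
    return out.reset_index(drop=True)


def cross_cohort_concordance(
    records_by_cohort: Mapping[str, pd.DataFrame], discovery: str | None = None
) -> pd.DataFrame:
    """Compare per-gene correlation signs across cohorts.

    ``records_by_cohort`` maps cohort id to a grade-screen table; the first
    key (or ``discovery``) fixes the reference signs. Genes absent from a
    cohort are marked unavailable and excluded from that gene's agreement
    denominator. Returns a long-format table with one sign column per cohort
    and the fraction of non-discovery cohorts agreeing with the discovery
    sign.
    """
    if len(records_by_cohort) < 2:
        raise GradeError("concordance needs at least two cohorts")
    discovery = discovery or next(iter(records_by_cohort))
    signs = {
        cid: df.set_index("symbol")["rho"].apply(lambda r: int(np.sign(r)))
        for cid, df in records_by_cohort.items()
    }
    genes = list(signs[discovery].index)
    rows = []
    for gene in genes:
        row: dict[str, object] = {"symbol": gene}
        ref = signs[discovery].get(gene)
        agree = total = 0
        for cid, s in signs.items():
            val = s.get(gene)
            row[f"sign_{cid}"] = val if val is not None else "unavailable"
            if cid != discovery and val is not None:
                total += 1
                agree += int(val == ref)
        row["agreement"] = agree / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
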