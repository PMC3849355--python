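"""Hierarchical clustering with multiscale-bootstrap cluster support (AU).

For each internal dendrogram node, features are resampled with replacement at
several scales r (resample size = ceil(r * n_features)); the bootstrap
probability BP_r of a node is the fraction of replicates in which exactly the
same item set reappears as a node. Fitting

    Phi^-1(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

by weighted least squares yields the signed distance v and curvature c of the
cluster boundary, from which the approximately unbiased support AU =
1 - Phi(v - c) and the scale-1 fitted bootstrap probability BP = 1 - Phi(v + c)
follow. AU corrects the ordinary bootstrap's bias; the root node always
reappears, so its AU is 1 by construction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import norm

logger = logging.getLogger("ionsig")

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * k, 1) for k in range(10))  # 0.5 .. 1.4


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class Dendrogram:
    """scipy linkage matrix plus item labels, with set-based node access."""

    linkage_matrix: np.ndarray
    items: tuple[str, ...]
    distance: str
    linkage: str

    def node_sets(self, include_root: bool = True) -> list[frozenset[str]]:
        """Item sets of all internal nodes (size >= 2), root included last."""
        n = len(self.items)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.items[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.append(merged)
        return out if include_root else out[:-1]


def _distances(matrix: np.ndarray, distance: str) -> np.ndarray:
    """Condensed item-item distances from a features x items matrix."""
    items = matrix.T
    if distance == "euclidean":
        return pdist(items, metric="euclidean")
    if distance == "correlation":
        sds = items.std(axis=1)
        if np.any(sds == 0):
            raise ClusterError("constant item under correlation distance")
        return pdist(items, metric="correlation")
    raise ClusterError(f"unknown distance {distance!r}")


def hcluster(
    matrix: pd.DataFrame, distance: str = "correlation", linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of the matrix columns (items).

    ``matrix`` is features x items. Ward linkage requires euclidean
    distance. Merge order under tied heights follows scipy's deterministic
    nearest-neighbor-chain order, so repeated runs agree exactly.
    """
    if matrix.shape[1] < 2:
        raise ClusterError("need at least 2 items")
    if linkage not in ("average", "complete", "ward"):
        raise ClusterError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ClusterError("ward linkage requires euclidean distance")
    d = _distances(matrix.to_numpy(dtype=float), distance)
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(
        linkage_matrix=z,
        items=tuple(str(c) for c in matrix.columns),
        distance=distance,
        linkage=linkage,
    )


@dataclass(frozen=True)
class ClusterSupport:
    """Multiscale-bootstrap support for one dendrogram node."""

    node_id: int
    items: frozenset[str]
    bp_by_scale: dict[float, float]
    v: float
    c: float
    au: float
    bp: float
    low_confidence: bool = False


def au_pvalues(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
    scales: tuple[float, ...] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int = 0,
) -> list[ClusterSupport]:
    """AU and BP support for every internal node of the dendrogram.

    Resampling is over features (rows). BP values are clipped to
    [1/(B+1), B/(B+1)] so the probit transform stays finite; the weighted
    least-squares fit uses the usual binomial delta-method weights
    B * phi(psi)^2 / (BP (1 - BP)). A node whose BP sits at the same clip
    bound on every scale gets a low-confidence flag (the fit is then
    extrapolation only); the root keeps AU = BP = 1 exactly.
    """
    if B < 100:
        raise ClusterError("need B >= 100 bootstrap replicates per scale")
    if len(scales) < 2 or min(scales) >= 1 or max(scales) <= 1:
        raise ClusterError("scales must span both sides of r = 1")
    rng = np.random.default_rng(seed)
    dendro = hcluster(matrix, distance=distance, linkage=linkage)
    nodes = dendro.node_sets()
    root = nodes[-1]
    n_features = matrix.shape[0]
    data = matrix.to_numpy(dtype=float)

    counts = {s: np.zeros(len(nodes), dtype=int) for s in scales}
    node_pos = {node: i for i, node in enumerate(nodes)}
    for scale in scales:
        m = math.ceil(scale * n_features)
        for _ in range(B):
            rows = rng.integers(0, n_features, size=m)
            boot = pd.DataFrame(data[rows], columns=matrix.columns)
            try:
                rep = hcluster(boot, distance=distance, linkage=linkage)
            except ClusterError:
                continue  # degenerate resample (constant item); counts unchanged
            for ns in rep.node_sets():
                pos = node_pos.get(ns)
                if pos is not None:
                    counts[scale][pos] += 1

    lo, hi = 1.0 / (B + 1), B / (B + 1)
    out = []
    for i, node in enumerate(nodes):
        bp_by_scale = {s: counts[s][i] / B for s in scales}
        if node == root:
            out.append(
                ClusterSupport(
                    node_id=i, items=node, bp_by_scale=bp_by_scale,
                    v=float("-inf"), c=0.0, au=1.0, bp=1.0,
                )
            )
            continue
        bp_raw = np.array([bp_by_scale[s] for s in scales])
        usable = (bp_raw > 0.0) & (bp_raw < 1.0)
        if usable.sum() < 2:
            # BP pinned at 0 or 1 on (almost) every scale: the probit fit
            # carries no scale information, so report the ceiling/floor
            # value directly and flag the node
            ceiling = bool(bp_raw.mean() >= 0.5)
            logger.warning("node %d: BP at %s on all scales; AU fallback used",
                           i, "ceiling" if ceiling else "floor")
            out.append(
                ClusterSupport(
                    node_id=i, items=node, bp_by_scale=bp_by_scale,
                    v=float("nan"), c=float("nan"),
                    au=1.0 if ceiling else 0.0,
                    bp=1.0 if ceiling else 0.0,
                    low_confidence=True,
                )
            )
            continue
        bp_clipped = np.clip(bp_raw[usable], lo, hi)
        psi = norm.ppf(1.0 - bp_clipped)
        r = np.asarray(scales)[usable]
        design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        w = B * norm.pdf(psi) ** 2 / (bp_clipped * (1.0 - bp_clipped))
        wd = design * w[:, None]
        v, c = np.linalg.solve(design.T @ wd, wd.T @ psi)
        au = float(1.0 - norm.cdf(v - c))
        bp_fit = float(1.0 - norm.cdf(v + c))
        degenerate = bool(np.all(psi == psi[0]))
        if degenerate:
            logger.warning("node %d: constant BP across usable scales; "
                           "AU is low-confidence", i)
        out.append(
            ClusterSupport(
                node_id=i, items=node, bp_by_scale=bp_by_scale,
                v=float(v), c=float(c), au=au, bp=bp_fit,
                low_confidence=degenerate,
            )
        )
    return out


def support_table(supports: list[ClusterSupport]) -> pd.DataFrame:
    """Long-format (node_id, items, au, bp) table for export."""
    return pd.DataFrame(
        {
            "node_id": [s.node_id for s in supports],
            "items": [",".join(sorted(s.items)) for s in supports],
            "au": [s.au for s in supports],
            "bp": [s.bp for s in supports],
            "low_confidence": [s.low_confidence for s in supports],
        }
    )
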