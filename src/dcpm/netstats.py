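"""Anatomy of predictive networks: composition, overlap, and comparisons.

Edges of a predictive network are located within a partition of the nodes
into functional networks (10 in the reference parcellation).  Composition
is the percentage of each functional-network pair's possible edges that the
predictive subnetwork contains, with enrichment significance from the
upper-tail hypergeometric distribution.  Overlap between two predictive
networks is the intersection size normalized by the smaller network, again
with hypergeometric significance against the full edge universe
(C(377, 2) = 70,876 for the reference parcellation); degrees of overlap are
compared with 2x2 chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom

from .cpm import Edge, PredictiveNetwork


@dataclass
class AtlasPartition:
    """Node index -> functional-network label."""

    labels: np.ndarray  # one label string per node

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def nodes_of(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.labels == network)


@dataclass
class OverlapTest:
    """Hypergeometric overlap between two edge sets in an M-edge universe.

    overlap_percent normalizes x by the smaller network so networks of
    different sizes are comparable; p is the upper tail P(X >= x) of the
    hypergeometric distribution with population M, |A| successes and |B|
    draws (symmetric in A and B).
    """

    x: int
    y: int                # edge count of one network
    n: int                # edge count of the other network
    M: int
    p: float
    overlap_percent: float


def hypergeom_upper_tail(x: int, M: int, K: int, n: int) -> float:
    """P(X >= x) for a hypergeometric draw of n from M with K successes."""
    if x <= 0:
        return 1.0
    return float(hypergeom.sf(x - 1, M, K, n))


def overlap_test(edges_a: frozenset[Edge] | set[Edge],
                 edges_b: frozenset[Edge] | set[Edge],
                 M: int, universe: frozenset[Edge] | None = None,
                 tail: str = "upper") -> OverlapTest:
    """Overlap percentage and hypergeometric significance of two edge sets.

    ``tail='upper'`` (default) gives the enrichment probability P(X >= x);
    ``tail='point'`` gives P(X = x) for callers who want the density.
    """
    a = frozenset((min(i, j), max(i, j)) for i, j in edges_a)
    b = frozenset((min(i, j), max(i, j)) for i, j in edges_b)
    if universe is not None:
        stray = (a | b) - universe
        if stray:
            raise ValueError(f"edges outside the universe: {sorted(stray)[:5]}")
    if len(a) > M or len(b) > M:
        raise ValueError("edge set larger than the declared universe")
    x = len(a & b)
    if min(len(a), len(b)) == 0:
        percent = 0.0
    else:
        percent = 100.0 * x / min(len(a), len(b))
    if tail == "upper":
        p = hypergeom_upper_tail(x, M, len(a), len(b))
    elif tail == "point":
        p = float(hypergeom.pmf(x, M, len(a), len(b)))
    else:
        raise ValueError("tail must be 'upper' or 'point'")
    return OverlapTest(x=x, y=len(a), n=len(b), M=M, p=p,
                       overlap_percent=percent)


def compare_overlaps(k1: int, n1: int, k2: int, n2: int,
                     correction: bool = False) -> tuple[float, float]:
    """Chi-square comparison of two overlap proportions k1/n1 vs k2/n2.

    Builds the 2x2 table [[k1, n1-k1], [k2, n2-k2]]; Yates continuity
    correction is off by default.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= k <= n with n > 0 for both overlap counts")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col = table.sum(axis=0)
    if np.any(col == 0):
        which = "overlapping" if col[0] == 0 else "non-overlapping"
        raise ValueError(f"degenerate contingency table: {which} column is zero")
    if k1 / n1 == k2 / n2:
        return 0.0, 1.0
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def composition_matrix(net: PredictiveNetwork, partition: AtlasPartition,
                       subnetwork: str = "positive", alpha: float = 0.05
                       ) -> pd.DataFrame:
    """Composition of a predictive subnetwork over functional-network pairs.

    For every unordered pair (A, B) of functional networks: the count of
    predictive edges joining A and B, the percentage of that pair's
    possible edges (|A|*|B| across networks, C(|A|, 2) within), and the
    upper-tail hypergeometric enrichment p-value of the count given the
    subnetwork's total size drawn from the full edge universe.
    """
    if partition.n_nodes != net.n_nodes:
        raise ValueError("partition and network disagree on node count")
    edges = net.positive_edges if subnetwork == "positive" else net.negative_edges
    labels = partition.labels
    unlabeled = [k for k in range(net.n_nodes) if labels[k] is None or
                 (isinstance(labels[k], float) and np.isnan(labels[k]))]
    if unlabeled:
        raise ValueError(f"unlabeled node(s): {unlabeled}")

    nets = partition.networks
    sizes = {g: len(partition.nodes_of(g)) for g in nets}
    M = net.n_nodes * (net.n_nodes - 1) // 2
    total_sel = len(edges)

    counts: dict[tuple[str, str], int] = {}
    for i, j in edges:
        a, b = sorted((str(labels[i]), str(labels[j])))
        counts[(a, b)] = counts.get((a, b), 0) + 1

    rows = []
    for ai in range(len(nets)):
        for bi in range(ai, len(nets)):
            a, b = sorted((nets[ai], nets[bi]))
            if a == b:
                possible = sizes[a] * (sizes[a] - 1) // 2
            else:
                possible = sizes[a] * sizes[b]
            x = counts.get((a, b), 0)
            percent = 100.0 * x / possible if possible else 0.0
            if possible and total_sel:
                p = hypergeom_upper_tail(x, M, possible, total_sel)
            else:
                p = 1.0
            rows.append({
                "network_a": a, "network_b": b, "n_edges": x,
                "n_possible": possible, "percent": percent,
                "p_value": p, "significant": p < alpha,
            })
    return pd.DataFrame(rows)
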