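"""Temporal engagement of predictive networks and internetwork cofluctuation.

Network engagement at each sample is the mean phase synchrony over the
positive subnetwork minus the mean over the negative subnetwork, so
positive values mean the behavior-boosting subnetwork is more in sync.
Internetwork cofluctuation is the Pearson correlation over time between two
networks' engagement series; edges shared between the two networks are
removed first so a common edge cannot inflate the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import EdgeSynchronyTensor
from .cpm import PredictiveNetwork

logger = logging.getLogger("dcpm")


@dataclass
class EngagementSeries:
    """Per-sample engagement of one predictive network in one run."""

    values: np.ndarray
    network: str                       # construct label of the network
    subject: str = ""
    session: str = ""
    run: str = ""
    shared_edges_removed: bool = False

    def __len__(self) -> int:
        return len(self.values)


def engagement(tensor: EdgeSynchronyTensor, net: PredictiveNetwork,
               statistic: str = "mean",
               shared_edges_removed: bool = False) -> EngagementSeries:
    """Positive-subnetwork synchrony minus negative-subnetwork synchrony.

    Subnetwork synchrony is by default the mean across the subnetwork's
    edges, which keeps engagement comparable between subnetworks of
    different sizes and bounds it in [-2, 2]; ``statistic='sum'`` gives the
    unnormalized variant.  An empty subnetwork contributes 0 (warned);
    both empty is an error.
    """
    if net.n_nodes != tensor.n_nodes:
        raise ValueError("network and tensor disagree on node count")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    pos = sorted(net.positive_indices)
    neg = sorted(net.negative_indices)
    if not pos and not neg:
        raise ValueError("both subnetworks are empty")
    agg = np.mean if statistic == "mean" else np.sum
    if pos:
        pos_term = agg(tensor.synchrony[pos, :], axis=0)
    else:
        logger.warning("positive subnetwork empty; its term set to 0")
        pos_term = np.zeros(tensor.n_samples)
    if neg:
        neg_term = agg(tensor.synchrony[neg, :], axis=0)
    else:
        logger.warning("negative subnetwork empty; its term set to 0")
        neg_term = np.zeros(tensor.n_samples)
    return EngagementSeries(
        values=pos_term - neg_term, network=net.construct,
        subject=tensor.subject, session=tensor.session, run=tensor.run,
        shared_edges_removed=shared_edges_removed,
    )


def remove_shared_edges(net_a: PredictiveNetwork, net_b: PredictiveNetwork
                        ) -> tuple[PredictiveNetwork, PredictiveNetwork]:
    """Drop every edge present in any subnetwork of both networks from both."""
    all_a = net_a.positive_edges | net_a.negative_edges
    all_b = net_b.positive_edges | net_b.negative_edges
    shared = all_a & all_b
    a = replace(net_a, positive_edges=net_a.positive_edges - shared,
                negative_edges=net_a.negative_edges - shared)
    b = replace(net_b, positive_edges=net_b.positive_edges - shared,
                negative_edges=net_b.negative_edges - shared)
    if shared:
        logger.info("removed %d shared edge(s) from both networks", len(shared))
    return a, b


def internetwork_cofluctuation(eng_a: EngagementSeries, eng_b: EngagementSeries,
                               require_disjoint: bool = True) -> float:
    """Pearson correlation over samples between two engagement series.

    Returns NaN (reported missing) when either series is constant.  By
    default refuses series whose networks have not been through
    :func:`remove_shared_edges`.
    """
    if len(eng_a) != len(eng_b):
        raise ValueError("engagement series lengths differ")
    if require_disjoint and not (eng_a.shared_edges_removed and
                                 eng_b.shared_edges_removed):
        raise ValueError(
            "shared-edge removal not applied; pass networks through "
            "remove_shared_edges first or set require_disjoint=False"
        )
    a, b = eng_a.values, eng_b.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant engagement series: cofluctuation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def summarize_by_condition(series: list[EngagementSeries],
                           cofluctuations: list[tuple[EngagementSeries,
                                                      EngagementSeries]] | None = None
                           ) -> pd.DataFrame:
    """Per subject/session/run mean engagement (and optional cofluctuation).

    Produces the tidy table consumed by external mixed-effects modeling;
    the model fitting itself is out of scope here.
    """
    rows = [{
        "subject": s.subject, "session": s.session, "run": s.run,
        "network": s.network, "mean_engagement": float(np.mean(s.values)),
    } for s in series]
    out = pd.DataFrame(rows)
    if cofluctuations:
        cof_rows = [{
            "subject": a.subject, "session": a.session, "run": a.run,
            "network_pair": f"{a.network}-{b.network}",
            "cofluctuation": internetwork_cofluctuation(a, b),
        } for a, b in cofluctuations]
        cof = pd.DataFrame(cof_rows)
        out = out.merge(cof, on=["subject", "session", "run"], how="left")
    return out
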