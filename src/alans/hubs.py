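"""Per-network weighted graphs, centrality, and hub detection.

Within each network and each participant, the regions form an undirected
graph whose edges carry the positive correlations (negative or zero
correlations yield no edge).  Two centralities are computed per region:

* degree centrality (weighted strength): the sum of the region's positive
  correlations with the other members, DC_i = sum_j r_ij;
* betweenness centrality: for every ordered pair (h, j) of other members,
  the fraction of minimum-length weighted paths passing through i,
  accumulated over pairs.  Edge lengths derive from the correlation weight
  w by ``reciprocal`` (1/w, the standard strong-edges-are-close convention,
  default) or ``one_minus_r`` (1 - w).  Raw betweenness (the ordered-pair
  sum) is reported by default; the 1/((N-1)(N-2)) normalization is available
  but never changes the hub set, because hub calls compare regions within
  one network.

Participant-averaged centralities get normal-approximation confidence
intervals.  A region is a hub when its average degree AND betweenness both
reach the network's mean-plus-one-standard-deviation thresholds (sample SD
across the network's regions; comparisons inclusive, so a region exactly on
a threshold qualifies).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .connectivity import ConnectivityStack

__all__ = [
    "build_positive_graph",
    "degree_centrality",
    "betweenness_centrality",
    "network_centrality",
    "summarize_over_participants",
    "detect_hubs",
    "CentralitySummary",
    "HubDetector",
]

EDGE_LENGTH_RULES = ("reciprocal", "one_minus_r")


def build_positive_graph(r_matrix: np.ndarray, members=None) -> nx.Graph:
    """Undirected graph over ``members`` with one edge per positive correlation.

    ``r_matrix`` is a full symmetric correlation matrix; ``members`` selects
    node indices (default: all).  Needs at least 3 nodes (the betweenness
    normalization is undefined below that).
    """
    r = np.asarray(r_matrix, dtype=float)
    if members is None:
        members = list(range(r.shape[0]))
    members = list(members)
    if len(members) < 3:
        raise ValueError("need >= 3 regions in a network graph")
    g = nx.Graph()
    g.add_nodes_from(members)
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            w = r[members[a], members[b]]
            if w > 0:
                g.add_edge(members[a], members[b], weight=float(w))
    return g


def degree_centrality(g: nx.Graph) -> dict:
    """Weighted strength: sum of incident positive edge weights."""
    return {n: float(d) for n, d in g.degree(weight="weight")}


def _edge_length(w: float, rule: str) -> float:
    if rule == "reciprocal":
        return 1.0 / w
    if rule == "one_minus_r":
        return 1.0 - w
    raise ValueError(f"edge_length_rule must be one of {EDGE_LENGTH_RULES}")


def betweenness_centrality(
    g: nx.Graph, edge_length_rule: str = "reciprocal", normalized: bool = False
) -> dict:
    """Shortest-path betweenness with weight-derived edge lengths.

    Raw values accumulate the through-fraction over ordered pairs (h, j);
    ``normalized=True`` divides by (N-1)(N-2).  All minimum-length paths are
    counted; unreachable pairs contribute nothing; disconnected graphs are
    allowed.
    """
    lengths = {
        (u, v): _edge_length(d["weight"], edge_length_rule)
        for u, v, d in g.edges(data=True)
    }
    nx.set_edge_attributes(g, lengths, "length")
    bc = nx.betweenness_centrality(g, weight="length", normalized=normalized)
    if not normalized:
        # networkx halves undirected raw counts; restore the ordered-pair sum
        bc = {n: 2.0 * v for n, v in bc.items()}
    return {n: float(v) for n, v in bc.items()}


def network_centrality(
    stack: ConnectivityStack,
    members,
    edge_length_rule: str = "reciprocal",
    bc_normalized: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant DC and BC arrays of shape (participants, members)."""
    idx = {r: i for i, r in enumerate(stack.region_ids)}
    missing = [m for m in members if m not in idx]
    if missing:
        raise ValueError(f"regions not in stack: {missing}")
    cols = [idx[m] for m in members]
    n_p, n_m = stack.n_participants, len(members)
    dc = np.zeros((n_p, n_m))
    bc = np.zeros((n_p, n_m))
    for p in range(n_p):
        g = build_positive_graph(stack.matrices[p], cols)
        d = degree_centrality(g)
        b = betweenness_centrality(g, edge_length_rule, bc_normalized)
        dc[p] = [d[c] for c in cols]
        bc[p] = [b[c] for c in cols]
    return dc, bc


@dataclass(frozen=True)
class CentralitySummary:
    """Participant-averaged centralities, CIs, thresholds, and hub flags."""

    table: pd.DataFrame  # region, dc_mean, dc_ci_low/high, bc_mean, ..., hub
    dc_threshold: float
    bc_threshold: float
    dc_network_mean: float
    dc_network_sd: float
    bc_network_mean: float
    bc_network_sd: float

    @property
    def hubs(self) -> tuple[str, ...]:
        return tuple(self.table.loc[self.table["hub"], "region"])


def _mean_ci(values: np.ndarray, ci_level: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Region means across participants with normal-approximation CIs."""
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n < 2:
        raise ValueError("need >= 2 participants for a confidence interval")
    sem = values.std(axis=0, ddof=1) / np.sqrt(n)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return mean, mean - z * sem, mean + z * sem


def summarize_over_participants(
    dc: np.ndarray,
    bc: np.ndarray,
    members,
    ci_level: float = 0.95,
) -> CentralitySummary:
    """Average per-participant centralities and derive the hub thresholds.

    The network threshold for each metric is the across-region mean plus the
    across-region sample SD (ddof=1) of the participant-averaged values.
    """
    dc_mean, dc_lo, dc_hi = _mean_ci(np.asarray(dc, float), ci_level)
    bc_mean, bc_lo, bc_hi = _mean_ci(np.asarray(bc, float), ci_level)
    dc_mu, dc_sd = float(dc_mean.mean()), float(dc_mean.std(ddof=1))
    bc_mu, bc_sd = float(bc_mean.mean()), float(bc_mean.std(ddof=1))
    dc_thr, bc_thr = dc_mu + dc_sd, bc_mu + bc_sd
    hub = detect_hubs(dc_mean, bc_mean, dc_thr, bc_thr)
    table = pd.DataFrame(
        {
            "region": list(members),
            "dc_mean": dc_mean,
            "dc_ci_low": dc_lo,
            "dc_ci_high": dc_hi,
            "bc_mean": bc_mean,
            "bc_ci_low": bc_lo,
            "bc_ci_high": bc_hi,
            "hub": hub,
        }
    )
    return CentralitySummary(
        table=table,
        dc_threshold=dc_thr,
        bc_threshold=bc_thr,
        dc_network_mean=dc_mu,
        dc_network_sd=dc_sd,
        bc_network_mean=bc_mu,
        bc_network_sd=bc_sd,
    )


def detect_hubs(
    dc_mean: np.ndarray,
    bc_mean: np.ndarray,
    dc_threshold: float,
    bc_threshold: float,
) -> np.ndarray:
    """Inclusive dual-threshold rule: hub iff DC >= thr_DC and BC >= thr_BC.

    Inclusive comparison means a region sitting exactly on a threshold (at
    the precision of the inputs) qualifies.
    """
    return (np.asarray(dc_mean) >= dc_threshold) & (np.asarray(bc_mean) >= bc_threshold)


class HubDetector(BaseEstimator):
    """Estimator computing centralities and hub flags for every network.

    Parameters
    ----------
    edge_length_rule : {"reciprocal", "one_minus_r"}, default "reciprocal"
    bc_normalized : bool, default False
    ci_level : float, default 0.95

    Attributes (after ``fit``)
    --------------------------
    summaries_ : dict network -> CentralitySummary
    hubs_ : dict network -> tuple of hub region ids
    """

    def __init__(self, edge_length_rule: str = "reciprocal",
                 bc_normalized: bool = False, ci_level: float = 0.95):
        self.edge_length_rule = edge_length_rule
        self.bc_normalized = bc_normalized
        self.ci_level = ci_level

    def fit(self, X: ConnectivityStack, y: dict | None = None) -> "HubDetector":
        """``X`` is the connectivity stack; ``y`` maps network -> member ids."""
        if y is None:
            raise ValueError("network membership mapping is required")
        self.summaries_ = {}
        for network, members in y.items():
            dc, bc = network_centrality(
                X, members, self.edge_length_rule, self.bc_normalized
            )
            self.summaries_[network] = summarize_over_participants(
                dc, bc, members, self.ci_level
            )
        self.hubs_ = {net: s.hubs for net, s in self.summaries_.items()}
        return self

    def region_table(self) -> pd.DataFrame:
        frames = [
            s.table.assign(network=net) for net, s in self.summaries_.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def network_table(self) -> pd.DataFrame:
        rows = [
            {
                "network": net,
                "dc_mean": s.dc_network_mean,
                "dc_sd": s.dc_network_sd,
                "dc_threshold": s.dc_threshold,
                "bc_mean": s.bc_network_mean,
                "bc_sd": s.bc_network_sd,
                "bc_threshold": s.bc_threshold,
            }
            for net, s in self.summaries_.items()
        ]
        return pd.DataFrame(rows)
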