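"""Node, task and network contributions of fitted models; overlap testing.

A ridge CPM distributes its predictive signal over hundreds of edges in
several task connectomes, so interpretation works with aggregates:

* node contribution ``W_n`` — for node n, the sum over its incident
  selected edges k and tasks m of ``B(k,m) * beta_m^k * std(E_k(:,m))``:
  the learned weight rescaled back to raw edge units by the training
  standard deviation.  Each selected edge contributes to both endpoint
  nodes.  Signed by default (a magnitude option exists for display).
* task contribution ``W_m`` — the same weight-times-std sum per task, using
  |beta| so the proportions are non-negative, normalized to sum to 1.
* network profile — ``W_n`` averaged over the member nodes of each
  canonical network.

Edge-set enrichment in network cells uses the hypergeometric distribution:
drawing ``n`` edges from the ``M``-edge population, the chance of sharing
more than ``x`` edges with a ``K``-edge cell is the survival function
``P(X > x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NetworkMap
from .edges import edge_node_indices
from .rcpm import PredictiveModel


def node_contribution(model: PredictiveModel, magnitude: bool = False) -> np.ndarray:
    """``W_n`` per node: selected-edge ridge weights scaled by train stds.

    With ``magnitude=True``, |beta| replaces beta (display convention).
    """
    from .edges import nodes_from_edge_count

    n_nodes = nodes_from_edge_count(model.n_edges)
    w = np.zeros(n_nodes)
    if model.n_features == 0:
        return w
    iu, ju = edge_node_indices(n_nodes)
    beta = np.abs(model.weights) if magnitude else model.weights
    contrib = beta * model.feature_stds
    np.add.at(w, iu[model.feat_edge], contrib)
    np.add.at(w, ju[model.feat_edge], contrib)
    return w


def task_contribution(model: PredictiveModel, signed: bool = False) -> pd.Series:
    """``W_m`` per task, normalized to sum to 1.

    Uses |beta| * std by default so each task's share is a non-negative
    proportion; ``signed=True`` keeps raw signs (then normalization divides
    by the signed total and shares may fall outside [0, 1]).
    """
    if model.n_features == 0:
        raise ValueError("model has no selected edges; task contribution undefined")
    beta = model.weights if signed else np.abs(model.weights)
    per_feature = beta * model.feature_stds
    w = np.bincount(model.feat_task, weights=per_feature,
                    minlength=len(model.task_names))
    total = w.sum()
    if total == 0:
        raise ValueError("all contributions are zero; cannot normalize")
    return pd.Series(w / total, index=model.task_names, name="W_m")


def network_average(w_n: np.ndarray, netmap: NetworkMap) -> pd.Series:
    """Mean node contribution per canonical network."""
    w_n = np.asarray(w_n, dtype=float)
    if len(w_n) != netmap.n_nodes:
        raise ValueError(f"W_n length {len(w_n)} != n_nodes {netmap.n_nodes}")
    out = {}
    for net in netmap.networks:
        members = netmap.members(net)
        if len(members) == 0:
            raise ValueError(f"network {net!r} has no member nodes")
        out[net] = float(w_n[members].mean())
    return pd.Series(out, name="network_mean")


def similarity(vec_a, vec_b) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between two contribution maps."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant vector; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class OverlapQuery:
    """Hypergeometric edge-overlap question: x of n drawn vs K of M."""

    x: int   # overlapping edges
    n: int   # edges in the first set (draws)
    K: int   # edges in the second set (successes in population)
    M: int = 35778  # population edge count (268-node atlas)

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.M and 0 <= self.n <= self.M):
            raise ValueError("need 0 <= K, n <= M")
        if not 0 <= self.x <= min(self.n, self.K):
            raise ValueError(f"x={self.x} outside [0, min(n, K)={min(self.n, self.K)}]")


def hypergeometric_overlap(q: OverlapQuery) -> float:
    """Right tail ``P(X > x)`` for X ~ Hypergeometric(M, K, n).

    Evaluated through the log-gamma-based survival function, so it stays
    accurate for edge counts in the tens of thousands.
    """
    return float(stats.hypergeom.sf(q.x, q.M, q.K, q.n))


@dataclass
class NetworkOverlapProfile:
    """Per network-cell overlap counts and hypergeometric p-values."""

    table: pd.DataFrame  # columns: net_a, net_b, x, n, K, M, p, cumulative_likelihood


def edge_set_network_profile(edge_mask: np.ndarray, netmap: NetworkMap) -> NetworkOverlapProfile:
    """Enrichment of an edge set in every within/between-network cell.

    For each of the within-network cells and between-network pairs:
    ``K`` = population edges in the cell, ``n`` = size of the query edge
    set, ``x`` = their overlap, ``M`` = total edges; ``p`` is the
    hypergeometric right tail and ``cumulative_likelihood`` = 1 - p (a
    reporting convenience for stacked profiles, not an inferential
    quantity).
    """
    mask = np.asarray(edge_mask, dtype=bool)
    n_nodes = netmap.n_nodes
    iu, ju = edge_node_indices(n_nodes)
    if len(mask) != len(iu):
        raise ValueError(f"edge mask length {len(mask)} != {len(iu)} edges for "
                         f"{n_nodes} nodes")
    lab = netmap.label_indices()
    nets = netmap.networks
    a = np.minimum(lab[iu], lab[ju])
    b = np.maximum(lab[iu], lab[ju])
    m_total = len(mask)
    n_draw = int(mask.sum())
    rows = []
    for ai in range(len(nets)):
        for bi in range(ai, len(nets)):
            cell = (a == ai) & (b == bi)
            k_cell = int(cell.sum())
            x = int((cell & mask).sum())
            p = float(stats.hypergeom.sf(x, m_total, k_cell, n_draw))
            rows.append((nets[ai], nets[bi], x, n_draw, k_cell, m_total, p, 1 - p))
    return NetworkOverlapProfile(table=pd.DataFrame(
        rows, columns=["net_a", "net_b", "x", "n", "K", "M", "p", "cumulative_likelihood"]
    ))
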