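"""Reward-network graph metrics, normalized by whole-brain counterparts.

Two summary measures per edge type (NOS, FA):

* connectivity strength (CS): the average connectivity over all pairwise
  regions of the network - the mean of the upper-triangle entries,
  absent (zero) edges included;
* weighted clustering coefficient (CC): the mean over nodes of the
  geometric-mean triangle intensity
  C_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)),
  with k_i the binary degree and weights scaled to [0, 1]; NOS weights
  are divided by the matrix maximum before the CC (per network), FA
  weights already live in [0, 1].

Network and node-wise metrics for the ten-region reward network are
divided by the corresponding whole-brain value, making them specific to
the reward circuit rather than to global connectivity differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Connectome, extract_subnetwork

__all__ = [
    "NetworkMetrics",
    "connectivity_strength",
    "weighted_clustering",
    "node_metrics",
    "normalize_metrics",
    "compute_subject_metrics",
]


def _check_matrix(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(w, w.T):
        raise ValueError("matrix must be symmetric")
    if np.diag(w).any():
        raise ValueError("matrix must have zero diagonal")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return w


def connectivity_strength(matrix: np.ndarray) -> float:
    """Mean edge weight over all N(N-1)/2 unordered pairs, zeros included."""
    w = _check_matrix(matrix)
    n = w.shape[0]
    if n < 2:
        raise ValueError("connectivity strength needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(w[iu].mean())


def weighted_clustering(matrix: np.ndarray, scale_by_max: bool = False):
    """Per-node weighted clustering coefficients and their mean.

    ``scale_by_max=True`` first divides the weights by the matrix maximum
    (the [0, 1] normalization applied to NOS weights; FA weights need no
    scaling).  Nodes with binary degree < 2 get C_i = 0.
    """
    w = _check_matrix(matrix)
    n = w.shape[0]
    if scale_by_max:
        m = w.max()
        if m > 0:
            w = w / m
    cbrt = np.cbrt(w)
    k = (w > 0).sum(axis=1)
    # diagonal of cbrt(W)^3 counts closed triangles around each node (x2)
    tri = np.diagonal(cbrt @ cbrt @ cbrt)
    ci = np.zeros(n)
    ok = k >= 2
    ci[ok] = tri[ok] / (k[ok] * (k[ok] - 1))
    return ci, float(ci.mean()) if n else 0.0


def node_metrics(matrix: np.ndarray, scale_by_max: bool = False) -> pd.DataFrame:
    """Per-node CS (mean of the node's N-1 within-network edge weights)
    and per-node weighted CC."""
    w = _check_matrix(matrix)
    n = w.shape[0]
    if n < 2:
        raise ValueError("node metrics need at least 2 nodes")
    cs = w.sum(axis=1) / (n - 1)
    cc, _ = weighted_clustering(w, scale_by_max=scale_by_max)
    return pd.DataFrame({"node_cs": cs, "node_cc": cc})


@dataclass
class NetworkMetrics:
    """Raw and whole-brain-normalized reward-network metrics for a subject."""

    raw_reward: dict = field(default_factory=dict)       # metric -> value
    raw_whole_brain: dict = field(default_factory=dict)
    normalized: dict = field(default_factory=dict)       # metric -> value or NaN
    undefined: list = field(default_factory=list)        # metrics with 0 denominator
    node_normalized: pd.DataFrame | None = None          # per reward node


def normalize_metrics(reward: dict, whole_brain: dict,
                      node_values: pd.DataFrame | None = None) -> NetworkMetrics:
    """Elementwise reward / whole-brain ratio; a zero whole-brain value is
    flagged undefined (NaN), never silently zero.  Node-wise values are
    divided by the same whole-brain network metric."""
    normalized = {}
    undefined = []
    for key, rew in reward.items():
        wb = whole_brain[key]
        if wb == 0:
            normalized[key] = float("nan")
            undefined.append(key)
        else:
            normalized[key] = rew / wb
    node_norm = None
    if node_values is not None:
        node_norm = node_values.copy()
        for col, metric in [("node_cs", "cs"), ("node_cc", "cc")]:
            wb = whole_brain[metric]
            node_norm[col] = node_values[col] / wb if wb != 0 else float("nan")
    return NetworkMetrics(raw_reward=dict(reward), raw_whole_brain=dict(whole_brain),
                          normalized=normalized, undefined=undefined,
                          node_normalized=node_norm)


def _network_summary(nos: np.ndarray, fa: np.ndarray) -> dict:
    return {
        "nos_cs": connectivity_strength(nos),
        "nos_cc": weighted_clustering(nos, scale_by_max=True)[1],
        "fa_cs": connectivity_strength(fa),
        "fa_cc": weighted_clustering(fa, scale_by_max=False)[1],
    }


def compute_subject_metrics(conn: Connectome,
                            reward_ids=None) -> pd.Series:
    """One row of normalized network + node-wise metrics for a subject.

    The reward network defaults to the node table's flagged reward nodes.
    Each network (reward and whole-brain) is max-normalized by its own
    maximum NOS weight before the weighted CC, and reward metrics are
    divided by whole-brain ones.
    """
    ids = conn.nodes.reward_ids if reward_ids is None else reward_ids
    reward = extract_subnetwork(conn, ids)

    wb = _network_summary(conn.nos, conn.fa)
    rew = _network_summary(reward.nos, reward.fa)

    row: dict[str, float] = {}
    for key in ("fa_cs", "fa_cc", "nos_cs", "nos_cc"):
        row[key] = rew[key] / wb[key] if wb[key] != 0 else float("nan")

    for kind, mat, scale in [("fa", reward.fa, False), ("nos", reward.nos, True)]:
        nm = node_metrics(mat, scale_by_max=scale)
        for i, r in reward.nodes.table.iterrows():
            tag = f"{r['name']}_{r['hemisphere']}"
            wb_cs, wb_cc = wb[f"{kind}_cs"], wb[f"{kind}_cc"]
            row[f"{kind}_cs_{tag}"] = (nm["node_cs"][i] / wb_cs
                                       if wb_cs != 0 else float("nan"))
            row[f"{kind}_cc_{tag}"] = (nm["node_cc"][i] / wb_cc
                                       if wb_cc != 0 else float("nan"))
    return pd.Series(row)
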