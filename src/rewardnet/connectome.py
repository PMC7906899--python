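"""Connectome construction: streamlines + parcellation -> weighted matrices.

Edges are undirected and unsigned.  Two edge weights are assessed per
region pair: the total number of connecting streamlines touching both
regions (NOS), and the mean FA across the distinct voxels included in
those streamlines (FA).  A streamline "touches" a region when any voxel
it visits carries that region's label (pass-through semantics by default;
endpoint-only counting is available as a sensitivity alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import StreamlineSet

__all__ = [
    "NodeTable",
    "Connectome",
    "build_connectome",
    "extract_subnetwork",
    "load_node_table",
    "phantom_node_table",
]

NODE_COLUMNS = ["node_id", "name", "hemisphere", "is_reward_node"]


@dataclass
class NodeTable:
    """Mapping from parcellation label values to named connectome nodes."""

    table: pd.DataFrame  # columns: node_id, name, hemisphere, is_reward_node

    def __post_init__(self) -> None:
        missing = set(NODE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"node table lacks columns {sorted(missing)}")
        if self.table["node_id"].duplicated().any():
            raise ValueError("node ids must be unique")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    @property
    def names(self) -> list:
        return self.table["name"].tolist()

    @property
    def reward_ids(self) -> np.ndarray:
        return self.table.loc[self.table["is_reward_node"].astype(bool),
                              "node_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def load_node_table() -> NodeTable:
    """The standard 82-node atlas table (68 cortical Desikan-Killiany
    regions + 14 subcortical structures); the ten bilateral reward nodes
    (lateral/medial orbitofrontal cortex, caudate, putamen, accumbens) are
    flagged."""
    with resources.files("rewardnet.resources").joinpath("dk82_nodes.csv").open() as fh:
        df = pd.read_csv(fh)
    return NodeTable(df)


def phantom_node_table(labels) -> NodeTable:
    """Ad-hoc node table for phantom end-region labels."""
    labels = [int(x) for x in labels]
    df = pd.DataFrame({
        "node_id": labels,
        "name": [f"region_{x}" for x in labels],
        "hemisphere": ["left"] * len(labels),
        "is_reward_node": [1] * len(labels),
    })
    return NodeTable(df)


@dataclass
class Connectome:
    """Symmetric NOS and FA matrices over a node table.

    Invariants: zero diagonal, exact symmetry, and an FA edge exists
    exactly where a NOS edge does.
    """

    nos: np.ndarray
    fa: np.ndarray
    nodes: NodeTable

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.nos = np.asarray(self.nos, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.nos.shape != (n, n) or self.fa.shape != (n, n):
            raise ValueError("matrix shape does not match the node table")
        if not np.allclose(self.nos, self.nos.T) or not np.allclose(self.fa, self.fa.T):
            raise ValueError("connectome matrices must be symmetric")
        if np.diag(self.nos).any() or np.diag(self.fa).any():
            raise ValueError("connectome matrices must have zero diagonal")


def build_connectome(streams: StreamlineSet, parcellation: np.ndarray,
                     fa_map: np.ndarray, nodes: NodeTable,
                     touch: str = "pass_through") -> Connectome:
    """Count streamlines per region pair and average FA over their voxels.

    For every unordered pair of distinct regions a streamline touches, the
    pair's NOS is incremented and the streamline's visited voxels join the
    pair's voxel set; the FA edge weight is the mean of ``fa_map`` over
    the union of distinct voxels (shared voxels counted once).  With
    ``touch="endpoints"`` only the first and last visited voxels can touch.
    """
    if touch not in ("pass_through", "endpoints"):
        raise ValueError("touch must be 'pass_through' or 'endpoints'")
    parc = np.asarray(parcellation)
    if parc.shape != fa_map.shape:
        raise ValueError("parcellation and fa_map grids differ")

    known = set(int(i) for i in nodes.ids)
    present = set(int(v) for v in np.unique(parc) if v != 0)
    unknown = present - known
    if unknown:
        warnings.warn(f"parcellation labels absent from node table ignored: "
                      f"{sorted(unknown)}", stacklevel=2)

    index = {int(nid): i for i, nid in enumerate(nodes.ids)}
    n = len(nodes)
    nos = np.zeros((n, n))
    voxel_sets: dict[tuple[int, int], set] = {}

    for s in streams.streamlines:
        vox = s.visited if touch == "pass_through" else [s.visited[0], s.visited[-1]]
        touched = sorted({index[int(parc[v])] for v in vox
                          if parc[v] != 0 and int(parc[v]) in index})
        if len(touched) < 2:
            continue
        svox = set(s.visited)
        for a_i, a in enumerate(touched):
            for b in touched[a_i + 1:]:
                nos[a, b] += 1
                nos[b, a] += 1
                voxel_sets.setdefault((a, b), set()).update(svox)

    fa = np.zeros((n, n))
    for (a, b), vset in voxel_sets.items():
        vals = np.array([fa_map[v] for v in vset], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean_fa = float(vals.mean()) if len(vals) else 0.0
        fa[a, b] = fa[b, a] = mean_fa
    return Connectome(nos=nos, fa=fa, nodes=nodes)


def extract_subnetwork(c: Connectome, node_ids) -> Connectome:
    """Row/column restriction of a connectome to a subset of node ids,
    preserving the node-table order of the subset."""
    wanted = [int(x) for x in node_ids]
    known = {int(nid): i for i, nid in enumerate(c.nodes.ids)}
    unknown = [x for x in wanted if x not in known]
    if unknown:
        raise KeyError(f"unknown node ids: {unknown}")
    keep = [i for i, nid in enumerate(c.nodes.ids) if int(nid) in set(wanted)]
    idx = np.asarray(keep, dtype=int)
    sub = NodeTable(c.nodes.table.iloc[idx].reset_index(drop=True))
    return Connectome(nos=c.nos[np.ix_(idx, idx)], fa=c.fa[np.ix_(idx, idx)],
                      nodes=sub)


# ---------------------------------------------------------------------------
# Serialization: CSV per edge type (node-name headers) + JSON bundle
# ---------------------------------------------------------------------------

def save_connectome(c: Connectome, out_dir: str | Path, stem: str = "connectome"):
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = c.nodes.names
    for kind, mat in [("nos", c.nos), ("fa", c.fa)]:
        pd.DataFrame(mat, index=names, columns=names).to_csv(
            out / f"{stem}_{kind}.csv")
    bundle = {
        "nodes": c.nodes.table.to_dict(orient="list"),
        "nos": c.nos.tolist(),
        "fa": c.fa.tolist(),
    }
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(bundle, fh)
    return out


def load_connectome_json(path: str | Path) -> Connectome:
    import json

    data = json.loads(Path(path).read_text())
    nodes = NodeTable(pd.DataFrame(data["nodes"]))
    return Connectome(nos=np.asarray(data["nos"]), fa=np.asarray(data["fa"]),
                      nodes=nodes)
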