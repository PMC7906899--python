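"""Connectome assembly: touch counting, FA union semantics, subnetworks."""

import numpy as np
import pandas as pd
import pytest

import rewardnet as rn
from rewardnet.tracking import Streamline, StreamlineSet


def _streamline(visited):
    visited = [tuple(v) for v in visited]
    pts = np.asarray(visited, dtype=float) + 0.5
    return Streamline(points=pts, seed=visited[0], visited=visited,
                      termination=("left_mask", "left_mask"))


def _stream_set(*visited_lists):
    return StreamlineSet([_streamline(v) for v in visited_lists],
                         n_seeds=len(visited_lists))


def _grid(shape, labels):
    parc = np.zeros(shape, dtype=int)
    for vox, lab in labels.items():
        parc[vox] = lab
    return parc


class TestBuildConnectome:
    def test_phantom_nos_equals_streamline_count(self, straight_phantom,
                                                 straight_field,
                                                 straight_streams):
        _, acq, parc, truth = straight_phantom
        nodes = rn.phantom_node_table(truth.end_region_labels)
        conn = rn.build_connectome(straight_streams, parc, straight_field.fa,
                                   nodes)
        assert conn.nos[0, 1] == truth.expected_nos
        assert conn.fa[0, 1] == pytest.approx(truth.expected_bundle_fa,
                                              abs=1e-8)

    def test_single_label_streamline_contributes_no_edge(self):
        shape = (5, 1, 1)
        parc = _grid(shape, {(0, 0, 0): 1})
        fa = np.full(shape, 0.5)
        streams = _stream_set([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        conn = rn.build_connectome(streams, parc, fa,
                                   rn.phantom_node_table([1, 2]))
        assert conn.nos.sum() == 0
        assert conn.fa.sum() == 0

    def test_fa_union_semantics_shared_voxels_counted_once(self):
        """Two connecting streamlines share voxels; the FA edge is the mean
        over the union of distinct voxels, computed here by hand."""
        shape = (5, 1, 2)
        parc = _grid(shape, {(0, 0, 0): 1, (4, 0, 0): 2})
        fa = np.zeros(shape)
        fa_values = {(0, 0, 0): 0.2, (1, 0, 0): 0.4, (2, 0, 0): 0.6,
                     (3, 0, 0): 0.8, (4, 0, 0): 1.0, (2, 0, 1): 0.5}
        for vox, v in fa_values.items():
            fa[vox] = v
        s1 = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0)]
        s2 = [(0, 0, 0), (1, 0, 0), (2, 0, 1), (3, 0, 0), (4, 0, 0)]
        conn = rn.build_connectome(_stream_set(s1, s2), parc, fa,
                                   rn.phantom_node_table([1, 2]))
        assert conn.nos[0, 1] == 2
        # union = 6 distinct voxels: (0.2+0.4+0.6+0.8+1.0+0.5)/6 = 0.5833...
        assert conn.fa[0, 1] == pytest.approx(3.5 / 6, abs=1e-12)

    def test_multi_region_streamline_increments_every_pair(self):
        shape = (7, 1, 1)
        parc = _grid(shape, {(0, 0, 0): 1, (3, 0, 0): 2, (6, 0, 0): 3})
        fa = np.full(shape, 0.5)
        streams = _stream_set([(i, 0, 0) for i in range(7)])
        conn = rn.build_connectome(streams, parc, fa,
                                   rn.phantom_node_table([1, 2, 3]))
        iu = np.triu_indices(3, k=1)
        assert (conn.nos[iu] == 1).all()  # all three pairs touched

    def test_unknown_label_warns_and_is_ignored(self):
        shape = (5, 1, 1)
        parc = _grid(shape, {(0, 0, 0): 1, (2, 0, 0): 99, (4, 0, 0): 2})
        fa = np.full(shape, 0.5)
        streams = _stream_set([(i, 0, 0) for i in range(5)])
        with pytest.warns(UserWarning, match="99"):
            conn = rn.build_connectome(streams, parc, fa,
                                       rn.phantom_node_table([1, 2]))
        assert conn.nos[0, 1] == 1

    def test_empty_streamline_set_gives_zero_matrices(self):
        shape = (3, 1, 1)
        parc = _grid(shape, {(0, 0, 0): 1, (2, 0, 0): 2})
        conn = rn.build_connectome(StreamlineSet([], n_seeds=0), parc,
                                   np.zeros(shape),
                                   rn.phantom_node_table([1, 2]))
        assert conn.nos.sum() == 0 and conn.fa.sum() == 0

    def test_nos_and_fa_edges_coincide(self, straight_phantom, straight_field,
                                       straight_streams):
        _, _, parc, truth = straight_phantom
        conn = rn.build_connectome(straight_streams, parc, straight_field.fa,
                                   rn.phantom_node_table(truth.end_region_labels))
        assert np.array_equal(conn.nos > 0, conn.fa > 0)

    def test_endpoint_touch_mode(self):
        """Pass-through counts a mid-track label; endpoint-only does not."""
        shape = (5, 1, 1)
        parc = _grid(shape, {(0, 0, 0): 1, (2, 0, 0): 3, (4, 0, 0): 2})
        fa = np.full(shape, 0.5)
        streams = _stream_set([(i, 0, 0) for i in range(5)])
        nodes = rn.phantom_node_table([1, 2, 3])
        pass_through = rn.build_connectome(streams, parc, fa, nodes)
        endpoints = rn.build_connectome(streams, parc, fa, nodes,
                                        touch="endpoints")
        assert pass_through.nos[0, 2] == 1  # 1 <-> 3 via pass-through
        assert endpoints.nos[0, 2] == 0
        assert endpoints.nos[0, 1] == 1


def _random_connectome(rng, n=82):
    w = rng.random((n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    fa = np.where(w > 0, rng.random((n, n)), 0.0)
    fa = np.triu(fa, k=1)
    fa = fa + fa.T
    ids = list(range(1, n + 1))
    nodes = rn.NodeTable(pd.DataFrame({
        "node_id": ids, "name": [f"r{i}" for i in ids],
        "hemisphere": ["left"] * n, "is_reward_node": [0] * n}))
    return rn.Connectome(nos=w, fa=fa, nodes=nodes)


class TestSubnetwork:
    def test_full_subset_is_identity(self, straight_phantom, straight_field,
                                     straight_streams):
        _, _, parc, truth = straight_phantom
        conn = rn.build_connectome(straight_streams, parc, straight_field.fa,
                                   rn.phantom_node_table(truth.end_region_labels))
        sub = rn.extract_subnetwork(conn, truth.end_region_labels)
        assert np.array_equal(sub.nos, conn.nos)
        assert np.array_equal(sub.fa, conn.fa)

    def test_restriction_equals_direct_indexing(self):
        rng = np.random.default_rng(0)
        conn = _random_connectome(rng)
        subset = [3, 17, 25, 40, 41, 60, 61, 70, 80, 82]
        sub = rn.extract_subnetwork(conn, subset)
        idx = np.array(subset) - 1  # ids are 1-based positions here
        assert np.array_equal(sub.nos, conn.nos[np.ix_(idx, idx)])
        assert np.array_equal(sub.fa, conn.fa[np.ix_(idx, idx)])

    def test_unknown_node_raises(self):
        rng = np.random.default_rng(1)
        conn = _random_connectome(rng, n=5)
        with pytest.raises(KeyError):
            rn.extract_subnetwork(conn, [1, 999])

    def test_permutation_equivariance(self):
        """Relabeling nodes permutes rows/columns consistently."""
        rng = np.random.default_rng(2)
        conn = _random_connectome(rng, n=10)
        perm = rng.permutation(10)
        permuted = rn.Connectome(
            nos=conn.nos[np.ix_(perm, perm)], fa=conn.fa[np.ix_(perm, perm)],
            nodes=rn.NodeTable(conn.nodes.table.iloc[perm].reset_index(drop=True)))
        subset = [2, 5, 7, 9]
        a = rn.extract_subnetwork(conn, subset)
        b = rn.extract_subnetwork(permuted, subset)
        order_a = list(a.nodes.ids)
        order_b = list(b.nodes.ids)
        reorder = [order_b.index(i) for i in order_a]
        assert np.array_equal(a.nos, b.nos[np.ix_(reorder, reorder)])


def test_standard_node_table():
    nodes = rn.load_node_table()
    assert len(nodes) == 82
    assert len(nodes.reward_ids) == 10
    reward_names = set(nodes.table.loc[nodes.table.is_reward_node == 1, "name"])
    for stem in ("lateralorbitofrontal", "medialorbitofrontal", "caudate",
                 "putamen", "accumbens"):
        assert sum(stem in n for n in reward_names) == 2  # bilateral


def test_connectome_invariants_enforced():
    nodes = rn.phantom_node_table([1, 2])
    with pytest.raises(ValueError, match="symmetric"):
        rn.Connectome(nos=np.array([[0, 1], [2, 0]]),
                      fa=np.zeros((2, 2)), nodes=nodes)
    with pytest.raises(ValueError, match="diagonal"):
        rn.Connectome(nos=np.eye(2), fa=np.zeros((2, 2)), nodes=nodes)


def test_connectome_json_roundtrip(tmp_path, straight_phantom, straight_field,
                                   straight_streams):
    _, _, parc, truth = straight_phantom
    from rewardnet.connectome import save_connectome, load_connectome_json
    conn = rn.build_connectome(straight_streams, parc, straight_field.fa,
                               rn.phantom_node_table(truth.end_region_labels))
    save_connectome(conn, tmp_path)
    loaded = load_connectome_json(tmp_path / "connectome.json")
    assert np.allclose(loaded.nos, conn.nos)
    assert np.allclose(loaded.fa, conn.fa)
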