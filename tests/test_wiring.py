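"""Adjacency construction, shared-partner similarity, embedding, type graph."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vlconn as vl
from conftest import make_diagram


def brute_force_similarities(A: np.ndarray):
    """O(N^3) shared-partner counting, the independent oracle."""
    n = A.shape[0]
    co = np.zeros((n, n), dtype=np.int64)
    ci = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                co[i, j] += A[i, k] * A[j, k]
                ci[i, j] += A[k, i] * A[k, j]
    return co, ci


class TestBuildWiringDiagram:
    def test_sums_multiple_rows(self, tiny_table):
        w = vl.build_wiring_diagram(tiny_table)
        assert w.A[w.index_of(1), w.index_of(2)] == 4
        assert w.A[w.index_of(2), w.index_of(3)] == 5

    def test_empty_synapse_table_is_zero_matrix(self):
        neurons = pd.DataFrame({"neuron_id": [0, 1], "cell_type": ["SFL", "SAM"]})
        synapses = pd.DataFrame(columns=["pre_id", "post_id", "n_sites", "x_um", "y_um", "z_um"])
        w = vl.build_wiring_diagram(vl.ConnectomeTable(neurons=neurons, synapses=synapses))
        assert w.A.sum() == 0

    def test_dangling_reference_raises(self):
        neurons = pd.DataFrame({"neuron_id": [0], "cell_type": ["SAM"]})
        synapses = pd.DataFrame(
            {"pre_id": [0], "post_id": [99], "n_sites": [1], "x_um": 0.0, "y_um": 0.0, "z_um": 0.0}
        )
        with pytest.raises(vl.ConnectomeError, match="undeclared"):
            vl.build_wiring_diagram(vl.ConnectomeTable(neurons=neurons, synapses=synapses))

    def test_sfl_columns_of_sams_sum_to_one(self, default_connectome, default_diagram):
        # generator guarantee: one SFL input per SAM; oracle = direct count
        w = default_diagram
        sam_cols = np.flatnonzero(w.cell_types == "SAM")
        sfl_rows = np.flatnonzero(w.cell_types == "SFL")
        assert (w.A[np.ix_(sfl_rows, sam_cols)].sum(axis=0) == 1).all()
        types = default_connectome.types()
        syn = default_connectome.synapses
        direct = syn[syn["pre_id"].map(types).eq("SFL") & syn["post_id"].map(types).eq("SAM")]
        assert direct.groupby("post_id").size().eq(1).all()


class TestSimilarities:
    def test_single_shared_target(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 2] = 1
        A[1, 2] = 1
        s = vl.compute_similarities(make_diagram(A))
        assert s.common_output[0, 1] == 1
        assert s.common_input[0, 1] == 0

    def test_zero_matrix(self):
        s = vl.compute_similarities(make_diagram(np.zeros((4, 4), dtype=int)))
        assert s.combined.sum() == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        A = rng.integers(0, 4, size=(n, n))
        np.fill_diagonal(A, 0)
        s = vl.compute_similarities(make_diagram(A))
        co, ci = brute_force_similarities(A)
        np.testing.assert_array_equal(s.common_output, co)
        np.testing.assert_array_equal(s.common_input, ci)
        np.testing.assert_array_equal(s.combined, co + ci)

    def test_symmetry_and_diagonal(self, default_diagram):
        s = vl.compute_similarities(default_diagram)
        assert (s.common_output == s.common_output.T).all()
        assert (s.common_input == s.common_input.T).all()
        A = default_diagram.A
        np.testing.assert_array_equal(np.diag(s.common_output), (A**2).sum(axis=1))


class TestEmbedding:
    def test_identical_rows_embed_identically(self):
        A = np.array([[0, 0, 3], [0, 0, 3], [0, 0, 0]])
        s = vl.compute_similarities(make_diagram(A))
        emb = vl.embed_neurons(s, k=2)
        np.testing.assert_allclose(
            emb.loc[0, ["dim1", "dim2"]].to_numpy(dtype=float),
            emb.loc[1, ["dim1", "dim2"]].to_numpy(dtype=float),
            atol=1e-10,
        )

    def test_gram_matrix_reconstruction(self):
        # rank-2 combined matrix: a k=2 embedding must reproduce it exactly
        rng = np.random.default_rng(0)
        B = rng.integers(0, 3, size=(5, 2)).astype(float)
        C = B @ B.T
        s = vl.SimilaritySet(
            common_output=C, common_input=np.zeros_like(C), combined=C,
            neuron_ids=np.arange(5),
        )
        emb = vl.embed_neurons(s, k=2)
        coords = emb[["dim1", "dim2"]].to_numpy(dtype=float)
        np.testing.assert_allclose(coords @ coords.T, C, atol=1e-8)

    def test_block_diagonal_separation(self):
        block = np.full((3, 3), 5.0)
        C = np.zeros((6, 6))
        C[:3, :3] = block
        C[3:, 3:] = block * 2
        s = vl.SimilaritySet(
            common_output=C, common_input=np.zeros_like(C), combined=C,
            neuron_ids=np.arange(6),
        )
        coords = vl.embed_neurons(s, k=2)[["dim1", "dim2"]].to_numpy(dtype=float)
        within = max(
            np.linalg.norm(coords[i] - coords[j])
            for blk in (range(3), range(3, 6))
            for i in blk
            for j in blk
        )
        between = min(np.linalg.norm(coords[i] - coords[j]) for i in range(3) for j in range(3, 6))
        assert between > within

    def test_relabeling_invariance_of_distances(self, default_diagram):
        s = vl.compute_similarities(default_diagram)
        emb = vl.embed_neurons(s, k=10)
        coords = emb.filter(like="dim").to_numpy(dtype=float)
        perm = np.random.default_rng(3).permutation(default_diagram.n)
        s2 = vl.SimilaritySet(
            common_output=s.common_output[np.ix_(perm, perm)],
            common_input=s.common_input[np.ix_(perm, perm)],
            combined=s.combined[np.ix_(perm, perm)],
            neuron_ids=default_diagram.neuron_ids[perm],
        )
        coords2 = vl.embed_neurons(s2, k=10).filter(like="dim").to_numpy(dtype=float)
        d1 = np.linalg.norm(coords[perm[0]] - coords[perm[1]])
        d2 = np.linalg.norm(coords2[0] - coords2[1])
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_k_clipped_with_warning(self):
        C = np.eye(3)
        s = vl.SimilaritySet(
            common_output=C, common_input=np.zeros_like(C), combined=C,
            neuron_ids=np.arange(3),
        )
        with pytest.warns(UserWarning, match="clipping"):
            emb = vl.embed_neurons(s, k=5)
        assert emb.shape[1] == 1 + 2  # neuron_id + 2 dims


class TestTypeGraph:
    def test_edge_set_matches_direct_count(self, default_connectome, default_diagram):
        tg = vl.build_type_graph(default_diagram, min_synapses=10)
        types = default_connectome.types()
        syn = default_connectome.synapses
        agg = (
            syn.assign(pre=syn["pre_id"].map(types), post=syn["post_id"].map(types))
            .groupby(["pre", "post"])["n_sites"]
            .sum()
        )
        expected = set(agg[agg > 10].index)
        assert tg.edge_set() == expected

    def test_infinite_threshold_empty(self, default_diagram):
        tg = vl.build_type_graph(default_diagram, min_synapses=np.inf)
        assert tg.edge_set() == set()

    def test_threshold_is_strict(self):
        A = np.zeros((2, 2), dtype=int)
        A[0, 1] = 10
        tg = vl.build_type_graph(make_diagram(A, types=["SFL", "SAM"]), min_synapses=10)
        assert ("SFL", "SAM") not in tg.edge_set()
        tg9 = vl.build_type_graph(make_diagram(A, types=["SFL", "SAM"]), min_synapses=9)
        assert tg9.weight("SFL", "SAM") == 10

    def test_weights_conserve_total_synapses(self, default_diagram):
        tg = vl.build_type_graph(default_diagram, min_synapses=0)
        total = sum(d["weight"] for _, _, d in tg.graph.edges(data=True))
        assert total == default_diagram.A.sum()


class TestLayouts:
    def test_layout_reproducible(self):
        A = np.zeros((2, 2), dtype=int)
        A[0, 1] = 5
        tg = vl.build_type_graph(make_diagram(A, types=["SFL", "SAM"]), min_synapses=0)
        p1 = vl.layout_type_graph(tg, seed=4)
        p2 = vl.layout_type_graph(tg, seed=4)
        d = np.linalg.norm(p1["SFL"] - p1["SAM"])
        assert np.isfinite(d)
        np.testing.assert_allclose(p1["SFL"], p2["SFL"])

    def test_heavy_edge_pulls_nodes_closer(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 100  # heavy
        A[1, 2] = 1
        A[2, 0] = 1
        tg = vl.build_type_graph(make_diagram(A, types=["SFL", "SAM", "LN"]), min_synapses=0)
        closer = 0
        for seed in range(100):
            pos = vl.layout_type_graph(tg, seed=seed)
            d_heavy = np.linalg.norm(pos["SFL"] - pos["SAM"])
            d_light = np.linalg.norm(pos["SAM"] - pos["LN"])
            closer += d_heavy < d_light
        assert closer >= 95

    def test_scale_zero_collapses_onto_anchor(self, default_connectome, default_diagram):
        s = vl.compute_similarities(default_diagram)
        emb = vl.embed_neurons(s, k=2)
        tg = vl.build_type_graph(default_diagram, min_synapses=10)
        pos = vl.layout_type_graph(tg, seed=0)
        combined = vl.combine_layouts(pos, emb, default_connectome.types(), scale=0.0)
        for t, anchor in pos.items():
            sub = combined[combined["cell_type"] == t]
            if len(sub):
                xy = sub[["x", "y"]].to_numpy(dtype=float)
                np.testing.assert_allclose(xy, np.broadcast_to(anchor, xy.shape), atol=1e-12)
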