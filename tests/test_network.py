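"""Connectivity matrices and graph indicators against brute-force oracles."""

from itertools import combinations

import numpy as np
import networkx as nx
import pytest

from mipipe.errors import ConfigurationError
from mipipe.montage import CHANNELS_1020, standard_montage
from mipipe.network import (
    BinaryGraph,
    ConnectivityMatrix,
    binarize,
    ex_degree,
    network_metrics,
    node_degree,
    node_degrees,
    pearson_connectivity,
    region_degree,
    transitivity,
)
from mipipe.preprocessing import TrialBlockERP


def _block_from_array(data, fs=200.0):
    times = np.arange(-int(fs), int(fs) + 1) / fs
    return TrialBlockERP(data=data, block_index=1, session=1, day=1,
                         task_label="left", n_trials=20, sampling_rate=fs,
                         times=times, channels=CHANNELS_1020,
                         start_trial=0)


def _random_conn(rng, n=19):
    a = rng.uniform(-1, 1, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 1.0)
    labels = tuple(f"n{i}" for i in range(n)) if n != 19 else CHANNELS_1020
    return ConnectivityMatrix(values=m, channels=labels, window_role="task")


class TestPearson:
    def test_identical_series_correlate_to_one(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(401)
        data = np.tile(base, (19, 1))
        conn = pearson_connectivity(_block_from_array(data))
        assert np.allclose(conn.values, 1.0)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(401)
        data = np.tile(base, (19, 1))
        data[1] = -base
        conn = pearson_connectivity(_block_from_array(data))
        assert conn.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_example(self):
        """rho([1,2,3],[1,2,4]) = 9/sqrt(84), checked to 1e-12."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        # brute force from the definition
        rho_brute = (np.sum((x - x.mean()) * (y - y.mean()))
                     / np.sqrt(np.sum((x - x.mean()) ** 2)
                               * np.sum((y - y.mean()) ** 2)))
        assert rho_brute == pytest.approx(9 / np.sqrt(84), abs=1e-12)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(9 / np.sqrt(84),
                                                        abs=1e-12)

    def test_zero_variance_channel_gets_zero_edges(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((19, 401))
        data[5] = 3.14  # constant channel
        conn = pearson_connectivity(_block_from_array(data))
        assert np.all(conn.values[5, np.arange(19) != 5] == 0.0)
        assert conn.values[5, 5] == 1.0
        assert np.isfinite(conn.values).all()

    def test_matrix_invariants_enforced(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(ConfigurationError):
            ConnectivityMatrix(values=bad, channels=("a", "b", "c"),
                               window_role="task")


class TestDegrees:
    def test_two_term_sum(self):
        m = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, 0.0], [0.5, 0.0, 1.0]])
        conn = ConnectivityMatrix(values=m, channels=("a", "b", "c"),
                                  window_role="task")
        assert node_degree(conn, "a") == pytest.approx(0.7, abs=1e-12)

    def test_degrees_match_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            conn = _random_conn(rng)
            degs = node_degrees(conn)
            for i, ch in enumerate(conn.channels):
                brute = sum(conn.values[i, j] for j in range(19) if j != i)
                assert node_degree(conn, ch) == pytest.approx(brute, abs=1e-9)
                assert degs[i] == pytest.approx(brute, abs=1e-9)

    def test_region_degree_three_pair_sum(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.1
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.3
        conn = ConnectivityMatrix(values=m, channels=("a", "b", "c"),
                                  window_role="task")
        assert region_degree(conn, ("a", "b", "c")) == pytest.approx(0.6)
        with pytest.raises(ConfigurationError):
            region_degree(conn, ("a",))

    def test_single_cross_edge_appears_only_in_ex(self):
        montage = standard_montage()
        m = np.eye(19)
        i, j = montage.index("C3"), montage.index("C4")
        m[i, j] = m[j, i] = 0.8
        conn = ConnectivityMatrix(values=m, channels=CHANNELS_1020,
                                  window_role="task")
        left = [c for c in CHANNELS_1020 if c in montage.left_set]
        right = [c for c in CHANNELS_1020 if c in montage.right_set]
        assert ex_degree(conn, montage) == pytest.approx(0.8)
        assert region_degree(conn, left) == 0.0
        assert region_degree(conn, right) == 0.0

    def test_partition_identity(self):
        """LnL + LnR + EX + medial-incident pairs == total edge weight."""
        rng = np.random.default_rng(4)
        montage = standard_montage()
        left = [c for c in CHANNELS_1020 if c in montage.left_set]
        right = [c for c in CHANNELS_1020 if c in montage.right_set]
        for _ in range(10):
            conn = _random_conn(rng)
            total = sum(conn.values[i, j]
                        for i, j in combinations(range(19), 2))
            medial_pairs = sum(
                conn.values[i, j] for i, j in combinations(range(19), 2)
                if CHANNELS_1020[i] in montage.medial_set
                or CHANNELS_1020[j] in montage.medial_set)
            lhs = (region_degree(conn, left) + region_degree(conn, right)
                   + ex_degree(conn, montage) + medial_pairs)
            assert lhs == pytest.approx(total, abs=1e-9)


class TestBinaryGraph:
    def test_threshold_boundary_is_inclusive(self):
        m = np.eye(4)
        vals = {(0, 1): 0.59, (0, 2): 0.60, (0, 3): 0.61}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        conn = ConnectivityMatrix(values=m, channels=("a", "b", "c", "d"),
                                  window_role="task")
        g = binarize(conn, 0.6)
        assert g.adjacency[0, 1] == 0
        assert g.adjacency[0, 2] == 1
        assert g.adjacency[0, 3] == 1

    def test_negative_correlations_make_no_edges(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = -0.9
        conn = ConnectivityMatrix(values=m, channels=("a", "b", "c"),
                                  window_role="task")
        assert binarize(conn, 0.6).adjacency.sum() == 0

    def test_all_ones_matrix_gives_complete_graph(self):
        conn = ConnectivityMatrix(values=np.ones((19, 19)),
                                  channels=CHANNELS_1020, window_role="task")
        g = binarize(conn, 0.6)
        assert g.adjacency.sum() == 19 * 18

    def test_threshold_range_enforced(self):
        conn = _random_conn(np.random.default_rng(5))
        with pytest.raises(ConfigurationError):
            binarize(conn, 1.5)

    def test_lowering_threshold_never_loses_triangles(self):
        rng = np.random.default_rng(6)
        conn = _random_conn(rng)
        triangles = []
        for thr in (0.8, 0.5, 0.2):
            a = binarize(conn, thr).adjacency
            triangles.append(int(np.trace(a @ a @ a)) // 6)
        assert triangles[0] <= triangles[1] <= triangles[2]


def _brute_transitivity(adj):
    """Exhaustive triad enumeration in exact integer arithmetic."""
    n = adj.shape[0]
    closed = opened = 0
    for i, j, k in combinations(range(n), 3):
        edges = adj[i, j] + adj[i, k] + adj[j, k]
        if edges == 3:
            closed += 1
        elif edges == 2:
            opened += 1
    if closed == 0 and opened == 0:
        return 0.0
    return 3 * closed / (3 * closed + opened)


class TestTransitivity:
    def test_triangle_is_fully_clustered(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        g = BinaryGraph(adjacency=adj, channels=("a", "b", "c"), threshold=0.6)
        assert transitivity(g) == 1.0

    def test_path_has_zero_clustering(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        g = BinaryGraph(adjacency=adj, channels=("a", "b", "c"), threshold=0.6)
        assert transitivity(g) == 0.0

    def test_k4_minus_edge(self):
        adj = 1 - np.eye(4, dtype=int)
        adj[0, 1] = adj[1, 0] = 0
        g = BinaryGraph(adjacency=adj, channels=("a", "b", "c", "d"),
                        threshold=0.6)
        assert transitivity(g) == pytest.approx(0.75)

    def test_matches_enumeration_and_networkx_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            p = rng.uniform(0.1, 0.9)
            adj = (rng.uniform(size=(n, n)) < p).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            labels = tuple(f"n{i}" for i in range(n))
            g = BinaryGraph(adjacency=adj, channels=labels, threshold=0.6)
            ours = transitivity(g)
            assert ours == pytest.approx(_brute_transitivity(adj), abs=0)
            assert ours == pytest.approx(
                nx.transitivity(nx.from_numpy_array(adj)), abs=1e-12)

    def test_small_subset_rejected(self):
        adj = np.zeros((4, 4), dtype=int)
        g = BinaryGraph(adjacency=adj, channels=("a", "b", "c", "d"),
                        threshold=0.6)
        with pytest.raises(ConfigurationError):
            transitivity(g, node_subset=("a", "b"))


def test_band_scan_single_band_matches_direct_pipeline(nonhold_small):
    """A one-band scan reproduces the manually-run filter/block/degree path."""
    from mipipe.network import ALL_TARGET_NODES, band_scan_degree
    from mipipe.preprocessing import ANALYSIS_BAND, bandpass, make_trial_blocks

    scan = band_scan_degree(nonhold_small, bands=(ANALYSIS_BAND,))
    blocks = make_trial_blocks(bandpass(nonhold_small, ANALYSIS_BAND))
    per_block = [
        np.mean([node_degree(pearson_connectivity(b, "task"), c)
                 for c in ALL_TARGET_NODES])
        for b in blocks
    ]
    assert scan["n_blocks"].sum() == len(blocks)
    assert scan.loc[0, "mean"] == pytest.approx(np.mean(per_block), abs=1e-9)


def test_band_scan_covers_five_band_grid(nonhold_small):
    from mipipe.network import band_scan_degree

    scan = band_scan_degree(nonhold_small)
    assert set(scan["band"]) == {"0.53-4Hz", "3-6Hz", "5-10Hz",
                                 "8-16Hz", "15-30Hz"}
    assert set(scan["session"]) == {1}
    assert (scan["sd"] >= 0).all()


class TestBlockMetrics:
    def test_zero_signal_block_yields_zero_metrics(self):
        block = _block_from_array(np.zeros((19, 401)))
        metrics = network_metrics(block)
        for role in ("task", "rest"):
            m = metrics[role]
            assert all(v == 0.0 for v in m.node_degree.values())
            assert m.lnl == m.lnr == m.ex == 0.0
            assert m.clustering_all == 0.0

    def test_metrics_invariant_under_channel_relabeling(self):
        """Permuting data with the montage relabeling leaves metrics fixed."""
        rng = np.random.default_rng(8)
        data = rng.standard_normal((19, 401))
        block = _block_from_array(data)
        m1 = network_metrics(block)["task"]
        # permute channels in the data and carry labels along
        perm = rng.permutation(19)
        permuted = data[perm]
        labels = tuple(CHANNELS_1020[i] for i in perm)
        block2 = TrialBlockERP(data=permuted, block_index=1, session=1, day=1,
                               task_label="left", n_trials=20,
                               sampling_rate=200.0, times=block.times,
                               channels=labels, start_trial=0)
        conn1 = pearson_connectivity(block)
        conn2 = pearson_connectivity(block2)
        for ch in CHANNELS_1020:
            i1 = conn1.channels.index(ch)
            i2 = conn2.channels.index(ch)
            assert node_degrees(conn1)[i1] == pytest.approx(
                node_degrees(conn2)[i2], abs=1e-9)
        assert m1 is not None
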