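import math

import networkx as nx
import numpy as np
import pytest

from clrnet.clr import (
    CLRMatrix,
    MIMatrix,
    bin_weights,
    clr_scores,
    mi_matrix,
    mutual_information,
    network_node_count,
    select_threshold_for_node_count,
    threshold_network,
    write_edge_list,
    write_graphml,
    write_xgmml,
)


def plugin_discrete_mi(x, y):
    """Independent oracle: plug-in MI from the joint count table (nats)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for a in np.unique(x):
        for b in np.unique(y):
            pj = np.mean((x == a) & (y == b))
            if pj > 0:
                mi += pj * math.log(pj / (np.mean(x == a) * np.mean(y == b)))
    return mi


class TestMutualInformation:
    def test_bin_weights_partition_of_unity(self):
        rng = np.random.default_rng(0)
        W = bin_weights(rng.normal(size=50), bins=10, spline_order=3)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(W >= 0)

    def test_order_one_equals_contingency_table_mi(self):
        """With first-order (hard) binning, binary vectors reduce to the
        classic discrete plug-in estimator."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 2, 20).astype(float)
            y = rng.integers(0, 2, 20).astype(float)
            if x.min() == x.max() or y.min() == y.max():
                continue
            est = mutual_information(x, y, bins=10, spline_order=1)
            assert est == pytest.approx(plugin_discrete_mi(x, y), abs=1e-12)

    def test_self_mi_equals_marginal_entropy_under_hard_binning(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 30).astype(float)
        W = bin_weights(x, bins=10, spline_order=1)
        p = W.sum(axis=0) / len(x)
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(x, x, spline_order=1) == pytest.approx(entropy, abs=1e-12)

    def test_constant_vector_gives_zero(self):
        x = np.full(20, 3.0)
        y = np.arange(20.0)
        assert mutual_information(x, y) == 0.0
        assert mutual_information(x, x) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12
        )

    def test_mi_decreases_with_noise(self):
        """Estimated MI is non-increasing in the noise variance corrupting a
        copy of the signal (data-processing sanity, averaged over 50 seeds)."""
        sds = [0.1, 0.5, 1.0, 2.0, 4.0]
        curves = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=60)
            curves.append(
                [mutual_information(x, x + rng.normal(scale=s, size=60)) for s in sds]
            )
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) < 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones(3), np.ones(3), bins=10, spline_order=3)

    def test_mi_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(6, 30))
        mim = mi_matrix(values, [f"p{i}" for i in range(6)])
        for i in range(6):
            for j in range(i + 1, 6):
                expected = mutual_information(values[i], values[j])
                assert mim.mi[i, j] == pytest.approx(expected, abs=1e-10)


class TestCLRScores:
    def test_three_gene_hand_example(self):
        """MI(A,B)=0.8 against backgrounds 0.2 gives z(A,B)=1.0000: each row
        has off-diagonal mean 0.5 and sample sd 0.4243, so both sides are
        0.7071 and the combined score is sqrt(2)*0.7071."""
        mi = np.array([[0, 0.8, 0.2], [0.8, 0, 0.2], [0.2, 0.2, 0]])
        clrm = clr_scores(MIMatrix(("A", "B", "C"), mi))
        assert clrm.z[0, 1] == pytest.approx(1.0, abs=5e-5)

    def test_flat_mi_gives_zero_scores(self):
        mi = np.full((4, 4), 0.3)
        np.fill_diagonal(mi, 0.0)
        clrm = clr_scores(MIMatrix(tuple("abcd"), mi))
        off = clrm.z[~np.eye(4, dtype=bool)]
        # all off-diagonal MI equal within each row => no deviation, z = 0
        assert np.allclose(off, 0.0)

    def test_scores_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(4)
        m = np.abs(rng.normal(size=(8, 8)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        clrm = clr_scores(MIMatrix(tuple("abcdefgh"), m))
        np.testing.assert_allclose(clrm.z, clrm.z.T, atol=1e-12)
        assert np.all(clrm.z >= 0)

    def test_score_increases_with_pair_mi(self):
        """Raising one pair's MI (others fixed) strictly raises its CLR score."""
        base = np.array(
            [[0, 0.5, 0.2, 0.1], [0.5, 0, 0.15, 0.2], [0.2, 0.15, 0, 0.1], [0.1, 0.2, 0.1, 0]]
        )
        scores = []
        for bump in (0.5, 0.7, 0.9):
            m = base.copy()
            m[0, 1] = m[1, 0] = bump
            scores.append(clr_scores(MIMatrix(tuple("abcd"), m)).z[0, 1])
        assert scores[0] < scores[1] < scores[2]

    def test_needs_three_probes(self):
        with pytest.raises(ValueError):
            clr_scores(MIMatrix(("a", "b"), np.zeros((2, 2))))


def _toy_clr():
    z = np.array(
        [
            [0.0, 5.0, 3.0, 0.5],
            [5.0, 0.0, 1.0, 0.2],
            [3.0, 1.0, 0.0, 0.1],
            [0.5, 0.2, 0.1, 0.0],
        ]
    )
    return CLRMatrix(("a", "b", "c", "d"), z)


class TestThresholdNetwork:
    def test_edges_meet_threshold_and_no_isolates(self):
        net = threshold_network(_toy_clr(), 2.0)
        assert set(net.nodes) == {"a", "b", "c"}
        assert net["a"]["b"]["clr_z"] == 5.0
        assert all(d["clr_z"] >= 2.0 for _, _, d in net.edges(data=True))

    def test_threshold_above_max_gives_empty_network(self):
        net = threshold_network(_toy_clr(), 10.0)
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_edge_sets_nest_as_threshold_rises(self):
        lo = threshold_network(_toy_clr(), 0.05)
        hi = threshold_network(_toy_clr(), 1.0)
        assert set(hi.edges) <= set(lo.edges)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_network(_toy_clr(), -1.0)


class TestSelectThreshold:
    def test_exact_hit_returned(self):
        clrm = _toy_clr()
        grid = [0.05, 2.0, 4.0]
        assert network_node_count(clrm, 2.0) == 3
        assert select_threshold_for_node_count(clrm, 3, grid) == 2.0

    def test_target_above_total_returns_smallest_grid_value(self):
        # node counts strictly decrease over this grid, so the smallest
        # threshold has the (uniquely) closest count to an oversized target
        assert select_threshold_for_node_count(_toy_clr(), 10, [0.05, 2.0, 4.0]) == 0.05

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        z = np.abs(rng.normal(size=(12, 12)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        clrm = CLRMatrix(tuple(f"p{i}" for i in range(12)), z)
        grid = np.linspace(0.1, 2.5, 25)
        for target in (2, 5, 9, 12):
            got = select_threshold_for_node_count(clrm, target, grid)
            errs = [abs(network_node_count(clrm, g) - target) for g in grid]
            assert abs(network_node_count(clrm, got) - target) == min(errs)

    def test_anchor_preference_breaks_plateau_ties(self):
        clrm = _toy_clr()
        grid = [0.01, 0.02, 0.03]  # all keep every node: a tie on node count
        assert select_threshold_for_node_count(clrm, 4, grid) == 0.03
        assert select_threshold_for_node_count(clrm, 4, grid, prefer_near=0.019) == 0.02

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_threshold_for_node_count(_toy_clr(), 3, [])


class TestExport:
    def test_edge_list_and_graphml_round_trip(self, tmp_path):
        net = threshold_network(_toy_clr(), 1.0)
        write_edge_list(net, tmp_path / "edges.tsv")
        lines = (tmp_path / "edges.tsv").read_text().strip().split("\n")
        assert lines[0] == "probe_a\tprobe_b\tclr_z"
        assert len(lines) == 1 + net.number_of_edges()
        write_graphml(net, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert set(back.nodes) == set(net.nodes)
        assert back.graph["threshold"] == 1.0

    def test_xgmml_is_well_formed(self, tmp_path):
        import xml.etree.ElementTree as ET

        net = threshold_network(_toy_clr(), 1.0)
        write_xgmml(net, tmp_path / "net.xgmml")
        root = ET.parse(tmp_path / "net.xgmml").getroot()
        ns = "{http://www.cs.rpi.edu/XGMML}"
        assert len(root.findall(f"{ns}node")) == net.number_of_nodes()
        assert len(root.findall(f"{ns}edge")) == net.number_of_edges()
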