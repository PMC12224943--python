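import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synspread import (
    GeneSet,
    RegulatoryNetwork,
    WellQuantification,
    adjust_pvalues,
    hypergeometric_enrichment,
    kd_edge_chisquare,
    key_driver_analysis,
    relative_pathology,
)


def _sets(n_bg, n_marker, n_cand, n_overlap):
    bg = [f"g{i}" for i in range(n_bg)]
    markers = bg[:n_marker]
    cands = bg[:n_overlap] + bg[n_marker : n_marker + (n_cand - n_overlap)]
    return (
        GeneSet("cand", frozenset(cands)),
        GeneSet("mark", frozenset(markers)),
        GeneSet("bg", frozenset(bg)),
    )


class TestHypergeometric:
    def test_exact_enumeration_example(self):
        # N=10, K=4, n=5, k=4 -> C(4,4) C(6,1) / C(10,5) = 6/252
        cand, mark, bg = _sets(10, 4, 5, 4)
        res = hypergeometric_enrichment(cand, mark, bg)
        assert res.p_value == pytest.approx(6 / 252)
        assert res.fold_enrichment == pytest.approx(2.0)

    def test_zero_overlap_p_is_one(self):
        cand, mark, bg = _sets(10, 4, 5, 0)
        res = hypergeometric_enrichment(cand, mark, bg)
        assert res.p_value == pytest.approx(1.0)

    def test_markers_outside_background_flagged(self):
        bg = GeneSet("bg", frozenset(["a", "b", "c"]))
        cand = GeneSet("cand", frozenset(["a"]))
        mark = GeneSet("mark", frozenset(["zzz"]))
        res = hypergeometric_enrichment(cand, mark, bg)
        assert res.flagged and res.p_value == 1.0 and res.fold_enrichment == 0.0

    def test_candidates_must_be_in_background(self):
        bg = GeneSet("bg", frozenset(["a"]))
        cand = GeneSet("cand", frozenset(["a", "x"]))
        with pytest.raises(ValueError):
            hypergeometric_enrichment(cand, GeneSet("m", frozenset(["a"])), bg)

    def test_agrees_with_fisher_exact_sample(self):
        # spot-check against the independent Fisher one-sided tail
        for n_bg, n_mark, n_cand, k in [(12, 5, 6, 3), (20, 8, 10, 7), (15, 3, 9, 1)]:
            cand, mark, bg = _sets(n_bg, n_mark, n_cand, k)
            res = hypergeometric_enrichment(cand, mark, bg)
            table = [[k, n_cand - k], [n_mark - k, n_bg - n_mark - n_cand + k]]
            _, fisher_p = stats.fisher_exact(table, alternative="greater")
            assert res.p_value == pytest.approx(fisher_p, rel=1e-9)


class TestAdjustPvalues:
    def test_bonferroni_with_family_size(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bonferroni", m=4)
        np.testing.assert_allclose(out, [0.04, 0.08, 0.12, 0.16])

    def test_bonferroni_single(self):
        np.testing.assert_allclose(adjust_pvalues([0.3], "bonferroni", m=1), [0.3])

    def test_bonferroni_family_too_small(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 0.2], "bonferroni", m=1)

    def test_bh_with_ties(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.01], "BH"), [0.01, 0.01])

    def test_bh_monotone(self):
        rng = np.random.default_rng(0)
        ps = rng.random(50)
        adj = adjust_pvalues(ps, "BH")
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= ps - 1e-12)


def _star_network(n_nodes=50, n_leaves=10):
    nodes = [f"n{i}" for i in range(n_nodes)]
    hub, leaves = nodes[0], nodes[1 : 1 + n_leaves]
    edges = [(hub, leaf) for leaf in leaves]
    # background chain so every node is in the network
    edges += [(nodes[i], nodes[i + 1]) for i in range(1 + n_leaves, n_nodes - 1)]
    return RegulatoryNetwork.from_edges(edges), hub, leaves


class TestKeyDriverAnalysis:
    def test_star_hub_is_key_driver(self):
        net, hub, leaves = _star_network()
        candidates = GeneSet("cand", frozenset(leaves))
        results = key_driver_analysis(net, candidates)
        by_node = {r.node: r for r in results}
        assert by_node[hub].is_key_driver
        assert by_node[hub].overlap == 10
        assert by_node[hub].neighborhood_size == 10

    def test_no_candidate_neighborhood_not_kd(self):
        net, hub, leaves = _star_network()
        # candidates entirely in the chain, far from the hub
        others = sorted(net.nodes - {hub} - set(leaves))[:5]
        results = key_driver_analysis(net, GeneSet("cand", frozenset(others)))
        by_node = {r.node: r for r in results}
        assert not by_node[hub].is_key_driver

    def test_direction_reversal_invariance(self):
        net, hub, leaves = _star_network()
        reversed_net = RegulatoryNetwork.from_edges(
            [(b, a) for a, b in net.graph.edges()]
        )
        candidates = GeneSet("cand", frozenset(leaves))
        fwd = {r.node: (r.p_value, r.overlap) for r in key_driver_analysis(net, candidates)}
        rev = {
            r.node: (r.p_value, r.overlap)
            for r in key_driver_analysis(reversed_net, candidates)
        }
        assert fwd == rev

    def test_disjoint_candidates_yield_no_kds(self):
        net, _, _ = _star_network()
        results = key_driver_analysis(net, GeneSet("cand", frozenset(["absent"])))
        assert all(not r.is_key_driver for r in results)

    def test_self_loops_dropped(self):
        net = RegulatoryNetwork.from_edges([("a", "a"), ("a", "b")])
        assert net.n_self_loops_dropped == 1
        assert net.neighborhood("a") == {"b"}


class TestKdEdgeChisquare:
    def test_expected_count_formula(self):
        # 10 edges from effect-A KDs to any KD, |KD_A|=3, |KD_any|=6 -> expected 4.0
        kd_a = ["a1", "a2", "a3"]
        kd_b = ["b1", "b2", "b3"]
        edges = []
        # a1 sends 10 edges to KDs: 3 within effect A, 7 to effect B... construct exactly
        edges += [("a1", "a2"), ("a1", "a3"), ("a2", "a3")]
        edges += [("a1", "b1"), ("a1", "b2"), ("a1", "b3"), ("a2", "b1"),
                  ("a2", "b2"), ("a3", "b1"), ("a3", "b2")]
        net = RegulatoryNetwork.from_edges(edges)
        out = kd_edge_chisquare(net, {"A": set(kd_a), "B": set(kd_b)})
        row = out[out["effect"] == "A"].iloc[0]
        assert row["observed_same"] + row["observed_other"] == 10
        assert row["expected_same"] == pytest.approx(10 * 2 / 5)
        assert row["expected_same"] + row["expected_other"] == pytest.approx(10.0)

    def test_observed_equals_expected_gives_zero(self):
        # |KD_A|=3 of |KD_any|=6 -> expected fraction 2/5; 5 edges with 2 same
        edges = [("a1", "a2"), ("a1", "a3"), ("a1", "b1"), ("a1", "b2"), ("a1", "b3")]
        net = RegulatoryNetwork.from_edges(edges)
        out = kd_edge_chisquare(
            net, {"A": {"a1", "a2", "a3"}, "B": {"b1", "b2", "b3"}}
        )
        row = out[out["effect"] == "A"].iloc[0]
        assert row["chi2"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_single_kd_undefined(self):
        net = RegulatoryNetwork.from_edges([("a", "b")])
        out = kd_edge_chisquare(net, {"A": {"a"}})
        assert out.iloc[0]["status"] == "undefined"


class TestRelativePathology:
    def _quant(self, treated, control, background):
        return WellQuantification(
            psyn_den={"treated": treated, "control": control, "background": background},
            map2_area={"treated": 1.0, "control": 1.0, "background": 1.0},
        )

    @pytest.mark.parametrize(
        "treated,expected", [(3.0, 0.5), (5.0, 1.0), (1.0, 0.0)]
    )
    def test_arithmetic(self, treated, expected):
        assert relative_pathology(self._quant(treated, 5.0, 1.0)) == pytest.approx(expected)

    def test_invariant_to_common_rescaling(self):
        q1 = self._quant(3.0, 5.0, 1.0)
        q2 = self._quant(30.0, 50.0, 10.0)
        assert relative_pathology(q1) == pytest.approx(relative_pathology(q2))

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            relative_pathology(self._quant(3.0, 1.0, 5.0))

    def test_zero_map2_area_rejected(self):
        q = WellQuantification(
            psyn_den={"treated": 1, "control": 2, "background": 0},
            map2_area={"treated": 0.0, "control": 1.0, "background": 1.0},
        )
        with pytest.raises(ValueError, match="MAP2"):
            relative_pathology(q)
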