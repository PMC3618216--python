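import networkx as nx
import pytest

from helpers import density_only_detect, random_graph
from ppicomplex import (
    DetectParams,
    candidate_score,
    cluster_density,
    compute_close_bottlenecks,
    detect_complexes,
    grow_cluster,
)


class TestClusterDensity:
    @pytest.mark.parametrize(
        "members, expected",
        [
            ({"D", "G"}, 1.0),                      # single present edge
            ({"C", "D", "E", "G", "H"}, 0.7),       # 7 induced edges / 10 pairs
            ({"G"}, 1.0),                           # singleton convention
            ({"A", "J"}, 0.0),                      # no induced edge
        ],
    )
    def test_on_toy(self, toy, members, expected):
        net, _, _ = toy
        assert cluster_density(net, members) == pytest.approx(expected)


class TestCandidateScore:
    def test_worked_example_score_of_d_is_one(self, toy, toy_index):
        """Cluster {G}: shared = {G,C,H}; D's close = {G,C,H}; edge D–G
        present, so density 1 × 3/3 × 3/3 = 1."""
        net, _, _ = toy
        shared = toy_index.close["G"]
        assert candidate_score(net, {"G"}, shared, "D", toy_index) == pytest.approx(1.0)

    def test_partial_sharing_scales_by_both_ratios(self, toy, toy_index):
        """Cluster {A,B} shares only {C}; C's close set has 3 bottlenecks,
        so score(C) = 1 × 1/1 × 1/3."""
        net, _, _ = toy
        shared = toy_index.close["A"] & toy_index.close["B"]
        assert shared == {"C"}
        score = candidate_score(net, {"A", "B"}, shared, "C", toy_index)
        assert score == pytest.approx(1 / 3)

    def test_candidate_without_close_bottlenecks_scores_zero(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")])
        idx = compute_close_bottlenecks(net, frozenset({"A"}))
        # F is far from the only bottleneck: close(F) is empty
        assert candidate_score(net, {"E"}, idx.close["E"], "F", idx) == 0.0

    def test_no_bottlenecks_reduces_to_density(self, toy):
        net, _, _ = toy
        idx = compute_close_bottlenecks(net, frozenset())
        score = candidate_score(net, {"C", "D"}, frozenset(), "E", idx)
        assert score == pytest.approx(cluster_density(net, {"C", "D", "E"}))

    def test_member_candidate_rejected(self, toy, toy_index):
        net, _, _ = toy
        with pytest.raises(ValueError):
            candidate_score(net, {"G", "D"}, frozenset("CGH"), "D", toy_index)


class TestGrowCluster:
    def test_walkthrough_trace_from_g(self, toy, toy_index):
        """Tie admission reproduces the narrated growth: {G} → {D,E,G} →
        {C,D,E,G,H}, ending because C and H are bottlenecks."""
        net, _, _ = toy
        p = DetectParams(cc_threshold=0.6, tie_admission=True)
        cl = grow_cluster(net, "G", toy_index, p)
        assert cl.trace == [frozenset("G"), frozenset("DEG"), frozenset("CDEGH")]
        assert cl.members == frozenset("CDEGH")
        assert cl.shared_bottlenecks == frozenset("CGH")

    def test_default_topk_growth_reaches_same_complex(self, toy, toy_index):
        net, _, _ = toy
        cl = grow_cluster(net, "G", toy_index, DetectParams(cc_threshold=0.6))
        assert cl.members == frozenset("CDEGH")

    def test_growth_from_a_ends_at_bottleneck_c(self, toy, toy_index):
        net, _, _ = toy
        cl = grow_cluster(net, "A", toy_index, DetectParams(cc_threshold=0.6))
        assert cl.members == frozenset("ABC")

    def test_isolated_seed_stays_singleton(self, toy_index):
        net = nx.Graph()
        net.add_node("G")
        idx = compute_close_bottlenecks(net, frozenset())
        cl = grow_cluster(net, "G", idx, DetectParams())
        assert cl.members == frozenset("G")

    def test_unknown_seed_raises(self, toy, toy_index):
        net, _, _ = toy
        with pytest.raises(KeyError):
            grow_cluster(net, "nope", toy_index, DetectParams())

    @pytest.mark.parametrize("seed", range(15))
    def test_bottleneck_members_never_generate_candidates(self, seed):
        """After the initial singleton, the active frontier excludes every
        bottleneck member — the search ends at bottlenecks."""
        net = random_graph(seed, n_max=20, p=0.3)
        ct = nx.betweenness_centrality(net, normalized=False)
        bots = frozenset(sorted(ct, key=lambda n: (-ct[n], n))[:3])
        idx = compute_close_bottlenecks(net, bots)
        for s in sorted(net.nodes):
            cl = grow_cluster(net, s, idx, DetectParams(cc_threshold=0.5))
            assert not (cl.active & bots - ({s} if cl.members == {s} else set()))


class TestDetectComplexes:
    def test_toy_yields_four_overlapping_complexes(self, toy):
        net, bots, expected = toy
        cs = detect_complexes(net, DetectParams(cc_threshold=0.6), bottlenecks=bots)
        assert set(cs) == set(expected)
        # each bottleneck sits on the boundary of exactly two complexes
        for b in bots:
            assert sum(1 for c in cs if b in c) == 2

    def test_toy_via_bc_percent_cut(self, toy):
        net, _, expected = toy
        cs = detect_complexes(net, DetectParams(bc_percent=3 / 11 * 100, cc_threshold=0.6))
        assert set(cs) == set(expected)

    def test_empty_network_gives_empty_set(self):
        assert len(detect_complexes(nx.Graph(), DetectParams())) == 0

    def test_triangle_without_bottlenecks_is_one_complex(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        cs = detect_complexes(net, DetectParams(bc_percent=0, cc_threshold=1.0))
        assert list(cs) == [frozenset("ABC")]

    @pytest.mark.parametrize("seed", range(10))
    def test_output_invariants_on_random_graphs(self, seed):
        net = random_graph(seed, n_max=25, p=0.25)
        p = DetectParams(bc_percent=10, cc_threshold=0.5)
        cs = detect_complexes(net, p)
        sets = list(cs)
        assert len(sets) == len(set(sets))              # no duplicate member sets
        for c in sets:
            assert len(c) >= p.min_size
            assert c <= set(net.nodes)

    @pytest.mark.parametrize("seed", range(10))
    def test_deterministic(self, seed):
        net = random_graph(seed, n_max=20, p=0.3)
        p = DetectParams(bc_percent=10, cc_threshold=0.5)
        assert list(detect_complexes(net, p)) == list(detect_complexes(net, p))

    @pytest.mark.parametrize("seed", range(10))
    def test_ablation_matches_pure_density_growth(self, seed):
        """bc_percent = 0 must coincide with an independently coded
        density-only seed-and-grow."""
        net = random_graph(seed, n_max=20, p=0.3)
        p = DetectParams(bc_percent=0, cc_threshold=0.5, k_percent=5, min_size=3)
        assert list(detect_complexes(net, p)) == density_only_detect(net, 0.5, 5, 3)


class TestDetectParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bc_percent": -1}, {"bc_percent": 101},
            {"cc_threshold": 1.5}, {"k_percent": 0},
            {"k_percent": 120}, {"min_size": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectParams(**kwargs)
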