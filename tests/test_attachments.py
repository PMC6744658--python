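from __future__ import annotations

import random
from itertools import combinations

import pytest

import oracles
from conftest import random_er_network
from ewca.attachments import (
    attach,
    candidate_attachments,
    classify_overlapping,
    classify_peripheral,
    core_weight_stats,
    in_out_weights,
)
from ewca.cores import ComplexCore, detect_cores
from ewca.network import PPINetwork, WeightedNetwork
from ewca.weighting import weight_network


def make_weighted(vertices, weights):
    """Weighted network straight from an explicit pair → weight mapping."""
    base = PPINetwork(vertices=vertices, edges=list(weights))
    return WeightedNetwork(base=base, hocn=dict(weights))


def core_of(wnet, members, seed=None):
    members = frozenset(members)
    edges = frozenset(
        (min(u, v), max(u, v))
        for u, v in combinations(sorted(members), 2)
        if (min(u, v), max(u, v)) in wnet.hocn
    )
    return ComplexCore(seed=seed or min(members), members=members, core_edges=edges)


class TestCandidates:
    def test_one_core_neighbor_is_not_enough(self):
        wnet = make_weighted("abcp", {("a", "b"): 0.5, ("b", "c"): 0.5,
                                      ("a", "c"): 0.5, ("a", "p"): 0.3})
        core = core_of(wnet, "abc")
        assert candidate_attachments(wnet, core) == set()

    def test_two_core_neighbors_suffice(self):
        wnet = make_weighted("abcp", {("a", "b"): 0.5, ("b", "c"): 0.5,
                                      ("a", "c"): 0.5, ("a", "p"): 0.3,
                                      ("b", "p"): 0.3})
        core = core_of(wnet, "abc")
        assert candidate_attachments(wnet, core) == {"p"}

    def test_isolated_core_has_no_candidates(self):
        wnet = make_weighted("abc", {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5})
        assert candidate_attachments(wnet, core_of(wnet, "abc")) == set()


class TestWeightArithmetic:
    def test_two_member_core_average_equals_edge_weight(self):
        wnet = make_weighted("ab", {("a", "b"): 0.37})
        assert core_weight_stats(wnet, core_of(wnet, "ab")) == pytest.approx(0.37)

    def test_core_without_internal_edges_averages_zero(self):
        wnet = make_weighted("abx", {("a", "x"): 0.5, ("b", "x"): 0.5})
        core = ComplexCore(seed="a", members=frozenset("ab"), core_edges=frozenset())
        assert core_weight_stats(wnet, core) == 0.0

    def test_in_out_partition_of_incident_edges(self):
        wnet = make_weighted("abcpq", {("a", "b"): 0.9, ("p", "a"): 0.3,
                                       ("p", "b"): 0.2, ("p", "q"): 0.4})
        core = core_of(wnet, "ab")
        w_in, w_out = in_out_weights(wnet, "p", core)
        assert w_in == pytest.approx(0.5)
        assert w_out == pytest.approx(0.4)

    def test_core_member_rejected(self):
        wnet = make_weighted("ab", {("a", "b"): 0.5})
        with pytest.raises(ValueError):
            in_out_weights(wnet, "a", core_of(wnet, "ab"))


class TestClassification:
    def test_inward_heavy_candidate_is_not_overlapping(self):
        # w_in = 0.6 > w_out = 0.2 fails the outward-pull condition
        wnet = make_weighted("abpq", {("a", "b"): 0.2, ("p", "a"): 0.3,
                                      ("p", "b"): 0.3, ("p", "q"): 0.2})
        core = core_of(wnet, "ab")
        assert classify_overlapping(wnet, core, {"p"}) == set()

    def test_both_boundaries_inclusive_for_overlapping(self):
        # weight_avg = 2*0.4/2 = 0.4; w_in = 0.2 = half of it exactly,
        # w_out = 0.2 = w_in exactly: both ⩾ comparisons hold
        wnet = make_weighted("abpq", {("a", "b"): 0.4, ("p", "a"): 0.1,
                                      ("p", "b"): 0.1, ("p", "q"): 0.2})
        core = core_of(wnet, "ab")
        assert classify_overlapping(wnet, core, {"p"}) == {"p"}

    def test_singleton_cp_member_is_peripheral(self):
        wnet = make_weighted("abpq", {("a", "b"): 0.9, ("p", "a"): 0.3,
                                      ("p", "b"): 0.3, ("p", "q"): 0.1})
        core = core_of(wnet, "ab")
        assert classify_peripheral(wnet, core, {"p"}, set()) == {"p"}

    def test_empty_cp_gives_empty_peripheral(self):
        wnet = make_weighted("ab", {("a", "b"): 0.5})
        assert classify_peripheral(wnet, core_of(wnet, "ab"), set(), set()) == set()

    def test_below_cp_average_is_dropped(self):
        # two inward-bound candidates, w_in 0.9 and 0.1: only the strong one
        # clears the CP mean of 0.5
        wnet = make_weighted(
            "abpq",
            {("a", "b"): 2.0, ("p", "a"): 0.45, ("p", "b"): 0.45,
             ("q", "a"): 0.05, ("q", "b"): 0.05},
        )
        core = core_of(wnet, "ab")
        assert classify_peripheral(wnet, core, {"p", "q"}, set()) == {"p"}

    def test_scale_covariance(self):
        rng = random.Random(17)
        for _ in range(30):
            net = random_er_network(rng, n_max=10)
            wnet = weight_network(net)
            scaled = WeightedNetwork(
                base=net, hocn={e: 7.3 * w for e, w in wnet.hocn.items()}
            )
            for core in detect_cores(wnet, ss=0.4):
                r1 = attach(wnet, core)
                r2 = attach(scaled, core)
                assert r1.overlapping == r2.overlapping
                assert r1.peripheral == r2.peripheral


class TestAttachComposite:
    def test_isolated_core_yields_empty_attachment(self):
        wnet = make_weighted("abc", {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5})
        res = attach(wnet, core_of(wnet, "abc"))
        assert res.attachment == frozenset()

    def test_invariants_on_random_graphs(self):
        rng = random.Random(41)
        for _ in range(100):
            wnet = weight_network(random_er_network(rng, n_max=12))
            for core in detect_cores(wnet, ss=0.4):
                res = attach(wnet, core)
                assert res.overlapping <= res.candidates
                assert res.peripheral <= res.candidates
                assert not (res.overlapping & res.peripheral)
                assert not (res.candidates & core.members)
                for p in res.candidates:
                    assert len(wnet.neighbors(p) & core.members) >= 2

    def test_matches_brute_force_classification(self):
        rng = random.Random(43)
        for _ in range(100):
            net = random_er_network(rng, n_max=12)
            wnet = weight_network(net)
            retained = set(wnet.hocn)
            for core in detect_cores(wnet, ss=0.4):
                cap = oracles.candidate_attachments(
                    retained, wnet.vertices, set(core.members)
                )
                res = attach(wnet, core)
                assert res.candidates == frozenset(cap)
                exp_over, exp_peri = oracles.classify(
                    wnet.hocn, set(core.members), cap
                )
                assert res.overlapping == frozenset(exp_over)
                assert res.peripheral == frozenset(exp_peri)

    def test_shared_bridge_is_overlapping_for_both_cores(self):
        # two triangles sharing no vertex, a bridge bound equally to both
        weights = {("a1", "a2"): 0.3, ("a1", "a3"): 0.3, ("a2", "a3"): 0.3,
                   ("b1", "b2"): 0.3, ("b1", "b3"): 0.3, ("b2", "b3"): 0.3,
                   ("x", "a1"): 0.25, ("x", "a2"): 0.25,
                   ("x", "b1"): 0.25, ("x", "b2"): 0.25}
        wnet = make_weighted(["a1", "a2", "a3", "b1", "b2", "b3", "x"], weights)
        for members in ({"a1", "a2", "a3"}, {"b1", "b2", "b3"}):
            core = core_of(wnet, members)
            res = attach(wnet, core)
            # w_in = w_out = 0.5, half the average weighted core degree is
            # 0.5·(2·0.9/3) = 0.3 ≤ 0.5: overlapping for each core
            assert "x" in res.overlapping
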