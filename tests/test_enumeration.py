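"""Candidate enumeration: seeds, extension, dedup, pruning.

All demo-instance expectations were first computed with the independent
brute-force oracle (tests/oracle.py) and then frozen here.
"""

import numpy as np
import pytest

from consnet.enumeration import (
    DepthInfeasibleError,
    enumerate_candidates,
    extend_candidate,
    max_shared_size,
    prune_non_maximal,
    seed_candidates,
)
from consnet.model import CohortColoring, ColoredSubnetwork, EnumOptions
from consnet.synthetic import generate_cohort, generate_network

from oracle import enumerate_all


class TestSeeds:
    def test_singleton_seeds_at_depth_three(self, demo):
        net, cohort = demo
        seeds = seed_candidates(net, cohort, t=3)
        assert [dict(s.assignment) for s in seeds] == [{"g2": "A"}]
        assert set(seeds.of_size(1)[0].support) == {"P1", "P2", "P3"}

    def test_multi_colored_gene_yields_one_seed_per_color(self):
        net = generate_network(1)
        cohort = CohortColoring(
            ["P1"], {("P1", "g0001"): {"A", "B"}}, alphabet=("A", "B")
        )
        seeds = seed_candidates(net, cohort, t=1)
        assert seeds.keys() == {
            (("g0001", "A"),),
            (("g0001", "B"),),
        }

    def test_colorful_seeds_are_bicolored_edges(self, demo):
        net, cohort = demo
        seeds = seed_candidates(net, cohort, t=2, colorful=True)
        assert all(s.size == 2 and s.is_colorful() for s in seeds)
        # {g2:A, g3:B} is shared by P1 and P2
        assert (("g2", "A"), ("g3", "B")) in seeds.keys()


class TestExtendCandidate:
    def test_accepts_when_support_holds(self, demo):
        net, cohort = demo
        T = ColoredSubnetwork({"g2": "A", "g3": "A"}, {"P1": 0, "P3": 0})
        ext = extend_candidate(T, "g4", "B", net, cohort, t=2)
        assert ext is not None and set(ext.support) == {"P1", "P3"}

    def test_rejects_when_support_drops_below_t(self, demo):
        net, cohort = demo
        T = ColoredSubnetwork(
            {"g2": "A", "g3": "A", "g4": "B"}, {"P1": 0, "P3": 0}
        )
        assert extend_candidate(T, "g5", "B", net, cohort, t=2) is None

    def test_rejects_non_adjacent_extension(self, demo):
        net, cohort = demo
        T = ColoredSubnetwork({"g1": "A"}, {"P1": 0, "P2": 0})
        with pytest.raises(ValueError, match="not adjacent"):
            extend_candidate(T, "g3", "A", net, cohort, t=1)

    def test_budget_growth_admits_sample_at_larger_size(self):
        # delta=0.34: budget floor(0.68)=0 at size 2 but floor(1.02)=1 at 3
        from consnet.model import InteractionNetwork

        a, b, c = "ga", "gb", "gc"
        net = InteractionNetwork.from_edges([(a, b), (b, c)])
        cohort = CohortColoring(
            ["P1", "P2"],
            {
                ("P1", a): {"A"}, ("P1", b): {"A"}, ("P1", c): {"A"},
                ("P2", a): {"A"}, ("P2", b): {"A"},  # c uncolored
            },
            alphabet=("A",),
        )
        T = ColoredSubnetwork({a: "A", b: "A"}, {"P1": 0, "P2": 0})
        ext = extend_candidate(T, c, "A", net, cohort, t=2, delta=0.34)
        assert ext is not None and ext.support == {"P1": 0, "P2": 1}


class TestEnumerate:
    def test_demo_candidates_match_oracle_and_peak_at_size_three(self, demo):
        net, cohort = demo
        opts = EnumOptions(t=2, k=5)
        cands = enumerate_candidates(net, cohort, opts)
        expect = enumerate_all(net, cohort, opts)
        assert {c.canonical_key(): set(c.support) for c in cands} == expect
        assert cands.max_size() == 3

    def test_t1_k1_gives_all_observed_pairs(self, demo):
        net, cohort = demo
        cands = enumerate_candidates(net, cohort, EnumOptions(t=1, k=1))
        observed = {
            (g, c)
            for (s, g), cs in cohort.colors.items()
            for c in cs
        }
        assert cands.keys() == {((g, c),) for g, c in observed}

    def test_colorful_empty_on_monochromatic_cohort(self):
        net = generate_network(6, 2.0, rng=1)
        cohort = CohortColoring(
            ["P1"],
            {("P1", g): {"A"} for g in net.nodes},
            alphabet=("A", "B"),
        )
        cands = enumerate_candidates(net, cohort, EnumOptions(t=1, colorful=True))
        assert len(cands) == 0

    def test_candidate_cap_raises_depth_infeasible(self, demo):
        net, cohort = demo
        opts = EnumOptions(t=1, candidate_cap=2)
        with pytest.raises(DepthInfeasibleError) as err:
            enumerate_candidates(net, cohort, opts)
        assert err.value.count > 2

    def test_delta_monotonicity_candidate_superset(self):
        rng = np.random.default_rng(5)
        net = generate_network(8, 2.5, rng)
        cohort = generate_cohort(net, 3, 0.25, ("A", "B"), rng=rng)
        lo = enumerate_candidates(net, cohort, EnumOptions(t=2, delta=0.0))
        hi = enumerate_candidates(net, cohort, EnumOptions(t=2, delta=0.34))
        assert lo.keys() <= hi.keys()

    def test_max_shared_size_matches_full_enumeration(self, demo):
        net, cohort = demo
        for t in (1, 2, 3):
            full = enumerate_candidates(net, cohort, EnumOptions(t=t))
            assert max_shared_size(net, cohort, EnumOptions(t=t)) == full.max_size()
        assert max_shared_size(net, cohort, EnumOptions(t=1), stop_at=2) == 2


class TestPrune:
    def test_demo_pruning_keeps_only_locally_maximal(self, demo):
        net, cohort = demo
        opts = EnumOptions(t=2, k=3)
        pruned = prune_non_maximal(
            enumerate_candidates(net, cohort, opts), net, cohort, opts
        )
        # oracle-confirmed: {g2:A,g3:A} is pruned (adding g4:B keeps {P1,P3});
        # the two size-3 maxima and the depth-3 singleton {g2:A} survive
        assert pruned.keys() == {
            (("g2", "A"),),
            (("g1", "A"), ("g2", "A"), ("g3", "B")),
            (("g2", "A"), ("g3", "A"), ("g4", "B")),
        }

    def test_candidate_at_size_bound_is_retained(self, demo):
        net, cohort = demo
        opts = EnumOptions(t=2, k=2)
        pruned = prune_non_maximal(
            enumerate_candidates(net, cohort, opts), net, cohort, opts
        )
        # {g2:A,g3:A} has the equal-support extension g4:B but sits at k
        assert (("g2", "A"), ("g3", "A")) in pruned.keys()

    def test_isolated_candidate_is_retained(self):
        net = generate_network(1)
        cohort = CohortColoring(
            ["P1"], {("P1", "g0001"): {"A"}}, alphabet=("A",)
        )
        opts = EnumOptions(t=1)
        pruned = prune_non_maximal(
            enumerate_candidates(net, cohort, opts), net, cohort, opts
        )
        assert pruned.keys() == {(("g0001", "A"),)}
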