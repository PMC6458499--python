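"""Maximum-coverage mode: universe, ILP, brute-force agreement.

Demo-instance objectives were first computed by subset enumeration and
then frozen: universe has 11 colored (sample, gene) pairs; the best
single subnetwork covers 6 of them, the best pair of subnetworks 10.
"""

import numpy as np
import pytest

from consnet.cover import (
    brute_force_cover,
    build_universe,
    covered_pairs,
    exclude_expression_only,
    solve_mcsc,
)
from consnet.enumeration import enumerate_candidates, prune_non_maximal
from consnet.model import ColoredSubnetwork, EnumOptions
from consnet.synthetic import generate_cohort, generate_network


@pytest.fixture()
def demo_candidates(demo):
    net, cohort = demo
    opts = EnumOptions(t=2, k=3)
    return list(
        prune_non_maximal(
            enumerate_candidates(net, cohort, opts), net, cohort, opts
        )
    )


class TestUniverse:
    def test_demo_universe_has_eleven_pairs(self, demo):
        net, cohort = demo
        uni = build_universe(net, cohort)
        assert len(uni) == 11
        assert ("P2", "g3") in uni and ("P2", "g4") not in uni

    def test_empty_cohort_gives_empty_universe(self, demo_network):
        from consnet.model import CohortColoring

        empty = CohortColoring(["P1"], {}, ("A",))
        assert build_universe(demo_network, empty) == set()

    def test_gene_absent_from_network_excluded(self, demo_network):
        from consnet.model import CohortColoring

        cohort = CohortColoring(
            ["P1"], {("P1", "gX"): {"A"}, ("P1", "g1"): {"A"}}, ("A",)
        )
        assert build_universe(demo_network, cohort) == {("P1", "g1")}


class TestSolveMcsc:
    def test_demo_objective_single_subnetwork(self, demo, demo_candidates):
        net, cohort = demo
        uni = build_universe(net, cohort)
        sol = solve_mcsc(demo_candidates, uni, cohort, l=1)
        assert sol.objective == 6

    def test_demo_objective_two_subnetworks(self, demo, demo_candidates):
        net, cohort = demo
        uni = build_universe(net, cohort)
        sol = solve_mcsc(demo_candidates, uni, cohort, l=2)
        assert sol.objective == 10
        chosen = {s.canonical_key() for s in sol.chosen}
        assert chosen == {
            (("g1", "A"), ("g2", "A"), ("g3", "B")),
            (("g2", "A"), ("g3", "A"), ("g4", "B")),
        }

    def test_relaxed_cardinality_covers_union_of_all(self, demo, demo_candidates):
        net, cohort = demo
        uni = build_universe(net, cohort)
        sol = solve_mcsc(demo_candidates, uni, cohort, l=len(demo_candidates))
        union = set().union(*(covered_pairs(c, cohort) for c in demo_candidates))
        assert sol.objective == len(union)

    def test_every_covered_pair_is_certified(self, demo, demo_candidates):
        net, cohort = demo
        sol = solve_mcsc(demo_candidates, build_universe(net, cohort), cohort, 2)
        for sample, gene in sol.covered:
            assert any(
                gene in c.assignment
                and c.assignment[gene] in cohort.color_set(sample, gene)
                and sample in c.support
                for c in sol.chosen
            )

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(25):
            net = generate_network(int(rng.integers(5, 10)), 2.5, rng)
            cohort = generate_cohort(net, int(rng.integers(2, 5)), 0.25, ("A", "B"), rng=rng)
            opts = EnumOptions(t=int(rng.integers(1, 3)), k=3)
            cands = list(enumerate_candidates(net, cohort, opts))[:12]
            uni = build_universe(net, cohort)
            l = int(rng.integers(1, 4))
            assert (
                solve_mcsc(cands, uni, cohort, l).objective
                == brute_force_cover(cands, uni, cohort, l).objective
            )


class TestBruteForce:
    def test_l_zero_covers_nothing(self, demo, demo_candidates):
        net, cohort = demo
        sol = brute_force_cover(demo_candidates, build_universe(net, cohort), cohort, 0)
        assert sol.objective == 0 and sol.chosen == ()

    def test_single_candidate_covers_its_own_pairs(self, demo):
        net, cohort = demo
        cand = ColoredSubnetwork({"g2": "A"}, {"P1": 0, "P2": 0, "P3": 0})
        sol = brute_force_cover([cand], build_universe(net, cohort), cohort, 1)
        assert sol.objective == 3

    def test_refuses_oversized_instances(self, demo):
        net, cohort = demo
        cands = [
            ColoredSubnetwork({"g2": "A"}, {"P1": 0}) for _ in range(25)
        ]
        with pytest.raises(ValueError, match="too large"):
            brute_force_cover(cands, build_universe(net, cohort), cohort, 2)


def test_exclude_expression_only_filter():
    expr = ColoredSubnetwork({"a": "UP", "b": "DOWN"})
    mixed = ColoredSubnetwork({"a": "UP", "b": "AMP"})
    assert exclude_expression_only([expr, mixed]) == [mixed]
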