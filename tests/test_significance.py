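"""Permutation null models and the p-value bracket."""

import numpy as np
import pytest

from consnet.model import CohortColoring, ColoredSubnetwork, EnumOptions
from consnet.significance import (
    PermutationConfig,
    empirical_pvalues,
    permute_cohort,
    permute_p1,
    permute_p2,
)
from consnet.synthetic import (
    PlantSpec,
    assign_arms,
    generate_cohort,
    generate_network,
    plant_pattern,
)


def _counts(coloring):
    out = {}
    for cs in coloring.values():
        for c in cs:
            out[c] = out.get(c, 0) + 1
    return out


class TestP1:
    def test_preserves_per_color_counts(self):
        net = generate_network(30, 3.0, rng=0)
        cohort = generate_cohort(net, 4, 0.15, ("MUT", "UP"), rng=1)
        rng = np.random.default_rng(2)
        for sample in cohort.samples:
            sc = cohort.sample_coloring(sample)
            assert _counts(permute_p1(sc, net, rng)) == _counts(sc)

    def test_empty_sample_stays_empty(self):
        net = generate_network(10, 2.0, rng=0)
        assert permute_p1({}, net, np.random.default_rng(0)) == {}

    def test_fixed_seed_reproducible(self):
        net = generate_network(30, 3.0, rng=0)
        cohort = generate_cohort(net, 2, 0.2, ("MUT",), rng=1)
        sc = cohort.sample_coloring(cohort.samples[0])
        a = permute_p1(sc, net, np.random.default_rng(7))
        b = permute_p1(sc, net, np.random.default_rng(7))
        assert a == b


class TestP2:
    def test_arm_blocks_are_all_or_none(self):
        net = generate_network(40, 3.0, rng=0)
        arm_map = assign_arms(net, genes_per_arm=8, rng=0)
        genes = sorted(net.nodes)[:8]
        sc = {g: frozenset({"AMP"}) for g in genes}
        rng = np.random.default_rng(3)
        for _ in range(50):
            permuted = permute_p2(sc, arm_map, net, rng)
            by_arm = {}
            for g in genes:  # originally colored nodes per arm
                by_arm.setdefault(arm_map[g], []).append(
                    "AMP" in permuted.get(g, frozenset())
                )
            for flags in by_arm.values():
                assert len(set(flags)) == 1

    def test_missing_arm_assignment_raises(self):
        net = generate_network(10, 2.0, rng=0)
        g = sorted(net.nodes)[0]
        with pytest.raises(ValueError, match="without an arm"):
            permute_p2({g: frozenset({"AMP"})}, {}, net, np.random.default_rng(0))

    def test_expected_cn_count_preserved(self):
        # one color per node + full arm coverage: E[#AMP] is exactly N_AMP
        net = generate_network(60, 3.0, rng=0)
        arm_map = assign_arms(net, genes_per_arm=6, rng=0)
        rng_data = np.random.default_rng(4)
        sc = {}
        for g in sorted(net.nodes):
            u = rng_data.random()
            if u < 0.25:
                sc[g] = frozenset({"AMP"})
            elif u < 0.45:
                sc[g] = frozenset({"MUT"})
        n_amp = sum(1 for cs in sc.values() if "AMP" in cs)
        total = sum(len(cs) for cs in sc.values())
        p = n_amp / total
        rng = np.random.default_rng(5)
        reps = 400
        counts = [
            sum(1 for cs in permute_p2(sc, arm_map, net, rng).values() if "AMP" in cs)
            for _ in range(reps)
        ]
        arm_sizes: dict[str, int] = {}
        for g in sc:  # V_A = colored nodes of the arm, any color
            arm_sizes[arm_map[g]] = arm_sizes.get(arm_map[g], 0) + 1
        var_one = sum(v * v for v in arm_sizes.values()) * p * (1 - p)
        se = np.sqrt(var_one / reps)
        assert abs(np.mean(counts) - n_amp) <= 3 * se

    def test_no_cn_colors_behaves_like_p1(self):
        net = generate_network(20, 2.5, rng=0)
        arm_map = assign_arms(net, 5, rng=0)
        sc = {sorted(net.nodes)[0]: frozenset({"MUT"})}
        out = permute_p2(sc, arm_map, net, np.random.default_rng(1))
        assert _counts(out) == {"MUT": 1}


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(9)
    net = generate_network(120, 4.0, rng)
    cohort = generate_cohort(net, 30, 0.005, rng=rng)
    cohort, truth = plant_pattern(cohort, PlantSpec(5, 12), net, rng)
    return net, cohort, truth


class TestEmpiricalPValues:
    def test_planted_subnetwork_is_significant_under_p1(self, planted):
        net, cohort, truth = planted
        config = PermutationConfig(mode="p1", reps=40, seed=1)
        bracket = empirical_pvalues(net, cohort, truth, t=12, config=config)
        assert bracket.p1 == 0.0
        assert bracket.p2 is None
        assert bracket.reps_used == 40

    def test_size_one_subnetwork_is_never_significant(self, planted):
        net, cohort, _ = planted
        trivial = ColoredSubnetwork({sorted(net.nodes)[0]: "MUT"}, {"S001": 0})
        config = PermutationConfig(mode="p1", reps=20, seed=2)
        bracket = empirical_pvalues(net, cohort, trivial, t=1, config=config)
        assert bracket.p1 == 1.0

    def test_default_rep_count_is_one_thousand(self):
        assert PermutationConfig().reps == 1000

    def test_pseudocount_option(self, planted):
        net, cohort, truth = planted
        config = PermutationConfig(mode="p1", reps=10, seed=3, pseudocount=True)
        bracket = empirical_pvalues(net, cohort, truth, t=12, config=config)
        assert bracket.p1 == pytest.approx(1 / 11)


def test_permute_cohort_requires_arms_for_p2():
    net = generate_network(10, 2.0, rng=0)
    cohort = generate_cohort(net, 2, 0.1, ("AMP",), rng=0)
    with pytest.raises(ValueError, match="arm map"):
        permute_cohort(cohort, net, "p2", np.random.default_rng(0))
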