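"""Synthetic networks and cohorts with planted conserved patterns.

Emulates the alteration structure of tumor multi-omics cohorts at desk
scale: a sparse PPI-like random network, per-gene background alterations
drawn independently per (sample, gene, color), optional arm-coherent
copy-number events (all-or-none per chromosome arm per sample), and a
planted connected colored subnetwork carried by a chosen number of
samples with a configurable per-node omission rate.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .model import (
    DEFAULT_ALPHABET,
    DEFAULT_CN_COLORS,
    CohortColoring,
    ColoredSubnetwork,
    InteractionNetwork,
)


def generate_network(
    n: int,
    mean_degree: float = 6.0,
    rng: np.random.Generator | int | None = None,
) -> InteractionNetwork:
    """Sparse connected random network (largest component of G(n, p)).

    ``p`` is chosen for the requested mean degree; the largest connected
    component is retained and nodes are relabelled g0001, g0002, ...
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_degree < 0 or (n > 1 and mean_degree >= n):
        raise ValueError("mean_degree must lie in [0, n)")
    rng = np.random.default_rng(rng)
    if n == 1:
        g = nx.Graph()
        g.add_node("g0001")
        return InteractionNetwork(g)
    p = mean_degree / (n - 1)
    seed = int(rng.integers(2**31 - 1))
    g = nx.gnp_random_graph(n, p, seed=seed)
    component = max(nx.connected_components(g), key=len)
    g = g.subgraph(component)
    mapping = {
        old: f"g{i + 1:04d}" for i, old in enumerate(sorted(g.nodes))
    }
    return InteractionNetwork(nx.relabel_nodes(g, mapping))


def assign_arms(
    network: InteractionNetwork,
    genes_per_arm: int = 20,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Random partition of the network's genes into equal-sized arms."""
    if genes_per_arm < 1:
        raise ValueError("genes_per_arm must be >= 1")
    rng = np.random.default_rng(rng)
    genes = sorted(network.nodes)
    order = rng.permutation(len(genes))
    return {
        genes[idx]: f"arm{pos // genes_per_arm + 1:02d}"
        for pos, idx in enumerate(order)
    }


def generate_cohort(
    network: InteractionNetwork,
    m: int,
    background_rate: float,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    arm_map: Mapping[str, str] | None = None,
    cn_colors: frozenset[str] = DEFAULT_CN_COLORS,
    rng: np.random.Generator | int | None = None,
) -> CohortColoring:
    """Background cohort: each (sample, gene, color) drawn independently.

    With an arm map, copy-number colors are instead drawn arm-wise: per
    sample, per arm, per copy-number color, all of the arm's genes
    receive the color together with probability ``background_rate``
    (mimicking arm-level amplifications/deletions).
    """
    if not 0.0 <= background_rate < 1.0:
        raise ValueError("background_rate must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    genes = sorted(network.nodes)
    samples = [f"S{i + 1:03d}" for i in range(m)]
    colors: dict[tuple[str, str], set[str]] = {}

    arm_genes: dict[str, list[str]] = {}
    if arm_map is not None:
        for g in genes:
            if g in arm_map:
                arm_genes.setdefault(arm_map[g], []).append(g)

    for sample in samples:
        for color in alphabet:
            if arm_map is not None and color in cn_colors:
                for arm in sorted(arm_genes):
                    if rng.random() < background_rate:
                        for g in arm_genes[arm]:
                            colors.setdefault((sample, g), set()).add(color)
            else:
                hits = rng.random(len(genes)) < background_rate
                for g, hit in zip(genes, hits):
                    if hit:
                        colors.setdefault((sample, g), set()).add(color)
    return CohortColoring(samples, colors, alphabet)


@dataclass
class PlantSpec:
    """What to plant: a connected colored pattern carried by some samples.

    pattern may be an explicit gene -> color mapping (its genes must
    induce a connected subgraph) or None for a random connected node set
    with colors drawn uniformly from ``color_pool``.
    """

    size: int
    depth: int
    pattern: Mapping[str, str] | None = None
    omission_rate: float = 0.0
    color_pool: Sequence[str] = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if self.size < 1 or self.depth < 1:
            raise ValueError("size and depth must be >= 1")
        if not 0.0 <= self.omission_rate < 1.0:
            raise ValueError("omission_rate must lie in [0, 1)")


def _random_connected_subset(
    network: InteractionNetwork, size: int, rng: np.random.Generator
) -> list[str]:
    """Random connected node set grown by frontier sampling."""
    genes = sorted(network.nodes)
    for _attempt in range(200):
        start = genes[int(rng.integers(len(genes)))]
        chosen = {start}
        frontier = sorted(network.neighbors(start))
        while len(chosen) < size and frontier:
            u = frontier.pop(int(rng.integers(len(frontier))))
            if u in chosen:
                continue
            chosen.add(u)
            frontier.extend(sorted(network.neighbors(u) - chosen - set(frontier)))
        if len(chosen) == size:
            return sorted(chosen)
    raise ValueError(f"no connected node set of size {size} found")


def plant_pattern(
    cohort: CohortColoring,
    spec: PlantSpec,
    network: InteractionNetwork,
    rng: np.random.Generator | int | None = None,
) -> tuple[CohortColoring, ColoredSubnetwork]:
    """Plant a conserved pattern into ``depth`` randomly chosen carriers.

    Each planted (gene, color) is added to a carrier independently with
    probability 1 - omission_rate.  The returned ground truth records the
    realized per-carrier omission counts; its depth counts all carriers.
    """
    rng = np.random.default_rng(rng)
    if spec.depth > cohort.m:
        raise ValueError("planted depth exceeds the cohort size")
    if spec.pattern is not None:
        assignment = dict(spec.pattern)
        if not network.is_connected_subset(assignment):
            raise ValueError("explicit pattern is not connected in the network")
        if len(assignment) != spec.size:
            raise ValueError("explicit pattern size disagrees with spec.size")
    else:
        nodes = _random_connected_subset(network, spec.size, rng)
        pool = list(spec.color_pool)
        assignment = {
            g: pool[int(rng.integers(len(pool)))] for g in nodes
        }

    carrier_idx = rng.choice(cohort.m, size=spec.depth, replace=False)
    carriers = [cohort.samples[i] for i in sorted(carrier_idx)]
    colors = {k: set(v) for k, v in cohort.colors.items()}
    support: dict[str, int] = {}
    for sample in carriers:
        omitted = 0
        for gene, color in assignment.items():
            if rng.random() < spec.omission_rate:
                omitted += 1
            else:
                colors.setdefault((sample, gene), set()).add(color)
        support[sample] = omitted
    planted = CohortColoring(cohort.samples, colors, cohort.alphabet)
    return planted, ColoredSubnetwork(assignment, support)


def demo_instance() -> tuple[InteractionNetwork, CohortColoring]:
    """Tiny worked example: a 5-gene path with 3 samples.

    P1 colors g1:A g2:A g3:{A,B} g4:B; P2 colors g1:A g2:A g3:B;
    P3 colors g2:A g3:A g4:B g5:B.  Small enough to verify every
    operation by hand or exhaustive search, yet exercises multi-colored
    nodes, ties and the error-rate relaxation.
    """
    net = InteractionNetwork.from_edges(
        [("g1", "g2"), ("g2", "g3"), ("g3", "g4"), ("g4", "g5")]
    )
    colors = {
        ("P1", "g1"): {"A"},
        ("P1", "g2"): {"A"},
        ("P1", "g3"): {"A", "B"},
        ("P1", "g4"): {"B"},
        ("P2", "g1"): {"A"},
        ("P2", "g2"): {"A"},
        ("P2", "g3"): {"B"},
        ("P3", "g2"): {"A"},
        ("P3", "g3"): {"A"},
        ("P3", "g4"): {"B"},
        ("P3", "g5"): {"B"},
    }
    cohort = CohortColoring(["P1", "P2", "P3"], colors, alphabet=("A", "B"))
    return net, cohort


def simulate_survival_cohort(
    n_patients: int,
    betas: Mapping[str, float],
    baseline_hazard: float = 0.1,
    censor_hazard: float = 0.05,
    rng: np.random.Generator | int | None = None,
):
    """Expression + survival times from a known proportional-hazards model.

    Expression x ~ N(0, 1) per gene; event times are exponential with
    rate baseline_hazard * exp(sum_i beta_i x_i); censoring times are
    exponential with rate ``censor_hazard``.  Returns a
    :class:`~consnet.survival.SurvivalInput`.
    """
    import pandas as pd

    from .survival import SurvivalInput

    rng = np.random.default_rng(rng)
    genes = sorted(betas)
    patients = [f"PT{i + 1:04d}" for i in range(n_patients)]
    x = pd.DataFrame(
        rng.standard_normal((n_patients, len(genes))),
        index=patients,
        columns=genes,
    )
    linpred = sum(betas[g] * x[g] for g in genes)
    rate = baseline_hazard * np.exp(linpred)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / censor_hazard, size=n_patients)
    time = pd.Series(np.minimum(event_time, censor_time), index=patients)
    event = pd.Series((event_time <= censor_time).astype(int), index=patients)
    return SurvivalInput(x, time, event)
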