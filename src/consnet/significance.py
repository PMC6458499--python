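"""Empirical p-value bracketing for a discovered subnetwork.

Two permutation null models bracket the true p-value of a conserved
subnetwork of size k at depth t:

* lower bound (independent-genes null): each color is shuffled
  independently across the network's nodes within each sample, exactly
  preserving the per-sample count of every color;
* upper bound (arm-level null): copy-number colors are reassigned to
  whole chromosome arms at once — for each arm and each copy-number
  color E, the arm's originally-colored nodes all receive E with
  probability N_E / sum_j |C[i,j]|, preserving the expected per-color
  count — and the remaining colors are shuffled over the still-uncolored
  nodes as in the lower bound.

The arm-level null treats an arm-wide amplification or deletion as a
single event, which is how large copy-number changes actually arise, so
conserved copy-number subnetworks look far less surprising under it.
For each permuted cohort the single-subnetwork search is re-run at the
discovery threshold t; the p-value is the fraction of replicates whose
largest subnetwork reaches size k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .enumeration import DepthInfeasibleError, max_shared_size
from .model import (
    DEFAULT_CN_COLORS,
    CohortColoring,
    ColoredSubnetwork,
    EnumOptions,
    InteractionNetwork,
)

logger = logging.getLogger(__name__)

ArmMap = Mapping[str, str]
SampleColoring = dict[str, frozenset[str]]


@dataclass
class PermutationConfig:
    mode: str = "both"  # "p1", "p2", or "both"
    reps: int = 1000
    seed: int = 0
    cn_colors: frozenset[str] = DEFAULT_CN_COLORS
    pseudocount: bool = False  # report (r + 1) / (reps + 1) instead of r / reps

    def __post_init__(self) -> None:
        if self.mode not in {"p1", "p2", "both"}:
            raise ValueError("mode must be 'p1', 'p2' or 'both'")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class PValueBracket:
    """p1 (lower) and/or p2 (upper) empirical bounds on the true p-value."""

    p1: float | None
    p2: float | None
    reps_used: int
    exceed_counts: dict[str, int]


def permute_p1(
    sample_coloring: SampleColoring,
    network: InteractionNetwork,
    rng: np.random.Generator,
) -> SampleColoring:
    """Shuffle each color independently across the network's nodes.

    For each color, the set of genes carrying it is replaced by a
    uniformly random node subset of identical cardinality; counts per
    color are exactly preserved and a gene may receive several colors.
    """
    nodes = sorted(network.nodes)
    carriers: dict[str, int] = {}
    for cs in sample_coloring.values():
        for c in cs:
            carriers[c] = carriers.get(c, 0) + 1
    out: dict[str, set[str]] = {}
    for color in sorted(carriers):
        count = carriers[color]
        assert count <= len(nodes), "more carriers than network nodes"
        chosen = rng.choice(len(nodes), size=count, replace=False)
        for idx in chosen:
            out.setdefault(nodes[idx], set()).add(color)
    return {g: frozenset(cs) for g, cs in out.items()}


def permute_p2(
    sample_coloring: SampleColoring,
    arm_map: ArmMap,
    network: InteractionNetwork,
    rng: np.random.Generator,
    cn_colors: frozenset[str] = DEFAULT_CN_COLORS,
) -> SampleColoring:
    """Arm-coherent copy-number reassignment, then shuffle the rest.

    Step 1: for each chromosome arm and each copy-number color E present
    in the sample, assign E to *all* of the arm's originally-colored
    nodes with probability N_E / sum_j |C[i,j]| (clamped to 1),
    independently per (arm, color).  Step 2: non-copy-number colors are
    shuffled over the nodes left uncolored by step 1.
    """
    counts: dict[str, int] = {}
    for cs in sample_coloring.values():
        for c in cs:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    present_cn = sorted(c for c in counts if c in cn_colors)
    missing = sorted(
        g
        for g, cs in sample_coloring.items()
        if cs & cn_colors and g not in arm_map
    )
    if missing:
        raise ValueError(
            f"copy-number-colored genes without an arm assignment: {missing}"
        )

    # arm -> originally colored nodes of that arm
    arm_nodes: dict[str, list[str]] = {}
    for g in sorted(sample_coloring):
        if sample_coloring[g] and g in arm_map:
            arm_nodes.setdefault(arm_map[g], []).append(g)

    out: dict[str, set[str]] = {}
    step1_hit: set[str] = set()
    for arm in sorted(arm_nodes):
        for color in present_cn:
            prob = counts[color] / total if total else 0.0
            if prob > 1.0:
                warnings.warn(
                    f"arm reassignment probability for {color} clamped to 1",
                    stacklevel=2,
                )
                prob = 1.0
            if rng.random() < prob:
                for g in arm_nodes[arm]:
                    out.setdefault(g, set()).add(color)
                    step1_hit.add(g)

    eligible = sorted(set(network.nodes) - step1_hit)
    for color in sorted(counts):
        if color in cn_colors:
            continue
        count = counts[color]
        if count > len(eligible):
            warnings.warn(
                f"only {len(eligible)} nodes available for {count} copies "
                f"of color {color}; count truncated",
                stacklevel=2,
            )
            count = len(eligible)
        chosen = rng.choice(len(eligible), size=count, replace=False)
        for idx in chosen:
            out.setdefault(eligible[idx], set()).add(color)
    return {g: frozenset(cs) for g, cs in out.items()}


def permute_cohort(
    cohort: CohortColoring,
    network: InteractionNetwork,
    mode: str,
    rng: np.random.Generator,
    arm_map: ArmMap | None = None,
    cn_colors: frozenset[str] = DEFAULT_CN_COLORS,
) -> CohortColoring:
    """Permute every sample's coloring under the requested null model."""
    if mode == "p2" and arm_map is None:
        raise ValueError("the arm-level null requires an arm map")
    colors: dict[tuple[str, str], frozenset[str]] = {}
    for sample in cohort.samples:
        sc = cohort.sample_coloring(sample)
        if mode == "p1":
            permuted = permute_p1(sc, network, rng)
        else:
            permuted = permute_p2(sc, arm_map, network, rng, cn_colors)
        for gene, cs in permuted.items():
            if cs:
                colors[(sample, gene)] = cs
    return CohortColoring(cohort.samples, colors, cohort.alphabet)


def empirical_pvalues(
    network: InteractionNetwork,
    cohort: CohortColoring,
    observed: ColoredSubnetwork,
    t: int,
    opts: EnumOptions | None = None,
    config: PermutationConfig | None = None,
    arm_map: ArmMap | None = None,
) -> PValueBracket:
    """Bracket the p-value of an observed subnetwork of size k, depth t.

    For each replicate, every sample's coloring is permuted and the
    single-subnetwork search is re-run at the same threshold t and
    options as the discovery run; a replicate *exceeds* when its largest
    shared subnetwork reaches size k.  A replicate whose enumeration
    trips the candidate cap is counted as exceeding (conservative) and
    logged.  The true p-value lies in [p1, p2].
    """
    config = config or PermutationConfig()
    opts = replace(opts, t=t, k=None) if opts is not None else EnumOptions(t=t)
    k = observed.size
    modes = ["p1", "p2"] if config.mode == "both" else [config.mode]
    exceed: dict[str, int] = {}
    for mode in modes:
        rng = np.random.default_rng([config.seed, 1 if mode == "p1" else 2])
        count = 0
        for _rep in range(config.reps):
            permuted = permute_cohort(
                cohort, network, mode, rng, arm_map, config.cn_colors
            )
            try:
                size = max_shared_size(network, permuted, opts, stop_at=k)
            except DepthInfeasibleError:
                logger.warning(
                    "replicate exceeded the candidate cap; counted as success"
                )
                size = k
            if size >= k:
                count += 1
        exceed[mode] = count

    def _p(mode: str) -> float | None:
        if mode not in exceed:
            return None
        if config.pseudocount:
            return (exceed[mode] + 1) / (config.reps + 1)
        return exceed[mode] / config.reps

    return PValueBracket(_p("p1"), _p("p2"), config.reps, exceed)
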