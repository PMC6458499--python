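"""Independent brute-force oracles used to validate the solvers.

These deliberately share no code with the enumeration engine: connected
node subsets are enumerated recursively, colorings by Cartesian product
over each gene's observed colors, and support by direct application of
the sharing predicate's definition.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable

from consnet.model import CohortColoring, EnumOptions, InteractionNetwork

Key = tuple[tuple[str, str], ...]


def connected_subsets(
    network: InteractionNetwork, max_size: int | None = None
) -> list[frozenset[str]]:
    """All connected induced node subsets (each exactly once)."""
    nodes = sorted(network.nodes)
    rank = {g: i for i, g in enumerate(nodes)}
    out: list[frozenset[str]] = []

    def grow(current: set[str], frontier: set[str], forbidden: set[str]) -> None:
        out.append(frozenset(current))
        if max_size is not None and len(current) >= max_size:
            return
        frontier = sorted(frontier)
        banned = set(forbidden)
        for u in frontier:
            new_frontier = (
                set(frontier) | network.neighbors(u)
            ) - current - banned - {u}
            grow(current | {u}, new_frontier, set(banned))
            banned.add(u)

    for start in nodes:
        allowed_frontier = {
            v for v in network.neighbors(start) if rank[v] > rank[start]
        }
        forbidden = {v for v in nodes if rank[v] < rank[start]}
        grow({start}, allowed_frontier, forbidden)
    return out


def observed_colors(cohort: CohortColoring, gene: str) -> list[str]:
    cs: set[str] = set()
    for sample in cohort.samples:
        cs |= cohort.color_set(sample, gene)
    return sorted(cs)


def sample_omissions(
    cohort: CohortColoring, sample: str, assignment: dict[str, str], lenient: bool
) -> int | None:
    """Minimal omission count, None when the sample can never share."""
    om = 0
    for gene, color in assignment.items():
        cs = cohort.color_set(sample, gene)
        if color in cs:
            continue
        if cs and not lenient:
            return None
        om += 1
    return om


def support_set(
    cohort: CohortColoring,
    assignment: dict[str, str],
    delta: float,
    lenient: bool,
) -> set[str]:
    budget = int(math.floor(delta * len(assignment) + 1e-9))
    out = set()
    for sample in cohort.samples:
        om = sample_omissions(cohort, sample, assignment, lenient)
        if om is not None and om <= budget:
            out.add(sample)
    return out


def enumerate_all(
    network: InteractionNetwork,
    cohort: CohortColoring,
    opts: EnumOptions,
) -> dict[Key, set[str]]:
    """Every connected colored subgraph with depth >= t, keyed canonically."""
    out: dict[Key, set[str]] = {}
    for subset in connected_subsets(network, opts.k):
        genes = sorted(subset)
        pools = [observed_colors(cohort, g) for g in genes]
        if any(not p for p in pools):
            continue
        for combo in itertools.product(*pools):
            assignment = dict(zip(genes, combo))
            if opts.colorful and len(set(combo)) < 2:
                continue
            supp = support_set(cohort, assignment, opts.delta, opts.lenient)
            if len(supp) >= opts.t:
                out[tuple(sorted(assignment.items()))] = supp
    return out


def mcsi_oracle(
    network: InteractionNetwork, cohort: CohortColoring, opts: EnumOptions
) -> tuple[int, set[Key]]:
    """(max size, tie set of canonical keys) by exhaustive search."""
    table = enumerate_all(network, cohort, opts)
    if not table:
        return 0, set()
    best = max(len(k) for k in table)
    return best, {k for k in table if len(k) == best}


def cover_objective(
    cover_sets: Iterable[frozenset], l: int
) -> int:
    """Best coverage of <= l sets by subset enumeration."""
    cover_sets = list(cover_sets)
    best = 0
    for r in range(0, min(l, len(cover_sets)) + 1):
        for combo in itertools.combinations(cover_sets, r):
            union = set().union(*combo) if combo else set()
            best = max(best, len(union))
    return best
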