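"""Single-subnetwork mode: largest conserved colored subnetwork (MCSI).

Solves the maximum conserved subnetwork identification problem: the
largest connected colored subnetwork shared by at least ``t`` samples.
Also provides the depth scan producing, for every feasible depth, the
maximum size and the number of distinct maximal solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .enumeration import (
    CandidateSet,
    DepthInfeasibleError,
    enumerate_candidates,
)
from .model import CohortColoring, ColoredSubnetwork, EnumOptions, InteractionNetwork


@dataclass
class FeasibilityRule:
    """Which depths are worth scanning.

    A depth is feasible when it is at least ``min_depth_fraction`` of the
    cohort, the maximal subnetwork at that depth has at least ``min_size``
    nodes, and no growth iteration produces more than ``candidate_cap``
    candidates.
    """

    min_depth_fraction: float = 0.10
    min_size: int = 3
    candidate_cap: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.min_depth_fraction <= 1.0:
            raise ValueError("min_depth_fraction must lie in (0, 1]")
        if self.min_size < 1 or self.candidate_cap < 1:
            raise ValueError("min_size and candidate_cap must be positive")


@dataclass
class ProfileRow:
    t: int
    max_size: int
    n_solutions: int
    categories: dict[str, int]
    valley_end: bool = False


@dataclass
class DepthProfile:
    """Depth-versus-size profile: one row per scanned depth t.

    ``max_size`` is non-increasing in t; a row is a *valley end* when it
    attains the largest depth for its subnetwork size.
    """

    rows: list[ProfileRow] = field(default_factory=list)

    def mark_valley_ends(self) -> None:
        best_t: dict[int, int] = {}
        for row in self.rows:
            best_t[row.max_size] = max(best_t.get(row.max_size, 0), row.t)
        for row in self.rows:
            row.valley_end = row.t == best_t[row.max_size]

    def to_rows(self) -> list[dict]:
        return [
            {
                "t": r.t,
                "max_size": r.max_size,
                "n_solutions": r.n_solutions,
                "valley_end": r.valley_end,
                **{f"n_{cat}": n for cat, n in sorted(r.categories.items())},
            }
            for r in self.rows
        ]


def solve_mcsi(
    network: InteractionNetwork,
    cohort: CohortColoring,
    t: int,
    opts: EnumOptions | None = None,
) -> list[ColoredSubnetwork]:
    """All maximum-size conserved colored subnetworks of depth >= t.

    Runs the enumeration without a size bound until an iteration empties,
    then returns the full tie set at the maximum size (empty when no
    colored node reaches depth t).  Solutions are ordered by canonical
    key for determinism.
    """
    if opts is None:
        opts = EnumOptions(t=t)
    else:
        opts = replace(opts, t=t, k=None)
    candidates = enumerate_candidates(network, cohort, opts)
    if len(candidates) == 0:
        return []
    best = candidates.max_size()
    return sorted(candidates.of_size(best), key=lambda s: s.canonical_key())


def scan_depths(
    network: InteractionNetwork,
    cohort: CohortColoring,
    rule: FeasibilityRule | None = None,
    opts: EnumOptions | None = None,
    t_values: Sequence[int] | None = None,
) -> DepthProfile:
    """Profile the maximal conserved subnetwork across feasible depths.

    Scans t upward from ceil(min_depth_fraction * m); stops once the
    maximal size drops below ``min_size`` (max size is non-increasing in
    t, so no larger depth can be feasible) or the candidate cap trips.
    """
    if cohort.m == 0:
        raise ValueError("cohort is empty")
    rule = rule or FeasibilityRule()
    base = opts or EnumOptions()
    if t_values is None:
        t_min = max(1, math.ceil(rule.min_depth_fraction * cohort.m))
        t_values = range(t_min, cohort.m + 1)
    profile = DepthProfile()
    for t in t_values:
        run_opts = replace(base, t=t, k=None, candidate_cap=rule.candidate_cap)
        try:
            solutions = solve_mcsi(network, cohort, t, run_opts)
        except DepthInfeasibleError:
            break
        if not solutions:
            break
        size = solutions[0].size
        if size < rule.min_size:
            break
        categories: dict[str, int] = {}
        for s in solutions:
            categories[s.category()] = categories.get(s.category(), 0) + 1
        profile.rows.append(ProfileRow(t, size, len(solutions), categories))
    profile.mark_valley_ends()
    return profile


__all__ = [
    "CandidateSet",
    "DepthProfile",
    "FeasibilityRule",
    "ProfileRow",
    "scan_depths",
    "solve_mcsi",
]
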