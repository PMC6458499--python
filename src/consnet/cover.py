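"""Multi-subnetwork mode: maximum conserved subnetwork cover (MCSC).

Given the candidate subnetworks (depth >= t, size <= k), choose at most
``l`` of them so that they collectively cover as many colored
(sample, gene) pairs as possible.  A pair is covered by a chosen
subnetwork T when T contains the gene, T's color for it is among the
sample's colors, and the sample shares T.  The problem is solved exactly
as a 0/1 integer linear program:

    maximize   sum_q C_q                 over universe pairs q
    such that  C_q <= sum_{p : q in cov(T_p)} X_p      for every q
               sum_p X_p <= l
               X_p, C_q binary

with HiGHS branch-and-bound as the backend; the reported objective is
re-verified by recomputing coverage from the chosen set.  A brute-force
subset-enumeration oracle is provided for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import CohortColoring, ColoredSubnetwork, InteractionNetwork

Pair = tuple[str, str]


@dataclass(frozen=True)
class CoverSolution:
    chosen: tuple[ColoredSubnetwork, ...]
    covered: frozenset[Pair]

    @property
    def objective(self) -> int:
        return len(self.covered)


def build_universe(
    network: InteractionNetwork, cohort: CohortColoring
) -> set[Pair]:
    """All colored (sample, gene) pairs over genes present in the network."""
    return {
        (s, g)
        for (s, g), cs in cohort.colors.items()
        if cs and network.has_node(g)
    }


def covered_pairs(sub: ColoredSubnetwork, cohort: CohortColoring) -> set[Pair]:
    """Pairs certified covered by one subnetwork.

    Restricted to supporting samples and properly colored nodes; an
    exception node admitted under the error rate is never counted (its
    color set either is empty — outside the universe — or does not
    contain the assigned color).
    """
    out: set[Pair] = set()
    for sample in sub.support:
        for gene, color in sub.assignment.items():
            if color in cohort.color_set(sample, gene):
                out.add((sample, gene))
    return out


def _coverage_sets(
    candidates: Sequence[ColoredSubnetwork], cohort: CohortColoring
) -> list[set[Pair]]:
    return [covered_pairs(c, cohort) for c in candidates]


def solve_mcsc(
    candidates: Sequence[ColoredSubnetwork],
    universe: Iterable[Pair],
    cohort: CohortColoring,
    l: int,
) -> CoverSolution:
    """Optimal <=l-subnetwork cover of the colored-node universe via ILP."""
    if l < 0:
        raise ValueError("l must be >= 0")
    candidates = sorted(candidates, key=lambda s: s.canonical_key())
    universe = sorted(set(universe))
    cov = _coverage_sets(candidates, cohort)
    # restrict to coverable pairs; uncoverable ones contribute 0 regardless
    coverable = [q for q in universe if any(q in c for c in cov)]
    if not candidates or not coverable or l == 0:
        return CoverSolution((), frozenset())

    n_x, n_c = len(candidates), len(coverable)
    q_index = {q: i for i, q in enumerate(coverable)}
    # variables: X_0..X_{n_x-1}, C_0..C_{n_c-1}; minimize -sum(C)
    objective = np.concatenate([np.zeros(n_x), -np.ones(n_c)])
    rows, cols, vals = [], [], []
    for p, pairs in enumerate(cov):
        for q in pairs:
            rows.append(q_index[q])
            cols.append(p)
            vals.append(-1.0)
    for i in range(n_c):
        rows.append(i)
        cols.append(n_x + i)
        vals.append(1.0)
    a_cover = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_c, n_x + n_c)
    )
    a_card = sparse.coo_matrix(
        (np.ones(n_x), (np.zeros(n_x, dtype=int), np.arange(n_x))),
        shape=(1, n_x + n_c),
    )
    constraints = [
        LinearConstraint(a_cover, -np.inf, 0.0),
        LinearConstraint(a_card, -np.inf, float(l)),
    ]
    res = milp(
        c=objective,
        constraints=constraints,
        bounds=Bounds(0.0, 1.0),
        integrality=np.ones(n_x + n_c),
    )
    if res.status != 0:  # pragma: no cover - all-zero is always feasible
        raise RuntimeError(f"MILP solver failed: {res.message}")
    chosen = tuple(
        candidates[p] for p in range(n_x) if res.x[p] > 0.5
    )
    covered = frozenset().union(*(covered_pairs(c, cohort) for c in chosen)) if chosen else frozenset()
    # re-verify the solver's objective against certified coverage
    assert abs(-res.fun - len(covered)) < 1e-6, "ILP objective mismatch"
    return CoverSolution(chosen, frozenset(covered))


def brute_force_cover(
    candidates: Sequence[ColoredSubnetwork],
    universe: Iterable[Pair],
    cohort: CohortColoring,
    l: int,
    max_candidates: int = 20,
) -> CoverSolution:
    """Exact optimum by enumerating all candidate subsets of size <= l."""
    candidates = sorted(candidates, key=lambda s: s.canonical_key())
    if len(candidates) > max_candidates:
        raise ValueError(
            f"instance too large for brute force: {len(candidates)} "
            f"candidates > {max_candidates}"
        )
    uni = set(universe)
    cov = _coverage_sets(candidates, cohort)
    best: tuple[int, tuple[int, ...]] = (0, ())
    for r in range(0, min(l, len(candidates)) + 1):
        for combo in itertools.combinations(range(len(candidates)), r):
            covered = set().union(*(cov[p] for p in combo)) if combo else set()
            covered &= uni
            if len(covered) > best[0]:
                best = (len(covered), combo)
    combo = best[1]
    covered = set().union(*(cov[p] for p in combo)) if combo else set()
    return CoverSolution(
        tuple(candidates[p] for p in combo), frozenset(covered & uni)
    )


def exclude_expression_only(
    candidates: Sequence[ColoredSubnetwork],
    expression_colors: Iterable[str] = ("UP", "DOWN"),
) -> list[ColoredSubnetwork]:
    """Drop candidates whose nodes are all expression outliers."""
    expr = set(expression_colors)
    return [
        c
        for c in candidates
        if not set(c.assignment.values()) <= expr
    ]
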