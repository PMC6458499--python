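"""Breadth-first a-priori enumeration of conserved colored subnetworks.

The generator grows candidate subnetworks one node at a time, keeping a
candidate only while it can still reach the minimum depth ``t``.  Pruning
rests on the anti-monotone property of sharing: a sample that shares a
subnetwork shares every connected sub-subnetwork with no more omissions,
so once a candidate's attainable support drops below ``t`` every
supergraph is hopeless.

With a nonzero error rate the omission budget floor(delta * size) grows
with size, so a subnetwork can meet the depth threshold while none of
its immediate subgraphs does at *their* (smaller) budget.  Growth
therefore retains any candidate whose support under the maximal budget —
the budget at the largest size any candidate could still reach — is at
least ``t``; only emission into the returned candidate set applies the
per-size budget.  Since every connected colored subset of a valid
candidate also passes the retention test, the search provably reaches
every valid candidate.

Two implementation choices keep the search fast: sample support is
tracked as bit masks over the cohort, one mask per omission level, so
extending a candidate is a handful of bitwise operations regardless of
cohort size; and node sets are generated exactly once each, by growing
only within an ordered extension frontier (the exclusion-set scheme used
for connected-subgraph census algorithms), with the coloring branched at
the moment a node enters.  Candidate nodes are restricted to genes with
at least one observed color, and a node's assignable colors are exactly
those observed for it in some sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .model import (
    CohortColoring,
    ColoredSubnetwork,
    EnumOptions,
    InteractionNetwork,
    canonical_key,
    shares,
)

Key = tuple[tuple[str, str], ...]


class DepthInfeasibleError(RuntimeError):
    """Raised when a growth iteration exceeds the candidate cap.

    Signals that the requested depth threshold is infeasible to
    enumerate exhaustively, rather than silently truncating the
    candidate set.
    """

    def __init__(self, size: int, count: int, cap: int):
        self.size = size
        self.count = count
        self.cap = cap
        super().__init__(
            f"candidate cap exceeded at subnetwork size {size}: "
            f"{count} > {cap}; raise t or the cap"
        )


@dataclass
class CandidateSet:
    """Deduplicated candidates surviving depth >= t and size <= k."""

    by_size: dict[int, list[ColoredSubnetwork]] = field(default_factory=dict)

    def add(self, sub: ColoredSubnetwork) -> None:
        self.by_size.setdefault(sub.size, []).append(sub)

    def __iter__(self) -> Iterator[ColoredSubnetwork]:
        for size in sorted(self.by_size):
            yield from self.by_size[size]

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_size.values())

    def max_size(self) -> int:
        return max(self.by_size) if self.by_size else 0

    def of_size(self, size: int) -> list[ColoredSubnetwork]:
        return list(self.by_size.get(size, []))

    def keys(self) -> set[Key]:
        return {s.canonical_key() for s in self}

    def sort(self) -> None:
        for size in self.by_size:
            self.by_size[size].sort(key=lambda s: s.canonical_key())


class _Index:
    """Bitmask index of a cohort restricted to network genes.

    For each (gene, color): mask of samples where the color is present.
    For each gene: mask of samples where the gene carries any color.
    """

    def __init__(self, network: InteractionNetwork, cohort: CohortColoring):
        self.network = network
        self.cohort = cohort
        self.samples = list(cohort.samples)
        self.m = len(self.samples)
        self.full_mask = (1 << self.m) - 1
        sample_bit = {s: 1 << i for i, s in enumerate(self.samples)}

        self.proper: dict[tuple[str, str], int] = {}
        self.colored: dict[str, int] = {}
        for (sample, gene), cs in cohort.colors.items():
            if not network.has_node(gene):
                continue
            bit = sample_bit[sample]
            self.colored[gene] = self.colored.get(gene, 0) | bit
            for c in cs:
                key = (gene, c)
                self.proper[key] = self.proper.get(key, 0) | bit

        self.observed_colors: dict[str, list[str]] = {}
        for gene, c in self.proper:
            self.observed_colors.setdefault(gene, []).append(c)
        for gene in self.observed_colors:
            self.observed_colors[gene].sort()

    def colored_gene_counts(self) -> list[int]:
        """Per-sample number of colored network genes (descending)."""
        counts = [0] * self.m
        for _gene, mask in self.colored.items():
            while mask:
                low = mask & -mask
                counts[low.bit_length() - 1] += 1
                mask ^= low
        return sorted(counts, reverse=True)

    def node_masks(self, gene: str, color: str, lenient: bool) -> tuple[int, int]:
        """(match mask, exception mask) for one assigned node.

        Samples in neither mask can never share any candidate containing
        the node (miscolored under strict semantics).
        """
        ok = self.proper.get((gene, color), 0)
        if lenient:
            exc = self.full_mask & ~ok
        else:
            exc = self.full_mask & ~self.colored.get(gene, 0)
        return ok, exc


def _max_reachable_size(index: _Index, opts: EnumOptions) -> int:
    """Largest size any depth->=t candidate could reach under delta.

    A sharing sample must properly color at least (1 - delta) of the
    nodes, so size is bounded by c_t / (1 - delta) where c_t is the t-th
    largest per-sample colored-gene count.  Used only to fix the maximal
    omission budget when k is unlimited.
    """
    counts = index.colored_gene_counts()
    if len(counts) < opts.t:
        return 0
    c_t = counts[opts.t - 1]
    if opts.delta == 0.0:
        return c_t
    return int(math.ceil((c_t + 1) / (1.0 - opts.delta)))


class _State:
    """One colored candidate on the growth frontier."""

    __slots__ = ("pairs", "levels", "root", "ext", "closed")

    def __init__(self, pairs, levels, root, ext, closed):
        self.pairs = pairs      # tuple[(gene, color)] in insertion order
        self.levels = levels    # tuple[int]: levels[b] = samples at b omissions
        self.root = root        # rank of the first node (uniqueness anchor)
        self.ext = ext          # ordered extension frontier (ranks)
        self.closed = closed    # frozenset of ranks: nodes U their neighbors

    def support_mask(self, budget: int) -> int:
        mask = 0
        for b in range(min(budget, len(self.levels) - 1) + 1):
            mask |= self.levels[b]
        return mask


class _Engine:
    """Shared growth loop for full enumeration and max-size queries.

    Node sets are enumerated exactly once each: growth starts from every
    colored gene as a root and only ever adds nodes of higher rank than
    the root, drawn from an ordered extension list that excludes nodes
    already adjacent to the candidate (so the same set cannot be reached
    along two different insertion orders).
    """

    def __init__(
        self,
        network: InteractionNetwork,
        cohort: CohortColoring,
        opts: EnumOptions,
    ):
        self.opts = opts
        self.index = _Index(network, cohort)
        k_bound = opts.k if opts.k is not None else _max_reachable_size(self.index, opts)
        self.max_budget = opts.budget(max(k_bound, 1))
        self.n_levels = self.max_budget + 1

        genes = sorted(self.index.observed_colors)
        self.genes = genes
        rank = {g: r for r, g in enumerate(genes)}
        self.adj: list[tuple[int, ...]] = [
            tuple(
                sorted(
                    rank[v]
                    for v in network.neighbors(g)
                    if v in rank
                )
            )
            for g in genes
        ]
        self.colors_of: list[list[tuple[str, tuple[int, int]]]] = [
            [
                (c, self.index.node_masks(g, c, opts.lenient))
                for c in self.index.observed_colors[g]
            ]
            for g in genes
        ]

    def _seed_states(self) -> list[_State]:
        t = self.opts.t
        n_levels = self.n_levels
        out: list[_State] = []
        for r, g in enumerate(self.genes):
            ext = tuple(x for x in self.adj[r] if x > r)
            closed = frozenset((r, *self.adj[r]))
            for c, (ok, exc) in self.colors_of[r]:
                levels = [0] * n_levels
                levels[0] = ok
                if n_levels > 1:
                    levels[1] = exc
                attain = ok | (exc if n_levels > 1 else 0)
                if attain.bit_count() >= t:
                    out.append(_State(((g, c),), tuple(levels), r, ext, closed))
        return out

    def frontiers(self) -> Iterator[tuple[int, list[_State]]]:
        """Yield (size, frontier) for successive sizes until exhaustion."""
        opts = self.opts
        t = opts.t
        n_levels = self.n_levels
        adj = self.adj
        genes = self.genes
        colors_of = self.colors_of
        size = 1
        frontier = self._seed_states()
        while frontier:
            if len(frontier) > opts.candidate_cap:
                raise DepthInfeasibleError(size, len(frontier), opts.candidate_cap)
            yield size, frontier
            if opts.k is not None and size >= opts.k:
                return
            nxt: list[_State] = []
            for state in frontier:
                ext = state.ext
                if not ext:
                    continue
                pairs = state.pairs
                levels = state.levels
                root = state.root
                closed = state.closed
                for i, w in enumerate(ext):
                    fresh = tuple(
                        x for x in adj[w] if x > root and x not in closed
                    )
                    child_ext = ext[i + 1:] + fresh
                    child_closed = closed.union(fresh)
                    gene_w = genes[w]
                    for c, (ok, exc) in colors_of[w]:
                        attain = 0
                        new_levels = [0] * n_levels
                        prev = levels[0]
                        lv = prev & ok
                        new_levels[0] = lv
                        attain = lv
                        for b in range(1, n_levels):
                            cur = levels[b]
                            lv = (cur & ok) | (prev & exc)
                            new_levels[b] = lv
                            attain |= lv
                            prev = cur
                        if attain.bit_count() >= t:
                            nxt.append(
                                _State(
                                    pairs + ((gene_w, c),),
                                    tuple(new_levels),
                                    root,
                                    child_ext,
                                    child_closed,
                                )
                            )
            frontier = nxt
            size += 1

    def emit(self, state: _State, size: int) -> ColoredSubnetwork | None:
        """Materialize a frontier state if it meets the per-size budget."""
        opts = self.opts
        if opts.colorful and len({c for _, c in state.pairs}) < 2:
            return None
        budget = min(opts.budget(size), self.max_budget)
        mask = state.support_mask(budget)
        if mask.bit_count() < opts.t:
            return None
        support: dict[str, int] = {}
        for b in range(min(budget, len(state.levels) - 1) + 1):
            lv = state.levels[b]
            while lv:
                low = lv & -lv
                support[self.index.samples[low.bit_length() - 1]] = b
                lv ^= low
        return ColoredSubnetwork(dict(state.pairs), support)


def seed_candidates(
    network: InteractionNetwork,
    cohort: CohortColoring,
    t: int,
    colorful: bool = False,
) -> CandidateSet:
    """Initial candidates of the breadth-first growth.

    Non-colorful mode: one size-1 candidate per (gene, color) pair whose
    support reaches ``t`` (every sample in which the node carries the
    color trivially shares the singleton).  Colorful mode: size-2
    candidates, one per edge with two distinct endpoint colors — a
    complete base case, because every connected colorful subgraph of
    size s >= 3 contains a connected colorful subgraph of size s - 1
    (remove a suitable spanning-tree leaf).
    """
    index = _Index(network, cohort)
    out = CandidateSet()
    if not colorful:
        for (gene, c), ok in sorted(index.proper.items()):
            if ok.bit_count() >= t:
                support = {
                    index.samples[i]: 0
                    for i in range(index.m)
                    if ok >> i & 1
                }
                out.add(ColoredSubnetwork({gene: c}, support))
        return out
    for edge in sorted(tuple(sorted(e)) for e in network.graph.edges):
        u, v = edge
        for cu in index.observed_colors.get(u, ()):
            for cv in index.observed_colors.get(v, ()):
                if cu == cv:
                    continue
                ok = index.proper[(u, cu)] & index.proper[(v, cv)]
                if ok.bit_count() >= t:
                    support = {
                        index.samples[i]: 0
                        for i in range(index.m)
                        if ok >> i & 1
                    }
                    out.add(ColoredSubnetwork({u: cu, v: cv}, support))
    out.sort()
    return out


def extend_candidate(
    T: ColoredSubnetwork,
    u: str,
    color: str,
    network: InteractionNetwork,
    cohort: CohortColoring,
    t: int,
    delta: float = 0.0,
    lenient: bool = False,
) -> ColoredSubnetwork | None:
    """Grow a candidate by one adjacent node; ``None`` when support < t.

    The new support is evaluated at the budget for the *new* size,
    floor(delta * (size + 1)), so a sample excluded at the smaller size
    may enter once the budget grows.
    """
    if u in T.assignment:
        raise ValueError(f"{u} already in the candidate")
    if not any(u in network.neighbors(g) for g in T.assignment):
        raise ValueError(f"{u} is not adjacent to the candidate")
    assignment = {**T.assignment, u: color}
    opts = EnumOptions(t=t, delta=delta, lenient=lenient)
    support = candidate_support(assignment, cohort, opts)
    if len(support) < t:
        return None
    return ColoredSubnetwork(assignment, support)


def enumerate_candidates(
    network: InteractionNetwork,
    cohort: CohortColoring,
    opts: EnumOptions,
) -> CandidateSet:
    """All connected colored subnetworks with size <= k and depth >= t.

    In colorful mode, exactly those with >= 2 distinct assigned colors
    (size >= 2).  Raises :class:`DepthInfeasibleError` when an iteration
    exceeds ``opts.candidate_cap``.
    """
    engine = _Engine(network, cohort, opts)
    out = CandidateSet()
    for size, frontier in engine.frontiers():
        for state in frontier:
            sub = engine.emit(state, size)
            if sub is not None:
                out.add(sub)
    out.sort()
    return out


def max_shared_size(
    network: InteractionNetwork,
    cohort: CohortColoring,
    opts: EnumOptions,
    stop_at: int | None = None,
) -> int:
    """Largest size of any depth->=t candidate, without materializing all.

    With ``stop_at`` the search returns as soon as a candidate of that
    size is confirmed (used by the permutation tests, which only ask
    whether the null reaches the observed size).
    """
    engine = _Engine(network, cohort, opts)
    best = 0
    for size, frontier in engine.frontiers():
        budget = min(opts.budget(size), engine.max_budget)
        for state in frontier:
            if opts.colorful and len({c for _, c in state.pairs}) < 2:
                continue
            if state.support_mask(budget).bit_count() >= opts.t:
                best = size
                break
        if stop_at is not None and best >= stop_at:
            return best
    return best


def candidate_support(
    sub: ColoredSubnetwork | Mapping[str, str],
    cohort: CohortColoring,
    opts: EnumOptions,
) -> dict[str, int]:
    """Recompute a candidate's support from scratch with :func:`shares`."""
    assignment = (
        sub.assignment if isinstance(sub, ColoredSubnetwork) else dict(sub)
    )
    budget = opts.budget(len(assignment))
    support: dict[str, int] = {}
    for sample in cohort.samples:
        ok, om = shares(
            cohort.sample_coloring(sample),
            assignment,
            budget,
            strict=not opts.lenient,
        )
        if ok:
            support[sample] = om  # type: ignore[assignment]
    return support


def prune_non_maximal(
    candidates: CandidateSet,
    network: InteractionNetwork,
    cohort: CohortColoring,
    opts: EnumOptions,
) -> CandidateSet:
    """Drop candidates made redundant by an equally-supported extension.

    A candidate is redundant when some single-node colored extension
    (still within the size bound) is shared by at least as many samples —
    the extension dominates it for the coverage step.  Candidates at the
    size bound are always kept.
    """
    index = _Index(network, cohort)
    out = CandidateSet()
    for sub in candidates:
        if opts.k is not None and sub.size >= opts.k:
            out.add(sub)
            continue
        base_n = len(candidate_support(sub, cohort, opts))
        boundary: set[str] = set()
        for g in sub.assignment:
            boundary.update(network.neighbors(g))
        boundary -= set(sub.assignment)
        redundant = False
        for u in sorted(boundary):
            for c in index.observed_colors.get(u, ()):
                ext = {**sub.assignment, u: c}
                if len(candidate_support(ext, cohort, opts)) >= base_n:
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            out.add(sub)
    return out
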