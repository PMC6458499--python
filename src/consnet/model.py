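"""Core domain types for conserved colored-subnetwork mining.

A tumor cohort is modelled as a single undirected gene/protein interaction
network ``G = (V, E)`` together with one *coloring* per sample: each gene
``j`` in sample ``i`` carries a (possibly empty) set of alteration types
``C[i, j]`` drawn from a small alphabet (somatic mutation, copy-number gain
or loss, expression outlier up/down by default).  A *colored subnetwork* is
a connected subgraph with exactly one color assigned to each node; a sample
*shares* it when every node's assigned color is present in that sample's
color set, up to a tolerated number of uncolored nodes (the error-rate
relaxation).  The number of sharing samples is the subnetwork's *depth*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

#: Default alteration-type alphabet: somatic mutation, copy-number
#: amplification / deletion, expression outlier up / down.
DEFAULT_ALPHABET: tuple[str, ...] = ("MUT", "AMP", "DEL", "UP", "DOWN")

#: Colors treated as copy-number events by the arm-level permutation null.
DEFAULT_CN_COLORS: frozenset[str] = frozenset({"AMP", "DEL"})


class InteractionNetwork:
    """Undirected, simple interaction network over gene symbols.

    Thin wrapper around :class:`networkx.Graph` enforcing the model's
    invariants (no self-loops, no parallel edges, optional edge scores).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = nx.Graph() if graph is None else graph
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            a, b = e[0], e[1]
            if a == b:
                continue
            score = e[2] if len(e) > 2 else None
            if g.has_edge(a, b):
                old = g.edges[a, b].get("score")
                if score is not None and (old is None or score > old):
                    g.edges[a, b]["score"] = score
            else:
                if score is None:
                    g.add_edge(a, b)
                else:
                    g.add_edge(a, b, score=score)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_connected_subset(self, genes: Iterable[str]) -> bool:
        genes = set(genes)
        if not genes:
            return False
        if not genes <= self.nodes:
            return False
        return nx.is_connected(self.graph.subgraph(genes))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"InteractionNetwork(n={self.graph.number_of_nodes()}, "
            f"e={self.graph.number_of_edges()})"
        )


class CohortColoring:
    """Per-sample gene -> color-set mapping over a fixed sample cohort.

    ``colors[(sample, gene)]`` is the set of alteration types observed for
    that gene in that sample; absent keys mean the empty set.
    """

    def __init__(
        self,
        samples: Sequence[str],
        colors: Mapping[tuple[str, str], Iterable[str]],
        alphabet: Sequence[str] = DEFAULT_ALPHABET,
    ):
        self.samples: list[str] = list(samples)
        self.alphabet: list[str] = list(alphabet)
        allowed = set(self.alphabet)
        self.colors: dict[tuple[str, str], frozenset[str]] = {}
        for (sample, gene), cs in colors.items():
            cs = frozenset(cs)
            bad = cs - allowed
            if bad:
                raise ValueError(
                    f"unknown alteration type(s) {sorted(bad)} for "
                    f"({sample}, {gene}); accepted alphabet: {self.alphabet}"
                )
            if cs:
                self.colors[(sample, gene)] = cs
        known = set(self.samples)
        extra = {s for s, _ in self.colors} - known
        if extra:
            raise ValueError(f"colored samples missing from cohort: {sorted(extra)}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str]],
        alphabet: Sequence[str] = DEFAULT_ALPHABET,
        samples: Sequence[str] | None = None,
    ) -> "CohortColoring":
        """Build from deduplicated (sample, gene, alteration) triples."""
        colors: dict[tuple[str, str], set[str]] = {}
        seen: list[str] = []
        for sample, gene, color in records:
            if sample not in seen:
                seen.append(sample)
            colors.setdefault((sample, gene), set()).add(color)
        return cls(samples if samples is not None else seen, colors, alphabet)

    @property
    def m(self) -> int:
        return len(self.samples)

    def color_set(self, sample: str, gene: str) -> frozenset[str]:
        return self.colors.get((sample, gene), frozenset())

    def sample_coloring(self, sample: str) -> dict[str, frozenset[str]]:
        return {g: cs for (s, g), cs in self.colors.items() if s == sample}

    def genes(self) -> set[str]:
        return {g for _, g in self.colors}

    def records(self) -> set[tuple[str, str, str]]:
        return {(s, g, c) for (s, g), cs in self.colors.items() for c in cs}

    def color_counts(self, sample: str) -> dict[str, int]:
        """Number of genes carrying each color in one sample."""
        counts: dict[str, int] = {}
        for (s, _g), cs in self.colors.items():
            if s == sample:
                for c in cs:
                    counts[c] = counts.get(c, 0) + 1
        return counts

    def total_assignments(self, sample: str) -> int:
        """Total color-assignment count of a sample, sum_j |C[i,j]|."""
        return sum(len(cs) for (s, _), cs in self.colors.items() if s == sample)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortColoring):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.colors == other.colors
            and self.alphabet == other.alphabet
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CohortColoring(m={self.m}, assignments={len(self.colors)})"


@dataclass(frozen=True)
class ColoredSubnetwork:
    """A connected node set with one color per node, plus its support.

    ``support`` maps each sharing sample to the number of color omissions
    used for it (0 everywhere when the error rate is 0).
    """

    assignment: Mapping[str, str]
    support: Mapping[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.assignment)

    @property
    def depth(self) -> int:
        return len(self.support)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def canonical_key(self) -> tuple[tuple[str, str], ...]:
        return canonical_key(self.assignment)

    def n_colors(self) -> int:
        return len(set(self.assignment.values()))

    def is_colorful(self) -> bool:
        return self.n_colors() >= 2

    def category(self) -> str:
        """Coarse pattern class: 'colorful' or 'all-<color>'."""
        colors = set(self.assignment.values())
        if len(colors) >= 2:
            return "colorful"
        return f"all-{next(iter(colors))}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = ",".join(f"{g}:{c}" for g, c in sorted(self.assignment.items()))
        return f"ColoredSubnetwork({{{body}}}, depth={self.depth})"


def canonical_key(assignment: Mapping[str, str]) -> tuple[tuple[str, str], ...]:
    """Order-independent identity of a colored subnetwork.

    The lexicographically sorted (gene, color) sequence; two candidates are
    duplicates iff their keys are equal, which makes the breadth-first
    growth enumerate each node-color set exactly once regardless of the
    order in which nodes were added.
    """
    return tuple(sorted(assignment.items()))


@dataclass
class EnumOptions:
    """Parameters of the candidate-subnetwork enumeration.

    t             minimum depth (number of sharing samples), >= 1
    k             maximum subnetwork size; ``None`` = unlimited
    delta         error rate in [0, 1): a sharing sample may leave up to
                  floor(delta * size) nodes uncolored
    colorful      require >= 2 distinct node colors (and hence size >= 2)
    lenient       if True, a tolerated exception node may carry *other*
                  colors; by default it must be uncolored in that sample
    candidate_cap abort threshold on candidates per growth iteration
    """

    t: int = 1
    k: int | None = None
    delta: float = 0.0
    colorful: bool = False
    lenient: bool = False
    candidate_cap: int = 2_000_000

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1 (or None)")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.candidate_cap < 1:
            raise ValueError("candidate_cap must be positive")

    def budget(self, size: int) -> int:
        """Omission budget floor(delta * size) for a given subnetwork size."""
        return int(math.floor(self.delta * size + 1e-9))


def shares(
    sample_coloring: Mapping[str, frozenset[str] | set[str]],
    subnetwork: ColoredSubnetwork | Mapping[str, str],
    max_omissions: int = 0,
    strict: bool = True,
) -> tuple[bool, int | None]:
    """Does a sample share a colored subnetwork, and at how many omissions?

    A node is *matched* when its assigned color is in the sample's color
    set for that gene (membership, never equality — a multi-colored node
    may support any one of its colors).  Up to ``max_omissions`` nodes may
    be exceptions; with ``strict`` (default) an exception node must carry
    no color at all in the sample, otherwise the subnetwork is not shared.
    With ``strict=False`` a miscolored node is also an allowed exception.

    Returns ``(shared, omissions)`` where ``omissions`` is the minimal
    exception count (``None`` when not shared).
    """
    if max_omissions < 0:
        raise ValueError("max_omissions must be >= 0")
    assignment = (
        subnetwork.assignment
        if isinstance(subnetwork, ColoredSubnetwork)
        else subnetwork
    )
    omissions = 0
    for gene, color in assignment.items():
        cs = sample_coloring.get(gene) or frozenset()
        if color in cs:
            continue
        if strict and cs:
            return False, None  # miscolored, not an allowed exception
        omissions += 1
        if omissions > max_omissions:
            return False, None
    return True, omissions
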