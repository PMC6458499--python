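"""Readers and writers for networks, alteration tables and results.

The network reader speaks the STRING edge-list dialect: tab-separated
``geneA geneB [combined_score]`` rows, scores on a 0-1000 scale that are
normalized by division by 1,000 and filtered at a configurable
confidence threshold (0.9 by default), self-loops dropped, duplicate
rows merged keeping the maximum score.  Alteration tables are
three-column TSVs of (sample, gene, alteration-type) triples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import (
    DEFAULT_ALPHABET,
    CohortColoring,
    ColoredSubnetwork,
    InteractionNetwork,
)

logger = logging.getLogger(__name__)


@dataclass
class NetworkFileSpec:
    """How to read an edge-list file.

    score_scale 'raw_0_1000' divides scores by 1,000 before thresholding
    (STRING combined scores); 'already_0_1' takes them as-is.  Without a
    score column no filtering is applied.
    """

    path: str | Path
    score_column_present: bool = True
    score_scale: str = "raw_0_1000"
    min_combined_score: float = 0.9

    def __post_init__(self) -> None:
        if self.score_scale not in {"raw_0_1000", "already_0_1"}:
            raise ValueError("score_scale must be 'raw_0_1000' or 'already_0_1'")
        if not 0.0 <= self.min_combined_score <= 1.0:
            raise ValueError("min_combined_score must lie in [0, 1]")


class ParseError(ValueError):
    pass


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_network(spec: NetworkFileSpec) -> InteractionNetwork:
    """Read a (filtered) undirected simple interaction network.

    Self-loops are discarded; duplicate rows (either orientation) are
    merged keeping the maximum score; edges below the normalized score
    threshold are dropped.  Raises on malformed rows (with the line
    number) and when the filtered network is empty.
    """
    path = Path(spec.path)
    edges: dict[frozenset[str], float | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if spec.score_column_present:
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: missing score column")
                token = fields[2].strip()
                if lineno == 1 and not _is_number(token):
                    continue  # header row, detected by non-numeric score
                if not _is_number(token):
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric score {token!r}"
                    )
                score = float(token)
                if spec.score_scale == "raw_0_1000":
                    score /= 1000.0
            else:
                if lineno == 1 and (a.lower(), b.lower()) in {
                    ("genea", "geneb"),
                    ("gene1", "gene2"),
                }:
                    continue
                score = None
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty gene symbol")
            if a == b:
                continue  # self-loop
            key = frozenset((a, b))
            if score is None:
                edges.setdefault(key, None)
            else:
                old = edges.get(key)
                edges[key] = score if old is None else max(old, score)

    kept: list[tuple[str, str] | tuple[str, str, float]] = []
    for key, score in edges.items():
        a, b = sorted(key)
        if score is None:
            kept.append((a, b))
        elif score >= spec.min_combined_score:
            kept.append((a, b, score))
    net = InteractionNetwork.from_edges(kept)
    if net.number_of_edges() == 0:
        raise ValueError(f"empty network after filtering: {path}")
    return net


def read_alterations(
    path: str | Path,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    network: InteractionNetwork | None = None,
) -> CohortColoring:
    """Read a (sample, gene, alteration) TSV into a cohort coloring.

    Triples are deduplicated; unknown alteration types raise with the
    accepted alphabet.  Genes absent from ``network`` (when given) are
    retained in the data model but logged — downstream enumeration
    ignores them.
    """
    path = Path(path)
    allowed = set(alphabet)
    records: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            sample, gene, color = fields[:3]
            if lineno == 1 and [f.lower() for f in fields[:3]] == [
                "sample",
                "gene",
                "alteration",
            ]:
                continue
            if color not in allowed:
                raise ParseError(
                    f"{path}:{lineno}: unknown alteration type {color!r}; "
                    f"accepted: {sorted(allowed)}"
                )
            records.append((sample, gene, color))
    cohort = CohortColoring.from_records(records, alphabet)
    if network is not None:
        missing = sorted(cohort.genes() - network.nodes)
        if missing:
            logger.warning(
                "%d altered gene(s) absent from the network (ignored "
                "downstream): %s%s",
                len(missing),
                ", ".join(missing[:10]),
                "..." if len(missing) > 10 else "",
            )
    return cohort


def write_alterations(cohort: CohortColoring, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\talteration\n")
        for sample, gene, color in sorted(cohort.records()):
            fh.write(f"{sample}\t{gene}\t{color}\n")


def read_arm_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``gene  arm`` TSV; each gene maps to one arm."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            gene, arm = fields[:2]
            if lineno == 1 and (gene.lower(), arm.lower()) == ("gene", "arm"):
                continue
            if gene in out and out[gene] != arm:
                raise ParseError(
                    f"{path}:{lineno}: gene {gene} mapped to multiple arms"
                )
            out[gene] = arm
    return out


def write_arm_map(arm_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tarm\n")
        for gene, arm in sorted(arm_map.items()):
            fh.write(f"{gene}\t{arm}\n")


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    """Write an edge list on the raw 0-1000 score scale (1000 if unscored)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            score = network.graph.edges[a, b].get("score")
            raw = 1000 if score is None else int(round(score * 1000))
            fh.write(f"{a}\t{b}\t{raw}\n")


def _subnetwork_record(
    sub: ColoredSubnetwork, network: InteractionNetwork | None
) -> dict:
    genes = sorted(sub.assignment)
    edges: list[list[str]] = []
    if network is not None:
        sg = network.graph.subgraph(genes)
        edges = sorted([sorted(e)[0], sorted(e)[1]] for e in sg.edges)
    return {
        "nodes": [[g, sub.assignment[g]] for g in genes],
        "edges": edges,
        "size": sub.size,
        "depth": sub.depth,
        "support": {s: om for s, om in sorted(sub.support.items())},
        "category": sub.category(),
    }


def write_subnetworks(
    solutions: Iterable[ColoredSubnetwork],
    path: str | Path,
    network: InteractionNetwork | None = None,
) -> None:
    """Write solutions as JSON plus a one-row-per-subnetwork TSV summary."""
    path = Path(path)
    solutions = list(solutions)
    payload = {
        "subnetworks": [_subnetwork_record(s, network) for s in solutions]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    tsv = path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("size\tdepth\tcategory\tnodes\tsupport\n")
        for s in solutions:
            nodes = ",".join(f"{g}:{c}" for g, c in sorted(s.assignment.items()))
            supp = ",".join(sorted(s.support))
            fh.write(f"{s.size}\t{s.depth}\t{s.category()}\t{nodes}\t{supp}\n")


def read_subnetworks(path: str | Path) -> list[ColoredSubnetwork]:
    """Inverse of :func:`write_subnetworks` (JSON part)."""
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for rec in payload["subnetworks"]:
        assignment = {g: c for g, c in rec["nodes"]}
        support = {s: int(om) for s, om in rec["support"].items()}
        out.append(ColoredSubnetwork(assignment, support))
    return out
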