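"""Build the background biomolecular knowledge network.

The background graph is assembled from a tab-separated table of binary
molecular interactions in the style of a Pathway Commons export: each
record names two gene symbols, a free-text interaction type, and the list
of source databases that reported the interaction.  An unordered gene pair
becomes an edge of the background network only when the union of source
databases supporting it (across all records and interaction types) reaches
a configurable threshold, two by default — single-database edges are
considered too weakly evidenced.  Self-interactions (protein complexes
reported as A–A) are pruned, redundant records collapse into single edges,
and analysis proceeds on the largest connected component.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "MolecularNetwork",
    "parse_interactions",
    "build_network",
    "largest_component",
    "degree_histogram",
    "write_sif",
]


class InteractionFileError(ValueError):
    """Raised when an interaction table line cannot be parsed."""


@dataclass(frozen=True)
class InteractionRecord:
    """One source-annotated binary interaction between two molecules.

    Parameters
    ----------
    gene_a, gene_b : str
        Gene symbols, kept verbatim (no identifier mapping).
    interaction_type : str
        Free-text relationship label (e.g. ``"INTERACTS_WITH"``).
    sources : frozenset of str
        Names of the source databases reporting this interaction;
        non-empty, deduplicated.
    """

    gene_a: str
    gene_b: str
    interaction_type: str
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("gene symbols must be non-empty strings")
        if not self.sources:
            raise ValueError(
                f"interaction {self.gene_a}-{self.gene_b} has no sources"
            )


@dataclass
class MolecularNetwork:
    """Simple, undirected, unweighted background graph over gene symbols.

    Wraps a :class:`networkx.Graph` whose edges carry two attributes:
    ``sources`` (frozenset of supporting database names) and ``types``
    (frozenset of interaction-type labels, kept only as annotation for
    SIF export — the graph itself is untyped and undirected).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def provenance(self) -> dict[frozenset[str], int]:
        """Per-edge count of distinct supporting source databases."""
        return {
            frozenset((u, v)): len(d.get("sources", frozenset()))
            for u, v, d in self.graph.edges(data=True)
        }

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def parse_interactions(
    path, *, source_delimiter: str = ";"
) -> list[InteractionRecord]:
    """Read a tab-separated interaction table into records.

    Expected columns: ``geneA <tab> geneB <tab> type <tab> sources`` where
    the sources field is a ``source_delimiter``-separated database list.
    A missing fourth column is tolerated (the record then carries the
    single pseudo-source ``"unspecified"``).  Records are returned one per
    line without any merging; self-pairs are retained here and removed by
    :func:`build_network`.

    Raises
    ------
    InteractionFileError
        If a line has fewer than three tab-separated fields.
    """
    records: list[InteractionRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InteractionFileError(
                    f"line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}: {line!r}"
                )
            gene_a, gene_b, itype = fields[0], fields[1], fields[2]
            if len(fields) >= 4 and fields[3].strip():
                sources = frozenset(
                    s.strip()
                    for s in fields[3].split(source_delimiter)
                    if s.strip()
                )
            else:
                sources = frozenset({"unspecified"})
            records.append(InteractionRecord(gene_a, gene_b, itype, sources))
    if not records:
        logger.warning("interaction file %s contained no records", path)
    return records


def build_network(
    records: list[InteractionRecord], min_sources: int = 2
) -> MolecularNetwork:
    """Collapse interaction records into the background network.

    For each unordered gene pair, the union of source databases across
    all of its records (any interaction type) is computed; the pair
    becomes an edge iff that union has at least ``min_sources`` members.
    Self-pairs are discarded.  The result has no self-loops and no
    multi-edges by construction.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    if not records:
        logger.warning("build_network called with no records")
        return MolecularNetwork()

    support: dict[frozenset[str], set[str]] = {}
    types: dict[frozenset[str], set[str]] = {}
    for rec in records:
        if rec.gene_a == rec.gene_b:
            continue  # self-directed edges are pruned
        key = frozenset((rec.gene_a, rec.gene_b))
        support.setdefault(key, set()).update(rec.sources)
        types.setdefault(key, set()).add(rec.interaction_type)

    g = nx.Graph()
    for key, srcs in support.items():
        if len(srcs) >= min_sources:
            u, v = sorted(key)
            g.add_edge(
                u, v, sources=frozenset(srcs), types=frozenset(types[key])
            )
    return MolecularNetwork(g)


def largest_component(net: MolecularNetwork) -> MolecularNetwork:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken by the lexicographically smallest
    member node, so the result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot take largest component of an empty network")
    components = list(nx.connected_components(net.graph))
    top = max(len(c) for c in components)
    chosen = min(
        (c for c in components if len(c) == top), key=lambda c: min(c)
    )
    sub = net.graph.subgraph(chosen).copy()
    return MolecularNetwork(sub)


def degree_histogram(net: MolecularNetwork) -> pd.DataFrame:
    """Degree distribution as a (degree, node count) table.

    Suitable for a log-log degree-distribution plot.  Counts sum to the
    number of nodes.
    """
    if net.n_nodes == 0:
        raise ValueError("degree_histogram of an empty network")
    counts = Counter(d for _, d in net.graph.degree)
    return (
        pd.DataFrame(
            sorted(counts.items()), columns=["degree", "count"]
        ).astype(int)
    )


def write_sif(net: MolecularNetwork, path, *, default_type: str = "pp") -> None:
    """Serialize the network as Cytoscape SIF plus nothing else.

    One line per edge: ``geneA <tab> type <tab> geneB``.  When an edge
    carries several interaction-type annotations the lexicographically
    smallest is written; untyped edges get ``default_type``.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v, d in sorted(net.graph.edges(data=True)):
            t = min(d.get("types", ())) if d.get("types") else default_type
            fh.write(f"{u}\t{t}\t{v}\n")
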