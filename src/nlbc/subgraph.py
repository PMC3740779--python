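"""Shortest-path-union subgraph extraction and Cytoscape export.

The subgraph H connecting an input gene set U is the union, over every
unordered input pair {s, t}, of *all* shortest s-t paths in the
background network: H = union_{s != t in U} SP<s, t>.  H contains exactly
the nodes eligible for nonzero nlBC plus the input endpoints themselves
(which anchor the paths even when their own nlBC is zero), and it does
not depend on the input weights — weights change nlBC values, never
which paths are shortest.

Export targets Cytoscape 2.x plain-text formats: a .sif edge list and
.noa node-attribute files carrying p-value (red colour depth), input
membership and weight (blue borders / border width), and nlBC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .centrality import CentralityTable, InputGeneSet, bfs_shortest_paths
from .network import MolecularNetwork

__all__ = ["ExtractedSubgraph", "extract_subgraph", "export_cytoscape"]


@dataclass
class ExtractedSubgraph:
    """Nodes and edges lying on >=1 shortest path between input pairs."""

    nodes: set[str]
    edges: set[frozenset[str]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def extract_subgraph(
    net: MolecularNetwork, inputs: InputGeneSet
) -> ExtractedSubgraph:
    """Union of all shortest paths between every unordered input pair.

    For each source s in U the BFS predecessor DAG is walked backward
    from each reachable target t in U \\ {s}; every predecessor edge
    visited lies on some shortest s-t path.  Disconnected pairs simply
    contribute nothing.
    """
    nodes: set[str] = set()
    edges: set[frozenset[str]] = set()
    u_nodes = inputs.nodes
    for i, s in enumerate(u_nodes):
        dag = bfs_shortest_paths(net, s)
        targets = [t for t in u_nodes[i + 1 :] if t in dag.dist]
        seen: set[str] = set()
        stack = list(targets)
        nodes.update(targets)
        if targets:
            nodes.add(s)
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            for p in dag.preds[v]:
                edges.add(frozenset((p, v)))
                nodes.add(p)
                if p not in seen:
                    stack.append(p)
    return ExtractedSubgraph(nodes=nodes, edges=edges)


def export_cytoscape(
    sub: ExtractedSubgraph,
    results: pd.DataFrame,
    inputs: InputGeneSet,
    prefix,
    *,
    net: MolecularNetwork | None = None,
    centrality: CentralityTable | None = None,
    default_type: str = "pp",
) -> list[Path]:
    """Write ``prefix.sif`` plus node-attribute ``.noa`` files for H.

    The .sif holds one space-delimited ``geneA type geneB`` line per edge
    of H; the interaction type comes from the background network's edge
    annotation when available, else ``default_type``.  Four .noa files
    are written: simulated p-value (nodes absent from the result table
    default to 1.0), input-membership flag, input weight (0 for
    non-input nodes) and nlBC.  Returns the written paths.
    """
    if not sub.nodes:
        raise ValueError("extracted subgraph is empty; nothing to export")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    sif_path = prefix.with_suffix(".sif")
    with open(sif_path, "wt", encoding="utf-8") as fh:
        for edge in sorted(tuple(sorted(e)) for e in sub.edges):
            u, v = edge
            etype = default_type
            if net is not None and net.graph.has_edge(u, v):
                types = net.graph.edges[u, v].get("types")
                if types:
                    etype = min(types)
            fh.write(f"{u} {etype} {v}\n")

    pvals = dict(zip(results["gene"], results["p_value"]))
    nlbc_lookup: dict[str, float] = {}
    if centrality is not None:
        nlbc_lookup = centrality.values
    elif "nlBC" in results:
        nlbc_lookup = dict(zip(results["gene"], results["nlBC"]))

    attrs: dict[str, dict[str, object]] = {
        "Pvalue": {g: pvals.get(g, 1.0) for g in sub.nodes},
        "InInput": {g: int(g in inputs.weights) for g in sub.nodes},
        "Weight": {g: inputs.weights.get(g, 0.0) for g in sub.nodes},
        "nlBC": {g: nlbc_lookup.get(g, 0.0) for g in sub.nodes},
    }
    written = [sif_path]
    for name, mapping in attrs.items():
        path = prefix.parent / f"{prefix.name}_{name.lower()}.noa"
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"{name}\n")
            for g in sorted(mapping):
                fh.write(f"{g} = {mapping[g]}\n")
        written.append(path)
    return written


def read_sif(path) -> set[frozenset[str]]:
    """Parse a space-delimited SIF file back into its edge set."""
    edges: set[frozenset[str]] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 3:
                edges.add(frozenset((parts[0], parts[2])))
    return edges
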