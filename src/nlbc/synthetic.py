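"""Synthetic interaction tables and gene lists for end-to-end testing.

Real biomolecular knowledge networks are scale-free: a few hub proteins
carry a large share of all edges.  The generator emulates that with a
preferential-attachment (Barabasi-Albert) background, then plants a
signalling motif on top of it:

* ``ligand`` nodes attached ONLY to receptor nodes,
* ``receptor`` nodes bridging ligands to transcription factors, and
* ``TF`` nodes drawn from existing well-connected background nodes.

The input gene list is the ligands plus the TFs (uniform weight 1.0 by
default); the receptors are the planted "hidden keys": every ligand-TF
shortest path must cross one, so they accumulate large nlBC despite
having far fewer neighbours than the background hubs.  The default motif
sizes (10 ligands, 4 receptors, 30 TFs) mirror the scale of a
ligand/transcription-factor pathway analysis where the receptor layer is
the recoverable answer.  Optional extra random edges per receptor
(``bridge_extra_degree``) stop the receptors from being trivially
identifiable low-degree pendants.

Every record is stamped with two synthetic source databases so the
planted structure survives the default two-source evidence filter.
All randomness flows from the single spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import InteractionRecord

__all__ = ["SyntheticPathwaySpec", "generate_background", "plant_pathway"]

_SOURCES = frozenset({"SynthDB-A", "SynthDB-B"})


@dataclass
class SyntheticPathwaySpec:
    """Parameters of the synthetic pathway instance.

    n_background : background node count (scale-free graph).
    attachment : edges per new node in preferential attachment.
    n_ligands, n_receptors, n_tfs : planted motif sizes.
    bridge_extra_degree : extra random background edges per receptor.
    seed : master seed; fixes the instance bit-for-bit.
    """

    n_background: int = 600
    attachment: int = 3
    n_ligands: int = 10
    n_receptors: int = 4
    n_tfs: int = 30
    bridge_extra_degree: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_background": self.n_background,
            "attachment": self.attachment,
            "n_ligands": self.n_ligands,
            "n_receptors": self.n_receptors,
            "n_tfs": self.n_tfs,
        }
        bad = {k: v for k, v in counts.items() if v < 1}
        if bad:
            raise ValueError(f"counts must be positive: {bad}")
        if self.attachment >= self.n_background:
            raise ValueError("attachment must be < n_background")
        if self.n_background < self.n_ligands + self.n_receptors + self.n_tfs:
            raise ValueError(
                "background too small for the planted motif sizes"
            )


def _node_name(i: int) -> str:
    return f"BG{i:05d}"


def generate_background(spec: SyntheticPathwaySpec) -> list[InteractionRecord]:
    """Scale-free background network as interaction records.

    Barabasi-Albert preferential attachment (connected by construction),
    each edge stamped with two synthetic sources so it passes the
    default min_sources=2 filter unchanged.  Reproducible from the spec
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    g = nx.barabasi_albert_graph(
        spec.n_background,
        spec.attachment,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    records = [
        InteractionRecord(
            _node_name(u), _node_name(v), "INTERACTS_WITH", _SOURCES
        )
        for u, v in sorted(g.edges)
    ]
    return records


def plant_pathway(
    records: list[InteractionRecord], spec: SyntheticPathwaySpec
) -> tuple[list[InteractionRecord], dict[str, float], list[str]]:
    """Plant the ligand->receptor->TF motif onto a background.

    Returns ``(records', input_weights, planted_keys)``: the augmented
    record list, the ligand+TF input list with uniform weight 1.0, and
    the receptor symbols (the ground truth the method should recover).

    TFs are sampled from the higher-degree half of the background so
    that ligand-TF paths must thread the planted bridges through a
    realistic hub tangle; receptors additionally get
    ``bridge_extra_degree`` random background edges each, keeping them
    connected but far below hub degree.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    degree: dict[str, int] = {}
    background_nodes: set[str] = set()
    for rec in records:
        for g in (rec.gene_a, rec.gene_b):
            degree[g] = degree.get(g, 0) + 1
            background_nodes.add(g)
    if len(background_nodes) < spec.n_tfs + spec.bridge_extra_degree:
        raise ValueError("background inconsistent with motif spec")

    ranked = sorted(background_nodes, key=lambda g: (-degree[g], g))
    upper_half = ranked[: max(spec.n_tfs, len(ranked) // 2)]
    tfs = sorted(
        str(x) for x in rng.choice(upper_half, size=spec.n_tfs, replace=False)
    )

    ligands = [f"LIG{i:03d}" for i in range(spec.n_ligands)]
    receptors = [f"REC{i:03d}" for i in range(spec.n_receptors)]

    out = list(records)

    def add(a: str, b: str, kind: str) -> None:
        out.append(InteractionRecord(a, b, kind, _SOURCES))

    # ligands attach ONLY to receptors (>=1 each, random subset)
    for lig in ligands:
        n_links = int(rng.integers(1, spec.n_receptors + 1))
        chosen = rng.choice(receptors, size=n_links, replace=False)
        for rec_node in sorted(str(x) for x in chosen):
            add(lig, rec_node, "LIGAND_RECEPTOR")

    # every receptor reaches several TFs so each ligand-TF pair is bridged
    n_tf_links = max(2, spec.n_tfs // spec.n_receptors)
    for rec_node in receptors:
        chosen = rng.choice(tfs, size=min(n_tf_links, spec.n_tfs), replace=False)
        for tf in sorted(str(x) for x in chosen):
            add(rec_node, tf, "SIGNALS_TO")

    # extra random background edges keep receptors non-pendant
    non_tf = sorted(background_nodes - set(tfs))
    for rec_node in receptors:
        chosen = rng.choice(non_tf, size=spec.bridge_extra_degree, replace=False)
        for other in sorted(str(x) for x in chosen):
            add(rec_node, other, "INTERACTS_WITH")

    input_weights = {g: 1.0 for g in ligands + tfs}
    return out, input_weights, receptors


def write_instance(
    spec: SyntheticPathwaySpec, interactions_path, genelist_path, key_path
) -> None:
    """Write one synthetic instance to disk: table, gene list, answer key."""
    records, weights, keys = plant_pathway(generate_background(spec), spec)
    with open(interactions_path, "wt", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                f"{rec.gene_a}\t{rec.gene_b}\t{rec.interaction_type}\t"
                + ";".join(sorted(rec.sources))
                + "\n"
            )
    with open(genelist_path, "wt", encoding="utf-8") as fh:
        for g, w in weights.items():
            fh.write(f"{g}\t{w}\n")
    with open(key_path, "wt", encoding="utf-8") as fh:
        json.dump(
            {"planted_keys": keys, "spec": vars(spec)}, fh, indent=2
        )
        fh.write("\n")
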