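# Methods

## Background network model

The knowledge network is a simple, undirected, unweighted graph over
gene symbols.  It is built from a tab-separated table of binary
interactions, each annotated with the source databases that report it.
An unordered gene pair becomes an edge iff the **union** of source names
across all of its records — pooling interaction types and ignoring
direction — contains at least `min_sources` distinct databases
(default 2).  The union rule, rather than a record count, reflects the
intent of multi-database evidence filtering: two records from the same
database are one piece of evidence.  Self-interactions are pruned
(shortest paths never use them) and redundant records collapse into
single edges.  Analysis runs on the largest connected component; a size
tie is broken by the lexicographically smallest member so the result is
deterministic.  Gene symbols are taken verbatim; identifier mapping
(HGNC/UniProt reconciliation) is out of scope.

When the same pair appears under different interaction types in
different databases, the sources are pooled across types.  The
interaction type survives only as an edge annotation for SIF export.

## Node-limited betweenness centrality

With input set `U` and positive weights `w(x)`:

```
nlBC(v) = (1/w) Σ_{ {s,t}⊆U, s≠t } (w(s)+w(t)) σ_st(v)/σ_st,
      w = Σ_{ {s,t}⊆U, s≠t } (w(s)+w(t)) = (|U|−1) Σ_{x∈U} w(x)
```

Conventions, and why:

* **Interior-only counting.**  `v` is credited only when `v ∉ {s,t}`,
  exactly as in classical betweenness.  Input nodes can still score
  through paths between *other* input pairs; endpoint-inclusive counting
  would push every input node toward 1 and destroy the ranking.
* **Unordered pairs.**  On an undirected graph, ordered summation is an
  exact factor of two in both numerator and normalizer; the unordered
  form is fixed as the canonical contract.
* **Hop-count shortest paths.**  The background graph is unweighted, so
  breadth-first search is exact; path counts are accumulated in floating
  point (they are exact integers well below 2^53 at these graph sizes).
* **Disconnected input pairs** contribute zero to the numerator while
  their `(w(s)+w(t))` term still counts in `w`.  This only matters if
  the caller bypasses the largest-component step; the normalizer then
  still has the closed form above.
* **Unmapped input symbols** are dropped with a logged warning and
  recorded, not raised — real gene lists always contain symbols absent
  from the network.  At least two mapped nodes are required.

Useful identities, all enforced by tests: values lie in `[0,1]`;
rescaling all weights leaves every value unchanged; uniform weights
reduce nlBC to the pair-averaged endpoint-restricted betweenness;
`U = V` with uniform weights gives `nlBC(v) = BC(v)/C(|V|,2)` and the
same ranking as classical betweenness; as one weight `w(s) → ∞` the
value tends to the average single-source dependency
`(1/(|U|−1)) Σ_{t∈U∖{s}} σ_st(v)/σ_st` (checked numerically at 10⁶).

### Implementation

One Brandes-style backward accumulation per source `s ∈ U`, restricted
to targets in `U∖{s}`.  Because the accumulation is linear in the
per-target weights, the source term `w(s)·δ¹` and the target term `δ^w`
collapse into a single pass that carries the pair weight `w(s)+w(t)`
directly.  All `|U|` sources advance in lockstep as columns of dense
`(nodes × |U|)` matrices driven by sparse adjacency products (BFS level
by level forward, then level by level backward), which makes one full
nlBC evaluation a few milliseconds on a ~600-node network and keeps the
Monte-Carlo loop tractable in pure numpy/scipy.  A literal
path-enumeration oracle (`brute_force_nlbc`, guarded to ≤200 nodes)
defines the ground truth in tests; the two agree to ~1e-16 on hundreds
of random instances.

## Simulated p-values

Null model: the input list carries no information, so `|U|` nodes are
drawn uniformly **without replacement** from all network nodes (no
degree matching — the null is "a random gene list of the same size and
weight profile") and the original weight multiset is permuted over them.
Each node `v` is compared against its *own* replicate distribution:
`r(v)` counts replicates with replicate-nlBC(v) ≥ observed-nlBC(v), and

```
P_v = (r + 1) / (n + 1),   n = 20,000 by default.
```

The minimum attainable p-value is `1/(n+1)`; p-values are never zero.
Only nodes with observed nlBC > 0 are tracked — every replicate value is
≥ 0, so zero-centrality nodes have `P_v = 1` by construction.  Counters
update streamingly; full replicate samples are retained only on request
(for diagnostic boxplots), keeping memory at one counter per tracked
node.  One master seed spawns an independent substream per replicate
(`numpy.random.SeedSequence.spawn`), so results are bit-for-bit
reproducible and independent of any execution order.  No
multiple-testing correction is applied; the result table thresholds raw
simulated p-values (strictly below α, default 0.05; α = 1 emits every
tracked node), sorted by p-value with ties broken by descending nlBC
then gene symbol.  The degree column reports degree in the background
network, not the extracted subgraph.

A note on calibration: the simulated p-value is marginally valid —
under the null, `P(P_v ≤ α) ≤ α` for every node, and the measured
all-node rejection rate at α = 0.05 is ≈ 0.04 (slightly conservative,
as expected for a discrete statistic with an atom at nlBC = 0).  The
rejection rate *among tracked nodes only* is much larger than α, because
tracking conditions on nlBC > 0, which is itself a rare event under the
null; that conditional rate is a property of any correct implementation,
not an inflation of the test.

## Subgraph extraction and export

The subgraph `H` connecting the inputs is the union over all unordered
input pairs of *all* their shortest paths, computed by walking each
source's BFS predecessor DAG backward from every reachable target.  `H`
contains exactly the nodes eligible for nonzero nlBC plus the input
endpoints themselves (they anchor the paths even at nlBC 0), and it is
invariant to the input weights — weights move values, never which paths
are shortest.  Export writes Cytoscape 2.x plain-text formats: a
space-delimited `.sif` (`geneA type geneB`, type `pp` when the edge
annotation lacks one) and four `.noa` node-attribute files (simulated
p-value, defaulting to 1.0 for nodes absent from the result table; input
membership; input weight, 0 for non-inputs; nlBC), each a header line
followed by `node = value` lines.

## Synthetic pathway fixture

The generator emulates the geometry of a ligand/receptor/transcription-
factor pathway inside a scale-free interactome:

* **Background**: Barabási–Albert preferential attachment,
  `n_background = 600` nodes, `attachment = 3` edges per node —
  a desk-scale stand-in for a filtered multi-database interactome, with
  the heavy-tailed degree distribution the method's hub-avoidance claim
  depends on.  Every record carries two synthetic source names so the
  default evidence filter passes it unchanged.
* **Motif**: 10 ligand nodes attached *only* to 4 receptor nodes;
  receptors wired to transcription factors drawn from the well-connected
  half of the background (so ligand–TF paths thread the receptors into a
  realistic hub tangle); 30 TFs.  The input list is the ligands plus the
  TFs at uniform weight 1.0; the receptors are the planted ground truth.
  Each receptor also gets 3 extra random background edges
  (`bridge_extra_degree`) so it is not a trivially identifiable pendant.
  Motif sizes mirror a ligand/TF pathway analysis in which the receptor
  layer is the recoverable answer.
* All randomness flows from the single spec seed; instances are
  byte-identical across runs.

What the fixture does **not** emulate: literature bias in edge coverage,
identifier noise, weight distributions shaped like real mutation
frequencies, or the modular/clustered structure of real interactomes.
Passing the recovery test therefore shows the statistic and its null are
implemented correctly and behave as designed on scale-free topology —
not that any particular biological discovery is guaranteed.

## Problem sizes used in checks

Oracle equivalence runs 200 random connected graphs of ≤30 nodes with
2–8 weighted inputs.  Calibration uses a 150-node background, 6 random
inputs, 1,000 replicates × 20 trials.  Planted-key recovery uses the
default 600-node fixture over 20 generator seeds at 1,000 replicates —
sizes chosen so the whole battery runs in a few minutes on one CPU while
keeping binomial noise on the measured rates small; the 20,000-replicate
default is reserved for real analyses.

## Known limitations

* Betweenness is exact, not sampled; very large networks (≫10⁵ edges)
  with large input lists will be slow in the Monte-Carlo loop.
* The null ignores degree: significance partly reflects a node's
  topological position, and degree-matched permutation nulls are a
  possible extension.
* Directed or edge-weighted interactions are deliberately unsupported;
  the model treats the interactome as evidence of connectivity only.
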