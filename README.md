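# clonecent

Clone temporal centrality measures for incomplete sequences of graph
snapshots, with a linear-in-time reversed-sweep shortest-temporal-path
engine, a dynamic-network simulator and an evaluation harness for rank
robustness under missing observations.

## The problem

Dynamic networks — gene co-expression across ages, contact networks,
spreading processes — are commonly recorded as an ordered sequence of
static *snapshots* 𝒢 = G₁, …, G_S over a fixed vertex set. Temporal
centralities rank vertices by **shortest temporal paths**: walks through
the sequence that make exactly one move per snapshot, either a *hop* along
an edge of the current snapshot or a *halt* on the current vertex. A path
starting at snapshot k and first reaching its destination at snapshot m
has length m − k + 1, and σ_{k,m,S}(a,c) counts the distinct hop/halt
combinations achieving the minimal arrival. Temporal betweenness sums, per
start snapshot and ordered vertex pair, the fraction of shortest paths
that pass through a vertex b:

    TBC(b) = Σ_{k=1}^{S−1} Σ_{(a,c): σ_{k,m,S}(a,c)>0}
             σ_{k,m,S}(a,b,c) / σ_{k,m,S}(a,c)

In practice the snapshot sequence is **incomplete**: edges arise and
vanish between observations, so durations and orderings are masked and
temporal paths go missing (or get mis-declared shortest). The *clone*
variants CTBC/CTCC compensate by inserting copies of observed snapshots —
e.g. one clone per known unobserved time point — and evaluating the same
measure on the lengthened sequence. With zero added clones the clone
measures equal the originals exactly.

Shortest-path search uses a reversed sweep over the snapshots (one
backward pass per destination vertex) that finds earliest arrivals,
shortest-path counts and the shortest-path DAG for *all* start snapshots
simultaneously, so the cost is linear in S (overall O(S·|V|³) for a full
betweenness) and the method stays practical for heavily cloned sequences.

## Worked example

Four vertices; the observed sequence has E₁ = {A–C}, E₂ = {A–D, B–D} and
an empty E₃. There is no temporal path from A to B: B's only edge (B–D)
lies in the same snapshot as A–D, so the order of those two edges is
masked.

```python
from clonecent import (GraphSequence, path_census, tbc, ctbc, plan_from_gaps)

seq = GraphSequence("ABCD", [{("A", "C")}, {("A", "D"), ("B", "D")}, set()])
print(tbc(path_census(seq)).to_frame().to_string(index=False))
```

```
vertex  value  rank
     A    1.0   1.0
     B    0.0   3.0
     C    0.0   3.0
     D    0.0   3.0
```

A's single unit of betweenness comes from the one shortest path C→A→D;
D mediates nothing because no path through D is observable. If the three
snapshots were taken at known time points 1, 3, 5 of a five-step horizon,
gap-based cloning inserts one copy after each of the first two snapshots
(copy counts (2, 2, 1)):

```python
plan = plan_from_gaps([1, 3, 5], horizon=5)
print(ctbc(seq, plan).to_frame().to_string(index=False))
```

```
vertex  value  rank
     A    4.0   2.0
     B    0.0   4.0
     C    1.0   3.0
     D    8.0   1.0
```

The cloned columns let paths such as A→D→B and C→A→D→B complete, and D —
the vertex that actually connects the two halves of the little network —
now ranks first. This is the qualitative effect the clone measures exist
for: recovering the importance of connector vertices whose paths are
invisible in the raw incomplete sequence.

The same operations are available from a shell:

```sh
clonecent --seed 7 simulate --n-vertices 50 --snapshots 100 --lifetime 6 -o gin.tsv
clonecent centrality gin.tsv --measure tbc -o tbc.csv
clonecent centrality gin.tsv --measure ctbc --n-clones 2 -o ctbc.csv
clonecent sample gin.tsv --alpha 0.3 -o sub.tsv --positions-out pos.csv
clonecent evaluate --config grid.cfg --out-prefix results
```

`simulate` implements the group-infection-network model: M subgraphs, a
baseline edge probability τ plus a rich-get-richer term D(a)/|E^(m)|,
bridge vertices that link consecutive subgraphs every κ snapshots, and a
fixed edge lifetime λ. The `evaluate` grid reproduces the incompleteness
experiment: simulate, compute true ranks on the full sequence, subsample
to a rate α, re-estimate with and without cloning, and score with
Spearman's ρ, top-vertex detection rate and absolute rank differences.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance target from scratch: it simulates a
fully observed GIN (|V| = 200, 10 subgraphs, 50 snapshots, τ = 0.0125,
κ = 8, λ = 1), computes temporal betweenness and its clone variant with
zero added clones, assigns tie-averaged ranks to both, and writes the
Spearman rank correlation between the two rank vectors as JSON.

## Layout

- `temporal_graph` — snapshot sequences, directed time graph, path
  validation, exhaustive enumeration oracle (the correctness reference).
- `ren` — the reversed sweep: arrival tables, shortest-path counts,
  pass-through counting on the shortest-path DAG.
- `cloning` — clone plans (fixed, gap-based, path-closure) and cloned
  sequence materialisation.
- `centrality` — TBC/TCC and the clone variants CTBC/CTCC.
- `gin_sim` — the group infection network simulator.
- `evaluation` — subsampling, rank metrics, the experiment grid runner.
- `io_cli` — snapshot edge-list format, event aggregation, the CLI.

See `docs/methods.md` for the model conventions, parameter meanings and
known limitations.
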