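# Methods

This note records the model conventions, algorithmic choices and
limitations behind `clonecent`. Everything stated here is exercised by the
test suite; no empirical claim is made that the tests or the acceptance
script do not themselves compute.

## Temporal paths and the census

A snapshot sequence 𝒢 = G₁…G_S over a fixed vertex set V unrolls into a
directed time graph: vertex occurrences (v, 0)…(v, S), and per column k a
halt arc (v, k−1)→(v, k) for every vertex plus hop arcs for the edges of
E_k (both orientations when undirected). A temporal path makes exactly one
move per column; a path from a (start snapshot k) to c (arrival m) has
length m − k + 1 and occupies occurrence indices k−1 … m. Paths terminate
at their *first* arrival at the destination, so a destination never
appears as an intermediate of its own shortest paths. σ counts distinct
hop/halt combinations with minimal arrival.

**Intermediate-vertex convention.** A shortest path ⟨a_{k−1}, …, c_m⟩
passes b iff b occurs at an index in {k, …, m−1}: the start occurrence is
excluded, the first-hop landing and the last pre-arrival occurrence are
included, and a path counts at most once per b regardless of halts or
revisits. The alternative strictly-interior reading (excluding index k)
would make length-2 paths contribute nothing to any betweenness, which
contradicts the worked example where the middle vertex of C→A→D carries
the entire betweenness; the chosen convention reproduces that example and
the cloned-sequence values (CTBC(D)=8, CTBC(A)=4) exactly.

**Ordered pairs.** Betweenness sums run over ordered pairs (a, c), a ≠ c,
since temporal reachability is asymmetric in time even for undirected
edges.

## The reversed sweep

One backward pass per destination c (columns S → 1) computes for every
(source a, start k): earliest arrival m(a, k), shortest-path count
σ(a, k), and the successor moves attaining the minimum:

- direct edge a–c in E_k: m = k, σ = 1, no expansion (the unique length-1
  path; this skip is why dense sequences are cheap);
- otherwise m(a, k) = min(m(a, k+1), min over hop targets b ∈ N_k(a)\{c}
  of m(b, k+1)), σ summing over all moves that attain the minimum.

The sweep always continues down to snapshot 1, otherwise paths starting
early would be missed. Storing per-(vertex, column) labels instead of
explicit paths keeps space at O(S·|E| + S·|V|²); paths are materialised
only on demand (`ArrivalTable.extract_paths`), which the tests use to
check that the successor DAG reproduces the exhaustive enumeration
exactly.

**Pass-through counting.** The number of shortest paths from (a, k)
passing b is computed as σ(a, k) minus the number of DAG paths that avoid
b entirely. The avoidance table rolls backwards as a (vertex × avoided-b)
matrix with the recorded successor moves, the diagonal forced to zero
("standing on b is a visit"). This counts each path once per distinct
intermediate vertex — halting on b twice, or leaving and re-entering b,
never double counts — and is verified elementwise against the brute-force
oracle on 300 random instances, directed and undirected.

**Counts as floats.** σ is held in float64. Counts are exact integers up
to 2⁵³; beyond that (astronomically many parallel hop/halt combinations)
the betweenness ratios degrade gracefully in precision. All oracle
comparisons run at scales where the counts are exact.

## Cloning

A clone plan assigns each snapshot a total copy count J_k ≥ 1; copies are
contiguous and placed immediately after the original (forward persistence
of observed edges). Cloning can only add paths — halting through inserted
copies preserves every original path — so reachability never degrades.
Three strategies:

- `plan_fixed(n_c)`: J_k = n_c + 1 everywhere (the excess-of-cloning
  design);
- `plan_from_gaps(positions, horizon)`: as many clones as unobserved time
  points before the next observation, with a trailing fill to the horizon
  (the comparison truth lives on the full horizon) and no leading fill
  (nothing is known before the first observation);
- `plan_path_closure(cap)`: J_k = 1 + min(cap, |V|−1, |E_{k−1} ∪ E_k|), a
  sufficient copy count for walking any static path of the two-snapshot
  union as a temporal path under block ordering (a path of L edges needs
  at most L columns). Interleaved clone orderings, which could realise
  some alternating-edge static paths with fewer copies, are not
  implemented.

CTBC/CTCC are the base measures evaluated on the cloned sequence; the
(snapshot, copy, pair) triple-sum formulation enumerates exactly the
cloned sequence's start positions, and the identity plan reproduces
TBC/TCC elementwise (asserted as the n_c = 0 identity, ρ = 1).

**Closeness convention.** The reference formulation of the closeness
variant was not available, so TCC is implemented as
Σ_k Σ_{c reachable} 1/(m − k + 1) with start snapshots 1…S and
unreachable pairs contributing zero. It is labelled a convention; only
qualitative comparisons to published closeness results are meaningful.

## The GIN simulator

`simulate_gin` draws an undirected group infection network:
|V| vertices in M equal subgraphs, S snapshots, baseline edge probability
τ, bridge interval κ, edge lifetime λ (defaults 10 subgraphs, S = 100,
τ = 0.0125, κ = 8 — the published experimental conditions).

- Snapshot 1: a uniformly chosen seed in subgraph 1 draws an edge to each
  subgraph peer independently with probability τ.
- Snapshots k ≥ 2: every active vertex a proposes an edge to each
  currently non-adjacent peer of its own subgraph with probability
  p = min(1, τ + D(a)/|E^(m)|), degrees and edge counts frozen at the
  snapshot start (iteration order cannot matter). *Active* means ever
  incident to an edge, plus the seed and bridge targets: a literal
  currently-connected reading would extinguish nearly every realisation
  right after snapshot 1 when λ is small (an infected vertex stays
  infectious). By default both endpoints of an active pair propose
  independently (two chances per snapshot); `pair_proposals="per-pair"`
  draws once per pair with the stronger endpoint's probability.
- Bridging: after κ·m snapshots (while κ·m < S) a uniformly chosen
  *ever-connected* vertex of subgraph m becomes the bridge and creates
  exactly one edge to a uniform vertex of subgraph m+1 at the next
  snapshot. If the subgraph is still edgeless when its slot comes up the
  event defers to the first snapshot with a connected vertex (with τ = 0
  nothing ever connects and no bridging occurs). Only bridge edges ever
  cross subgraphs.
- Every created edge lives exactly λ consecutive snapshots; re-proposal
  of a live edge is a no-op (no refresh), re-creation after expiry is
  allowed. The degree term uses the vertex's full current degree
  (including a bridge's single cross edge); the subgraph edge count
  |E^(m)| is intra-subgraph.

What the generator does **not** emulate: directed dynamics (the engine
supports directed sequences, the simulator does not generate them),
heavy-tailed edge-duration mixtures, permanent edges, or any
vertex-attribute structure of real co-expression networks. A green
experiment on GINs therefore establishes rank-recovery behaviour under
the stated mechanism, not performance on any particular real network.

## Evaluation harness

Ranks are descending with ties averaged (rank 1 = most central); ρ is the
Pearson correlation of tie-averaged rank vectors (cross-checked against
an independent implementation in the tests) and is reported missing when
a rank vector has zero variance. Detection counts a replicate as a hit
when the estimated maximal-value set intersects the true one (the tie
rule at rank 1 is otherwise unspecified). Random subsampling retains
round(α·S) snapshots uniformly without replacement, order preserved;
systematic thinning keeps every j-th snapshot with default offset j
(37 snapshots at step 4 → nine retained). `run_experiment` derives every
random stream from (seed, lifetime, replicate) via `SeedSequence`, so
grids are bit-reproducible and embarrassingly restartable.

## Numerical and degenerate-input choices

- Unreachable arrivals use the sentinel −1; σ = 0 iff unreachable.
- Single-snapshot sequences have zero betweenness (the outer sum is
  empty); empty snapshots yield zero everywhere.
- The enumeration oracle is guarded by an expansion budget (default
  5·10⁵ nodes, cumulative across a census) and is intended for |V| ≤ ~8,
  S ≤ ~7.
- The edge-probability term uses 0/0 → 0 in an edgeless subgraph.
- On-disk snapshot indices are 1-based; aggregation windows are
  half-open [(k−1)w, kw), and an interval event contributes to every
  window it intersects.

## Known limitations

- Excess cloning biases the clone measures by construction; the harness
  quantifies the effect (ρ decays with n_c) rather than correcting it.
- Cloning cannot recover edges that were never observed, only masked
  durations/orderings.
- No probabilistic interpolation between snapshots; clone counts are
  deterministic functions of the observation pattern.
- The per-pair proposal mode is a documented variant, not a calibrated
  alternative model.
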