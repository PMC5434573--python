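"""Group infection network (GIN) simulator.

A GIN is a dynamic network of M disjoint subgraphs over |V| vertices
(|V| divisible by M) evolving over S snapshots:

* the process starts from a single randomly chosen seed vertex in
  subgraph 1; at snapshot 1 the seed draws an edge to every other vertex of
  its subgraph independently;
* from snapshot 2 on, every *active* vertex proposes a new edge to each
  currently non-adjacent vertex of its own subgraph with probability
  ``p = min(1, tau + D(a)/|E^(m)|)`` - a baseline rate plus a
  rich-get-richer term based on the proposer's degree and the subgraph's
  edge count, both frozen at the snapshot start (so iteration order cannot
  matter);
* after kappa*m snapshots (m = 1..M-1, while kappa*m < S) a connected
  vertex of subgraph m is chosen as *bridge*; at the next snapshot it
  builds exactly one edge to a uniformly chosen vertex of subgraph m+1,
  which becomes that subgraph's first active vertex.  Only bridge vertices
  ever carry cross-subgraph edges.  A bridge must be a vertex that has
  actually carried an edge; if the subgraph is still edgeless when its
  slot comes up, the bridging defers to the first later snapshot with a
  connected vertex (and never happens when tau = 0);
* every created edge persists exactly ``lambda`` consecutive snapshots
  (creation snapshot included) and then vanishes; re-proposing an existing
  edge is a no-op (no lifetime refresh) and re-creation after expiry is
  allowed.

"Active" means *ever* incident to an edge, plus the initial seed and each
bridge target: with short lifetimes a literal "currently has an edge"
reading would extinguish almost every realisation right after snapshot 1,
which contradicts the model's published dynamics (an infected vertex stays
infectious).  Vertex labels are zero-padded strings ``v00..`` so that disk
round-trips preserve order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .temporal_graph import GraphSequence

__all__ = ["GINParams", "edge_probability", "simulate_gin"]


@dataclass(frozen=True)
class GINParams:
    """Parameters of a dynamic GIN.

    ``tau`` is the baseline edge probability, ``bridge_interval`` the
    number of snapshots (kappa) between subgraph bridgings, and
    ``edge_lifetime`` (lambda) the number of consecutive snapshots a
    created edge persists.  ``pair_proposals`` selects whether each active
    vertex proposes independently ("per-vertex", the default: a pair with
    two active endpoints gets two chances per snapshot) or each pair is
    drawn once with the stronger endpoint's probability ("per-pair").
    """

    n_vertices: int
    n_subgraphs: int = 10
    n_snapshots: int = 100
    tau: float = 0.0125
    bridge_interval: int = 8
    edge_lifetime: int = 1
    seed: int | None = None
    pair_proposals: str = "per-vertex"

    def __post_init__(self):
        if self.n_vertices < 1 or self.n_subgraphs < 1:
            raise ValueError("need at least one vertex and one subgraph")
        if self.n_vertices % self.n_subgraphs:
            raise ValueError("|V| must be divisible by the number of subgraphs")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be a probability")
        if self.bridge_interval < 1 or self.edge_lifetime < 1:
            raise ValueError("kappa and lambda must be positive integers")
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")
        if self.pair_proposals not in ("per-vertex", "per-pair"):
            raise ValueError("pair_proposals must be 'per-vertex' or 'per-pair'")
        if self.bridge_interval * (self.n_subgraphs - 1) >= self.n_snapshots:
            warnings.warn(
                "kappa*(M-1) >= S: not every subgraph will be bridged",
                stacklevel=2,
            )

    @property
    def subgraph_size(self) -> int:
        return self.n_vertices // self.n_subgraphs


def edge_probability(degree: int, n_subgraph_edges: int, tau: float) -> float:
    """p = min(1, tau + degree / subgraph edge count), with 0/0 -> 0.

    ``degree`` and ``n_subgraph_edges`` are taken from the proposing
    vertex's subgraph at the start of the snapshot.
    """
    plus = degree / n_subgraph_edges if n_subgraph_edges else 0.0
    return min(1.0, tau + plus)


def simulate_gin(
    params: GINParams, seed: int | None = None, return_events: bool = False
):
    """Simulate one undirected GIN snapshot sequence.

    ``seed`` overrides ``params.seed``; identical (params, seed) yield an
    identical sequence.  With ``return_events`` the function returns
    ``(sequence, events)`` where ``events`` is the list of edge creations
    as ``(snapshot, u, v)`` label triples (no entry is ever emitted for a
    pair that is currently present: proposing an existing edge is a no-op).
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    V, M, S = params.n_vertices, params.n_subgraphs, params.n_snapshots
    nm = params.subgraph_size
    tau, lam, kappa = params.tau, params.edge_lifetime, params.bridge_interval
    subgraph_of = lambda v: v // nm  # noqa: E731
    members = [list(range(m * nm, (m + 1) * nm)) for m in range(M)]

    edges: dict[tuple, int] = {}          # canonical (u, v), u < v -> last snapshot present
    active: set[int] = set()              # ever-active vertices (proposers)
    ever_connected: set[int] = set()      # ever incident to an edge (bridge candidates)
    seed_vertex = int(rng.integers(0, nm))
    active.add(seed_vertex)
    next_bridge = 1                       # subgraph (1-based) to be bridged next
    pending_bridge: tuple | None = None   # (snapshot, bridge vertex, target subgraph)
    snapshots = []
    events: list[tuple] = []

    def propose(a: int, deg, m_edges, adjacency, new_edges):
        m = subgraph_of(a)
        p = edge_probability(int(deg[a]), int(m_edges[m]), tau)
        for u in members[m]:
            if u == a or u in adjacency[a]:
                continue
            pair = (a, u) if a < u else (u, a)
            if rng.random() < p:
                new_edges.add(pair)

    for k in range(1, S + 1):
        edges = {e: last for e, last in edges.items() if last >= k}
        # frozen state at snapshot start
        deg = np.zeros(V, dtype=np.int64)
        m_edges = np.zeros(M, dtype=np.int64)
        adjacency: dict[int, set] = {v: set() for v in active}
        for (u, v) in edges:
            deg[u] += 1
            deg[v] += 1
            if subgraph_of(u) == subgraph_of(v):
                m_edges[subgraph_of(u)] += 1
            adjacency.setdefault(u, set()).add(v)
            adjacency.setdefault(v, set()).add(u)
        frozen_active = sorted(active)
        new_edges: set[tuple] = set()

        if k == 1:
            a = seed_vertex
            p = edge_probability(0, 0, tau)
            for u in members[0]:
                if u != a and rng.random() < p:
                    new_edges.add((a, u) if a < u else (u, a))
        else:
            if pending_bridge is not None and pending_bridge[0] == k:
                _, b, tgt = pending_bridge
                u = int(rng.choice(members[tgt]))
                new_edges.add((b, u) if b < u else (u, b))
                active.add(u)
                pending_bridge = None
            if params.pair_proposals == "per-vertex":
                for a in frozen_active:
                    adjacency.setdefault(a, set())
                    propose(a, deg, m_edges, adjacency, new_edges)
            else:
                seen_pairs = set()
                for a in frozen_active:
                    m = subgraph_of(a)
                    for u in members[m]:
                        if u == a or u in adjacency.get(a, ()):  # existing edge: no-op
                            continue
                        pair = (a, u) if a < u else (u, a)
                        if pair in seen_pairs:
                            continue
                        seen_pairs.add(pair)
                        best = max(
                            edge_probability(int(deg[x]), int(m_edges[m]), tau)
                            for x in pair
                            if x in active
                        )
                        if rng.random() < best:
                            new_edges.add(pair)

        for pair in sorted(new_edges):
            if pair not in edges:          # simultaneous double proposal: one edge
                edges[pair] = k + lam - 1
                events.append((k, *pair))
            active.update(pair)
            ever_connected.update(pair)

        snapshots.append(set(edges))

        # Bridge selection happens after the snapshot's growth, among the
        # subgraph's ever-connected vertices; the cross edge appears at k+1.
        # If the subgraph has no connected vertex yet when its slot kappa*m
        # comes up, the event defers to the first snapshot where one exists
        # (a bridge must be a connected vertex; with tau = 0 nothing ever
        # connects and no bridging happens at all).
        if (
            pending_bridge is None
            and next_bridge <= M - 1
            and kappa * next_bridge < S
            and k >= kappa * next_bridge
            and k < S
        ):
            candidates = sorted(
                v for v in ever_connected if subgraph_of(v) == next_bridge - 1
            )
            if candidates:
                b = int(rng.choice(candidates))
                pending_bridge = (k + 1, b, next_bridge)
                next_bridge += 1

    width = len(str(V - 1))
    labels = [f"v{v:0{width}d}" for v in range(V)]
    named = [
        {(labels[u], labels[v]) for (u, v) in snap} for snap in snapshots
    ]
    seq = GraphSequence(labels, named, directed=False)
    if return_events:
        return seq, [(k, labels[u], labels[v]) for (k, u, v) in events]
    return seq
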