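"""REN: reversed-sweep search for all shortest temporal paths into a vertex.

Temporal shortest paths do not satisfy the static subpath property: a
shortest path in G_k..G_S need not remain one in G_{k+1}..G_S, so the naive
computation of a temporal centrality restarts a search per start snapshot.
The reversed sweep exploits the one direction in which optimal substructure
*does* hold (every upper/suffix subpath of a shortest temporal path is again
shortest): one backward pass over the snapshots per destination vertex c
computes, for every source a and every start snapshot k simultaneously, the
earliest arrival m(a, k), the number sigma(a, k) of shortest paths, and the
successor structure of the shortest-path DAG.  Cost is linear in S for fixed
V and E.

The per-layer recurrence (k = S..1, with m(., S+1) = unreachable)::

    m(a, k) = k, sigma = 1                    if the edge a->c is in E_k
    m(a, k) = min( m(a, k+1),                 # halt
                   min_{b in N_k(a), b != c} m(b, k+1) )   # hops
    sigma(a, k) = sum of sigma(x, k+1) over the moves x attaining the min

A vertex adjacent to the destination is never expanded further (the direct
move is provably the unique shortest path from that start), which is the
step the paper credits for REN's speed on dense sequences.

Pass-through counts are obtained from the same DAG by avoidance counting:
``sigma(a, b, c) = sigma(a, c) - #(shortest paths avoiding b entirely)``,
rolled backwards as a (source x avoided-vertex) matrix.  This counts each
path once per distinct intermediate vertex, so halts on or revisits to b
never double count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .temporal_graph import UNREACHABLE, GraphSequence, PathCensus, TemporalPath, HOP, HALT

__all__ = ["ArrivalTable", "ren_sweep", "pass_counts", "path_census"]


def _arc_arrays(seq: GraphSequence):
    """Per-snapshot hop arcs as (src, dst) index arrays.

    Undirected edges contribute both orientations; directed edges only the
    stored one.  The arrays drive every relaxation in the sweep.
    """
    idx = seq._index
    arcs = []
    for k in range(1, seq.n_snapshots + 1):
        src, dst = [], []
        for u, v in seq.edges(k):
            ui, vi = idx[u], idx[v]
            src.append(ui)
            dst.append(vi)
            if not seq.directed:
                src.append(vi)
                dst.append(ui)
        arcs.append((np.asarray(src, dtype=np.int64), np.asarray(dst, dtype=np.int64)))
    return arcs


@dataclass
class ArrivalTable:
    """Earliest arrivals, shortest-path counts and successor moves for one destination.

    Arrays are indexed ``[k-1, source]`` for start snapshots ``k = 1..S``;
    unreachable entries hold :data:`clonecent.temporal_graph.UNREACHABLE`
    in ``m`` and 0 in ``sigma``.  ``op_count`` is the number of candidate
    relaxations performed (used to check the linear-in-S scaling without
    wall clocks).
    """

    destination: object
    vertices: tuple
    directed: bool
    m: np.ndarray          # (S, V) int64, UNREACHABLE where no path
    sigma: np.ndarray      # (S, V) float64
    op_count: int
    _succ: list = field(repr=False)   # per k: (direct_idx, halt_idx, hop_src, hop_dst)
    _index: dict = field(repr=False)

    @property
    def n_snapshots(self) -> int:
        return self.m.shape[0]

    def earliest_arrival(self, a, k: int) -> int:
        return int(self.m[k - 1, self._index[a]])

    def count(self, a, k: int) -> float:
        return float(self.sigma[k - 1, self._index[a]])

    def successors(self, a, k: int) -> list:
        """Moves x recorded for (a, k): ``a`` itself for a halt, hop targets
        otherwise; the direct move to the destination is reported as the
        destination.  Every recorded x satisfies m(x, k+1) = m(a, k)
        (suffix closure), except the terminal direct move."""
        ai = self._index[a]
        direct, halt, hs, hd = self._succ[k - 1]
        out = []
        if ai in direct:
            return [self.destination]
        if ai in halt:
            out.append(a)
        for s, d in zip(hs, hd):
            if s == ai:
                out.append(self.vertices[d])
        return out

    def extract_paths(self, a, k: int, limit: int = 100_000) -> list[TemporalPath]:
        """Materialise all shortest paths from (a, k) by walking the DAG.

        Exponential in the worst case; intended for small instances and
        cross-checks against the enumeration oracle."""
        ai = self._index[a]
        if self.m[k - 1, ai] == UNREACHABLE:
            return []
        out: list[TemporalPath] = []

        def walk(vi, col, occ, moves):
            if len(out) > limit:
                raise RuntimeError("path extraction limit exceeded")
            direct, halt, hs, hd = self._succ[col - 1]
            if vi in direct:
                out.append(
                    TemporalPath(
                        start=k,
                        occurrences=occ + (self.destination,),
                        moves=moves + (HOP,),
                    )
                )
                return
            if vi in halt:
                walk(vi, col + 1, occ + (self.vertices[vi],), moves + (HALT,))
            for s, d in zip(hs, hd):
                if s == vi:
                    walk(int(d), col + 1, occ + (self.vertices[d],), moves + (HOP,))

        walk(ai, k, (self.vertices[ai],), ())
        return out


def ren_sweep(seq: GraphSequence, c) -> ArrivalTable:
    """One reversed sweep from destination ``c`` over all snapshots.

    The sweep continues down to snapshot 1 even after paths are found;
    otherwise shortest paths starting at or near the first snapshot would be
    missed.  For directed sequences the sweep follows arcs against their
    direction, which is realised here by relaxing along out-neighbour moves
    of the source side.
    """
    if c not in seq._index:
        raise KeyError(f"unknown destination vertex {c!r}")
    V, S = seq.n_vertices, seq.n_snapshots
    ci = seq._index[c]
    INF = S + 2
    arcs = _arc_arrays(seq)

    m = np.full((S + 2, V), INF, dtype=np.int64)       # rows k = 1..S+1 used
    sigma = np.zeros((S + 2, V), dtype=np.float64)
    succ: list = [None] * S
    ops = 0
    all_idx = np.arange(V)

    for k in range(S, 0, -1):
        src, dst = arcs[k - 1]
        m_next = m[k + 1]
        sig_next = sigma[k + 1]

        direct = np.unique(src[dst == ci]) if len(src) else np.empty(0, dtype=np.int64)
        is_direct = np.zeros(V, dtype=bool)
        is_direct[direct] = True

        # candidate moves; direct vertices and the destination are not expanded
        halt_src = all_idx[~is_direct & (all_idx != ci)]
        if len(src):
            keep = (dst != ci) & ~is_direct[src] & (src != ci)
            hs, hd = src[keep], dst[keep]
        else:
            hs = hd = np.empty(0, dtype=np.int64)
        ops += len(halt_src) + len(hs)

        best = np.full(V, INF, dtype=np.int64)
        best[halt_src] = m_next[halt_src]
        if len(hs):
            np.minimum.at(best, hs, m_next[hd])
        best[direct] = k
        best[ci] = INF

        sig = np.zeros(V, dtype=np.float64)
        halt_match = (~is_direct) & (best < INF) & (m_next == best)
        halt_match[ci] = False
        sig[halt_match] = sig_next[halt_match]
        if len(hs):
            hop_match = m_next[hd] == best[hs]
            hs_m, hd_m = hs[hop_match], hd[hop_match]
            np.add.at(sig, hs_m, sig_next[hd_m])
        else:
            hs_m = hd_m = hs
        sig[direct] = 1.0
        sig[ci] = 0.0

        m[k] = best
        sigma[k] = sig
        succ[k - 1] = (
            frozenset(int(i) for i in direct),
            frozenset(int(i) for i in np.nonzero(halt_match)[0]),
            hs_m,
            hd_m,
        )

    m_pub = m[1 : S + 1].copy()
    m_pub[m_pub >= INF] = UNREACHABLE
    return ArrivalTable(
        destination=c,
        vertices=seq.vertices,
        directed=seq.directed,
        m=m_pub,
        sigma=sigma[1 : S + 1].copy(),
        op_count=ops,
        _succ=succ,
        _index=seq._index,
    )


def pass_counts(table: ArrivalTable, seq: GraphSequence) -> np.ndarray:
    """Per-(start, source, through) shortest-path pass counts for one destination.

    Returns a (S, V, V) array ``P`` with ``P[k-1, a, b]`` = number of
    shortest paths from (a, k) to the destination whose occurrence list
    contains ``b`` at an index in {k, ..., m-1}, each path counted once.

    Computed as sigma minus avoidance counts on the shortest-path DAG:
    ``Avd[v, b]`` = number of DAG paths from (v, k) that avoid ``b`` from
    occurrence index k-1 onward, rolled backwards with the recorded
    successor moves.  Zeroing the diagonal encodes "standing on b is a
    visit"; the start vertex itself is exempt because pass counts are only
    read for b not in {a, c}.
    """
    if tuple(table.vertices) != tuple(seq.vertices) or table.n_snapshots != seq.n_snapshots:
        raise ValueError("arrival table does not match the sequence")
    V, S = len(table.vertices), table.n_snapshots
    ci = table._index[table.destination]
    diag = np.arange(V)
    P = np.zeros((S, V, V), dtype=np.float64)
    avd_next = np.zeros((V, V), dtype=np.float64)
    for k in range(S, 0, -1):
        direct, halt, hs, hd = table._succ[k - 1]
        avd = np.zeros((V, V), dtype=np.float64)
        if halt:
            hidx = np.fromiter(halt, dtype=np.int64)
            avd[hidx] = avd_next[hidx]
        if len(hs):
            np.add.at(avd, hs, avd_next[hd])
        if direct:
            didx = np.fromiter(direct, dtype=np.int64)
            avd[didx] = 1.0
        avd[diag, diag] = 0.0
        avd[ci] = 0.0
        sig_k = table.sigma[k - 1]
        block = sig_k[:, None] - avd
        block[sig_k == 0.0] = 0.0
        block[:, ci] = 0.0
        block[diag, diag] = 0.0   # a path never "passes" its own source
        P[k - 1] = block
        avd_next = avd
    return P


def path_census(seq: GraphSequence) -> PathCensus:
    """Full census from one reversed sweep (plus pass counting) per destination.

    Matches :func:`clonecent.temporal_graph.census_oracle` elementwise
    wherever the oracle is feasible.  Arrival/count tables are cached per
    destination; the (S, V, V) pass blocks are recomputed on demand so that
    large instances can stream one destination at a time.
    """
    tables: dict = {}

    def table_for(c):
        if c not in tables:
            tables[c] = ren_sweep(seq, c)
        return tables[c]

    def provider(c, with_pass):
        t = table_for(c)
        P = pass_counts(t, seq) if with_pass else None
        return t.m, t.sigma, P

    return PathCensus(seq.vertices, seq.n_snapshots, seq.directed, provider)
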