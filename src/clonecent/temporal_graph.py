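"""Snapshot sequences, directed time graphs and an exhaustive path oracle.

A dynamic network observed at discrete times is represented as an ordered
sequence of static graphs ("snapshots") G_1, ..., G_S over one fixed vertex
set.  Equivalently the sequence can be unrolled into a *directed time graph*
(DTG): every vertex occurs S+1 times, once per occurrence index 0..S, and
column k holds a *halt* arc (v, k-1) -> (v, k) for every vertex plus a *hop*
arc for every edge of G_k.  A temporal path makes exactly one move (hop or
halt) per column; a path starting at snapshot k and arriving at snapshot m
has length m - k + 1.

This module provides the data model plus a brute-force enumeration oracle
used as the correctness reference for the reversed-sweep algorithm in
:mod:`clonecent.ren`.  The oracle is exponential and guarded by an expansion
budget; it is meant for small instances only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "UNREACHABLE",
    "HOP",
    "HALT",
    "OracleBudgetError",
    "GraphSequence",
    "DirectedTimeGraph",
    "TemporalPath",
    "PathCensus",
    "build_dtg",
    "validate_path",
    "enumerate_paths_oracle",
    "census_oracle",
]

#: Sentinel arrival value for vertex/start pairs with no temporal path.
UNREACHABLE = -1

HOP = "hop"
HALT = "halt"

#: Default cap on node expansions in the exhaustive oracle.
DEFAULT_ORACLE_BUDGET = 500_000


class OracleBudgetError(RuntimeError):
    """Raised when the exhaustive oracle exceeds its expansion budget."""


def _canonical_edge(u, v, directed: bool):
    if directed:
        return (u, v)
    try:
        return (u, v) if u <= v else (v, u)
    except TypeError:  # mixed label types; fall back to repr order
        return (u, v) if repr(u) <= repr(v) else (v, u)


class GraphSequence:
    """An ordered sequence of graph snapshots over a fixed vertex set.

    Parameters
    ----------
    vertices:
        Ordered collection of distinct, hashable vertex labels.
    snapshots:
        Ordered collection (1-based snapshot index ``k = 1..S``) of edge
        collections.  Each edge is a pair of distinct vertex labels.
        Undirected edges are stored in one canonical orientation
        (lexicographically smaller endpoint first) and duplicates collapse.
    directed:
        Interpret edges as ordered pairs when true.
    """

    __slots__ = ("vertices", "snapshots", "directed", "_index")

    def __init__(
        self,
        vertices: Iterable[Hashable],
        snapshots: Iterable[Iterable[tuple]],
        directed: bool = False,
    ):
        self.vertices = tuple(vertices)
        self._index = {v: i for i, v in enumerate(self.vertices)}
        if len(self._index) != len(self.vertices):
            raise ValueError("duplicate vertex labels")
        self.directed = bool(directed)
        canon = []
        for k, edges in enumerate(snapshots, start=1):
            es = set()
            for edge in edges:
                u, v = edge
                if u == v:
                    raise ValueError(f"self-loop {edge!r} in snapshot {k}")
                if u not in self._index or v not in self._index:
                    raise ValueError(f"edge {edge!r} in snapshot {k} has unknown endpoint")
                es.add(_canonical_edge(u, v, self.directed))
            canon.append(frozenset(es))
        if not canon:
            raise ValueError("a graph sequence needs at least one snapshot")
        self.snapshots = tuple(canon)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_snapshots(self) -> int:
        """S, the number of snapshots."""
        return len(self.snapshots)

    def index(self, v) -> int:
        return self._index[v]

    def edges(self, k: int) -> frozenset:
        """Edge set E_k of snapshot ``k`` (1-based)."""
        if not 1 <= k <= self.n_snapshots:
            raise IndexError(f"snapshot index {k} outside 1..{self.n_snapshots}")
        return self.snapshots[k - 1]

    def has_edge(self, u, v, k: int) -> bool:
        """Whether the move u -> v is available as a hop in column ``k``."""
        if self.directed:
            return (u, v) in self.edges(k)
        return _canonical_edge(u, v, False) in self.edges(k)

    def out_neighbors(self, v, k: int) -> list:
        """Vertices reachable from ``v`` by one hop in column ``k``."""
        out = []
        for a, b in self.edges(k):
            if a == v:
                out.append(b)
            elif not self.directed and b == v:
                out.append(a)
        return out

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GraphSequence)
            and self.vertices == other.vertices
            and self.directed == other.directed
            and self.snapshots == other.snapshots
        )

    def __hash__(self):
        return hash((self.vertices, self.directed, self.snapshots))

    def __repr__(self):
        kind = "directed" if self.directed else "undirected"
        return (
            f"GraphSequence(|V|={self.n_vertices}, S={self.n_snapshots}, {kind})"
        )


@dataclass(frozen=True)
class DirectedTimeGraph:
    """The layered unrolling of a snapshot sequence.

    ``columns[k-1]`` holds the arcs of column ``d_k`` as pairs of
    vertex-occurrences ``((v, k-1), (u, k))``: one halt arc per vertex plus
    the hop arcs induced by ``E_k`` (both orientations when undirected).
    """

    vertices: tuple
    columns: tuple  # tuple of frozensets of ((v, k-1), (u, k)) arcs

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def build_dtg(seq: GraphSequence) -> DirectedTimeGraph:
    """Unroll a graph sequence into its directed time graph."""
    cols = []
    for k in range(1, seq.n_snapshots + 1):
        arcs = {((v, k - 1), (v, k)) for v in seq.vertices}
        for u, v in seq.edges(k):
            arcs.add(((u, k - 1), (v, k)))
            if not seq.directed:
                arcs.add(((v, k - 1), (u, k)))
        cols.append(frozenset(arcs))
    return DirectedTimeGraph(vertices=seq.vertices, columns=tuple(cols))


@dataclass(frozen=True)
class TemporalPath:
    """A temporal path <v_{k-1}, ..., v_m> with one move per column.

    ``start`` is the start snapshot k (the first occurrence sits at DTG
    index k-1); ``occurrences`` lists the m - k + 2 visited vertices and
    ``moves`` the per-column tags (:data:`HOP` or :data:`HALT`).
    """

    start: int
    occurrences: tuple
    moves: tuple

    @property
    def arrival(self) -> int:
        """m, the snapshot at which the path ends."""
        return self.start + len(self.moves) - 1

    @property
    def length(self) -> int:
        """Number of moves, m - k + 1."""
        return len(self.moves)

    @property
    def source(self):
        return self.occurrences[0]

    @property
    def destination(self):
        return self.occurrences[-1]

    def intermediates(self) -> set:
        """Distinct vertices at occurrence indices k..m-1 (endpoints excluded).

        This is the set a shortest path "passes": the first-hop landing
        counts, the start occurrence (index k-1) and the arrival occurrence
        (index m) do not.
        """
        return set(self.occurrences[1:-1])


def validate_path(seq: GraphSequence, path: TemporalPath) -> bool:
    """True iff ``path`` is a well-formed temporal path of ``seq``.

    Never raises for malformed input; any structural defect (wrong lengths,
    unknown vertices, a move tag that contradicts the occurrence pair, or an
    absent edge) yields ``False``.
    """
    try:
        occ, moves, k = path.occurrences, path.moves, path.start
        if len(moves) < 1 or len(occ) != len(moves) + 1:
            return False
        if not 1 <= k or not k <= path.arrival <= seq.n_snapshots:
            return False
        if any(v not in seq._index for v in occ):
            return False
        for i, move in enumerate(moves):
            col = k + i
            prev, nxt = occ[i], occ[i + 1]
            if move == HALT:
                if prev != nxt:
                    return False
            elif move == HOP:
                if prev == nxt or not seq.has_edge(prev, nxt, col):
                    return False
            else:
                return False
        return True
    except Exception:
        return False


def enumerate_paths_oracle(
    seq: GraphSequence,
    a,
    c,
    k: int,
    max_arrival: int | None = None,
    budget: int = DEFAULT_ORACLE_BUDGET,
    _counter: list | None = None,
) -> list[TemporalPath]:
    """Exhaustively enumerate temporal paths from ``a`` (start ``k``) to ``c``.

    Depth-first expansion of every hop/halt combination in the DTG; a path
    terminates at its *first* arrival at ``c`` (the destination never occurs
    as an intermediate).  Returns all distinct paths arriving no later than
    ``max_arrival`` (default S).  Intended for small instances; raises
    :class:`OracleBudgetError` when more than ``budget`` node expansions are
    needed.
    """
    if a == c:
        raise ValueError("source and destination must differ")
    if max_arrival is None:
        max_arrival = seq.n_snapshots
    if not 1 <= k <= max_arrival <= seq.n_snapshots:
        raise ValueError("need 1 <= k <= max_arrival <= S")
    paths: list[TemporalPath] = []
    counter = _counter if _counter is not None else [0]

    def extend(v, col, occ, moves):
        counter[0] += 1
        if counter[0] > budget:
            raise OracleBudgetError(
                f"oracle budget of {budget} expansions exceeded"
            )
        if col > max_arrival:
            return
        nxts = [(v, HALT)]
        for b in sorted(seq.out_neighbors(v, col), key=repr):
            nxts.append((b, HOP))
        for nxt, tag in nxts:
            if nxt == c:
                paths.append(
                    TemporalPath(start=k, occurrences=occ + (c,), moves=moves + (tag,))
                )
            else:
                extend(nxt, col + 1, occ + (nxt,), moves + (tag,))

    extend(a, k, (a,), ())
    return paths


class PathCensus:
    """Aggregated earliest arrivals, shortest-path counts and pass-through counts.

    For every destination ``c``, start snapshot ``k`` and source ``a != c``
    the census records the earliest arrival ``m(a, k, c)``
    (:data:`UNREACHABLE` if none), the number ``sigma(a, k, c)`` of shortest
    temporal paths, and for every other vertex ``b`` the number
    ``sigma(a, b, c)`` of those paths that pass ``b`` at an occurrence index
    in ``{k, ..., m-1}`` (each path counted at most once per ``b``).

    The storage is a per-destination provider so that large instances can be
    streamed without materialising the (S, |V|, |V|) pass blocks for every
    destination at once.
    """

    def __init__(
        self,
        vertices: Sequence,
        n_snapshots: int,
        directed: bool,
        provider: Callable,
    ):
        self.vertices = tuple(vertices)
        self.n_snapshots = int(n_snapshots)
        self.directed = bool(directed)
        self._index = {v: i for i, v in enumerate(self.vertices)}
        self._provider = provider  # provider(c, with_pass) -> (m, sigma, P|None)
        self._cache: dict = {}
        self._last_pass: tuple | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def blocks(self, with_pass: bool = True) -> Iterator[tuple]:
        """Yield ``(c, m, sigma, pass_block)`` per destination.

        ``m`` and ``sigma`` are (S, |V|) arrays indexed by (k-1, source);
        ``pass_block`` is a (S, |V|, |V|) array indexed by
        (k-1, source, through) or ``None`` when ``with_pass`` is false.
        """
        for c in self.vertices:
            m, sigma, P = self._provider(c, with_pass)
            yield c, m, sigma, P

    def _table(self, c):
        if c not in self._cache:
            m, sigma, _ = self._provider(c, False)
            self._cache[c] = (m, sigma)
        return self._cache[c]

    def m(self, a, k: int, c) -> int:
        """Earliest arrival snapshot of a shortest a -> c path from start k."""
        marr, _ = self._table(c)
        return int(marr[k - 1, self._index[a]])

    def sigma(self, a, k: int, c):
        """Number of shortest a -> c temporal paths from start k."""
        _, sig = self._table(c)
        val = sig[k - 1, self._index[a]]
        return int(val) if float(val).is_integer() else float(val)

    def sigma_through(self, a, b, c, k: int):
        """Number of shortest a -> c paths from start k passing b."""
        if self._last_pass is None or self._last_pass[0] != c:
            _, _, P = self._provider(c, True)
            self._last_pass = (c, P)
        P = self._last_pass[1]
        val = P[k - 1, self._index[a], self._index[b]]
        return int(val) if float(val).is_integer() else float(val)


def census_oracle(
    seq: GraphSequence, budget: int = DEFAULT_ORACLE_BUDGET
) -> PathCensus:
    """Brute-force census by direct enumeration; reference for REN.

    Shortest paths per (destination, start, source) triple are found by
    iterative deepening on the arrival snapshot, so dense instances stay
    cheap; ``budget`` caps the cumulative expansions of the whole census.
    """
    V, S = seq.n_vertices, seq.n_snapshots
    idx = seq._index
    counter = [0]  # one expansion budget for the whole census
    data = {}
    for c in seq.vertices:
        marr = np.full((S, V), UNREACHABLE, dtype=np.int64)
        sig = np.zeros((S, V), dtype=np.float64)
        P = np.zeros((S, V, V), dtype=np.float64)
        for a in seq.vertices:
            if a == c:
                continue
            ai = idx[a]
            for k in range(1, S + 1):
                shortest: list[TemporalPath] = []
                for m_try in range(k, S + 1):
                    shortest = enumerate_paths_oracle(
                        seq, a, c, k, max_arrival=m_try, budget=budget,
                        _counter=counter,
                    )
                    if shortest:
                        break
                if not shortest:
                    continue
                m = shortest[0].arrival
                marr[k - 1, ai] = m
                sig[k - 1, ai] = len(shortest)
                for p in shortest:
                    for b in p.intermediates():
                        if b != a and b != c:
                            P[k - 1, ai, idx[b]] += 1.0
        data[c] = (marr, sig, P)

    def provider(c, with_pass):
        m, sig, P = data[c]
        return m, sig, (P if with_pass else None)

    return PathCensus(seq.vertices, S, seq.directed, provider)
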