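"""Clone plans: inserting copies of observed snapshots into a sequence.

An incompletely observed snapshot sequence hides edge durations and edge
orderings between observations.  Cloning compensates by repeating each
observed snapshot ``J_k`` times (the original counts as copy 1), so that
temporal paths consistent with the unknown in-between dynamics become
realisable.  Copies of snapshot k are contiguous and placed immediately
after the original, before the copies of snapshot k+1.

Three strategies produce plans:

* a fixed number of added clones per snapshot (``n_c``), used to study the
  bias from *excess* cloning;
* gap-based counts when the observation times are known: as many clones as
  there were unobserved time points between consecutive observations, with
  a trailing fill up to the horizon;
* a path-closure bound: enough copies that any static path in the union of
  two consecutive snapshots is realisable as a temporal path under block
  ordering, capped by the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .temporal_graph import GraphSequence

__all__ = [
    "ClonePlan",
    "plan_fixed",
    "plan_from_gaps",
    "plan_path_closure",
    "apply_clones",
]


@dataclass(frozen=True)
class ClonePlan:
    """Per-snapshot total copy counts J_k >= 1 (original included)."""

    copies: tuple
    strategy: str = "manual"

    def __post_init__(self):
        object.__setattr__(self, "copies", tuple(int(j) for j in self.copies))
        if not self.copies:
            raise ValueError("empty clone plan")
        if any(j < 1 for j in self.copies):
            raise ValueError("copy counts J_k must be >= 1")

    @property
    def n_snapshots(self) -> int:
        return len(self.copies)

    @property
    def cloned_length(self) -> int:
        """S' = sum of J_k."""
        return sum(self.copies)

    @property
    def is_identity(self) -> bool:
        return all(j == 1 for j in self.copies)

    @property
    def added_clones(self) -> tuple:
        """n_c per snapshot, i.e. J_k - 1."""
        return tuple(j - 1 for j in self.copies)

    def to_frame(self) -> pd.DataFrame:
        """Two-column serialisation (snapshot index, copy count)."""
        return pd.DataFrame(
            {"snapshot": range(1, self.n_snapshots + 1), "copies": self.copies}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strategy: str = "manual") -> "ClonePlan":
        df = df.sort_values("snapshot")
        expected = list(range(1, len(df) + 1))
        if list(df["snapshot"]) != expected:
            raise ValueError("plan table must cover snapshots 1..S exactly once")
        return cls(tuple(df["copies"]), strategy=strategy)


def plan_fixed(seq: GraphSequence, n_c: int) -> ClonePlan:
    """``n_c`` added clones for every snapshot: J_k = n_c + 1."""
    n_c = int(n_c)
    if n_c < 0:
        raise ValueError("n_c must be nonnegative")
    return ClonePlan((n_c + 1,) * seq.n_snapshots, strategy=f"fixed(n_c={n_c})")


def plan_from_gaps(observed_positions, horizon: int) -> ClonePlan:
    """Clone counts equal to the number of unobserved time points.

    ``observed_positions`` are the original (1-based) time indices of the
    retained snapshots, strictly increasing within ``1..horizon``.  Snapshot
    k gets as many added clones as there are unobserved positions between it
    and the next observed one; the last observed snapshot is filled up to
    the horizon.  No leading fill: nothing is known before the first
    observation.
    """
    pos = [int(t) for t in observed_positions]
    if not pos:
        raise ValueError("no observed positions")
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("observed positions must be strictly increasing")
    if pos[0] < 1 or pos[-1] > horizon:
        raise ValueError(f"positions must lie within 1..{horizon}")
    copies = [nxt - t for t, nxt in zip(pos, pos[1:])]
    copies.append(horizon - pos[-1] + 1)
    return ClonePlan(tuple(copies), strategy="gaps")


def plan_path_closure(seq: GraphSequence, cap: int) -> ClonePlan:
    """Copies sufficient to realise static paths of G_{k-1} u G_k temporally.

    A static path of L edges needs at most L columns to be walked as a
    temporal path, so J_k = 1 + min(cap, |V|-1, |E_{k-1} u E_k|) suffices
    for paths realisable under block ordering (|V|-1 bounds any simple
    path's edge count).  For k = 1 only E_1 is available.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    vmax = seq.n_vertices - 1
    copies = []
    for k in range(1, seq.n_snapshots + 1):
        union = seq.edges(k) if k == 1 else seq.edges(k - 1) | seq.edges(k)
        copies.append(1 + min(cap, vmax, len(union)))
    return ClonePlan(tuple(copies), strategy=f"path_closure(cap={cap})")


def apply_clones(seq: GraphSequence, plan: ClonePlan):
    """Materialise the cloned sequence G_{1,1}, G_{1,2}, ..., G_{S,J_S}.

    Returns ``(cloned_sequence, first_positions)`` where
    ``first_positions[k-1]`` is the (1-based) position of the original copy
    of snapshot k inside the cloned sequence.
    """
    if plan.n_snapshots != seq.n_snapshots:
        raise ValueError(
            f"plan covers {plan.n_snapshots} snapshots, sequence has {seq.n_snapshots}"
        )
    snaps = []
    first_positions = []
    pos = 1
    for k, j in enumerate(plan.copies, start=1):
        first_positions.append(pos)
        snaps.extend([seq.edges(k)] * j)
        pos += j
    cloned = GraphSequence(seq.vertices, snaps, directed=seq.directed)
    return cloned, tuple(first_positions)
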