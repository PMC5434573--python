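"""Temporal betweenness/closeness centralities and their clone variants.

Temporal betweenness of a vertex b sums, over every start snapshot k and
every ordered source/destination pair (a, c) with a path, the fraction of
shortest temporal paths from a (start k) to c that pass b::

    TBC(b) = sum_{k=1}^{S-1} sum_{(a,c): sigma_k(a,c) > 0}
             sigma_k(a, b, c) / sigma_k(a, c)

The outer sum over start snapshots is what distinguishes the temporal from
the static measure: a path that is shortest from start k need not exist at
all from start k+1, so every suffix subsequence contributes its own terms.

The clone variants (CTBC/CTCC) are the same measures evaluated on the
cloned sequence: the triple sum over (snapshot, copy, pair) enumerates
exactly the start positions of the cloned sequence, so CTBC on a plan with
zero added clones is TBC, elementwise.

Temporal closeness uses a reciprocal-shortest-length convention::

    TCC(a) = sum_{k=1}^{S} sum_{c != a reachable from (a,k)} 1 / (m - k + 1)

labelled as a convention in all outputs (the reference formulation of the
closeness variant is not available; any comparison to published closeness
figures is qualitative only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import ren
from .cloning import ClonePlan, apply_clones
from .temporal_graph import GraphSequence, PathCensus, UNREACHABLE

__all__ = ["CentralityResult", "tbc", "tcc", "ctbc", "ctcc"]


@dataclass
class CentralityResult:
    """Per-vertex centrality values with tie-averaged descending ranks."""

    measure: str
    values: pd.Series
    n_snapshots: int
    plan: ClonePlan | None = None
    ranks: pd.Series = field(init=False)

    def __post_init__(self):
        r = rankdata(-self.values.to_numpy(), method="average")
        self.ranks = pd.Series(r, index=self.values.index, name="rank")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vertex": self.values.index, "value": self.values.to_numpy(),
             "rank": self.ranks.to_numpy()}
        )


def _result(measure, vertices, values, S, plan=None) -> CentralityResult:
    series = pd.Series(values, index=pd.Index(vertices, name="vertex"), name="value")
    return CentralityResult(measure=measure, values=series, n_snapshots=S, plan=plan)


def tbc(census: PathCensus, S: int | None = None) -> CentralityResult:
    """Temporal betweenness from a path census.

    Streams one destination at a time; the pass block of a destination is
    a (S, V, V) array of pass-through counts whose rows are divided by the
    shortest-path totals and accumulated per through-vertex.  Start
    snapshots run to S-1: from start S only length-1 paths exist and those
    have no intermediates.
    """
    if S is None:
        S = census.n_snapshots
    if S != census.n_snapshots:
        raise ValueError("S does not match the census")
    V = census.n_vertices
    total = np.zeros(V, dtype=np.float64)
    if S >= 2:
        for _c, _m, sigma, P in census.blocks(with_pass=True):
            sig = sigma[: S - 1]                      # (S-1, V) totals
            reach = sig > 0.0
            if not reach.any():
                continue
            W = np.divide(
                P[: S - 1], sig[:, :, None],
                out=np.zeros_like(P[: S - 1]), where=reach[:, :, None],
            )
            total += W.sum(axis=(0, 1))
    return _result("TBC", census.vertices, total, S)


def tcc(census: PathCensus, S: int | None = None) -> CentralityResult:
    """Temporal closeness (reciprocal shortest temporal path length).

    Needs only the arrival tables, not pass counts.  Unreachable pairs
    contribute 0; start snapshots run to S so that direct edges in the last
    snapshot still count with length 1.
    """
    if S is None:
        S = census.n_snapshots
    if S != census.n_snapshots:
        raise ValueError("S does not match the census")
    V = census.n_vertices
    total = np.zeros(V, dtype=np.float64)
    starts = np.arange(1, S + 1)[:, None]            # (S, 1)
    for _c, m, _sigma, _P in census.blocks(with_pass=False):
        reach = m != UNREACHABLE
        lengths = np.where(reach, m - starts + 1, 1)
        total += np.where(reach, 1.0 / lengths, 0.0).sum(axis=0)
    return _result("TCC", census.vertices, total, S)


def ctbc(seq: GraphSequence, plan: ClonePlan) -> CentralityResult:
    """Clone temporal betweenness: TBC on the cloned sequence.

    The cloned sequence has length S' = sum J_k; its start positions are
    exactly the (snapshot, copy) pairs of the triple-sum formulation, so
    this equals the literal sum over clones (the extra start at S'
    contributes 0).  With the all-ones plan this is TBC on the original
    sequence, elementwise.
    """
    cloned, _ = apply_clones(seq, plan)
    res = tbc(ren.path_census(cloned), cloned.n_snapshots)
    return _result("CTBC", res.values.index, res.values.to_numpy(),
                   cloned.n_snapshots, plan=plan)


def ctcc(seq: GraphSequence, plan: ClonePlan) -> CentralityResult:
    """Clone temporal closeness: TCC on the cloned sequence."""
    cloned, _ = apply_clones(seq, plan)
    res = tcc(ren.path_census(cloned), cloned.n_snapshots)
    return _result("CTCC", res.values.index, res.values.to_numpy(),
                   cloned.n_snapshots, plan=plan)
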