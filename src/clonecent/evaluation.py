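"""Incompleteness experiments: subsampling, rank metrics and the grid runner.

The evaluation protocol mirrors the simulation study: simulate a dynamic
network, compute the *true* temporal betweenness ranks on the complete
sequence, thin the sequence to an observation rate alpha (or keep it whole
and inject a fixed number of clones), re-estimate the centrality with and
without cloning, and score the estimates against the truth with Spearman's
rank correlation, the top-vertex detection rate and absolute rank
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import centrality, ren
from .cloning import plan_fixed, plan_from_gaps
from .gin_sim import GINParams, simulate_gin
from .temporal_graph import GraphSequence

__all__ = [
    "ExperimentResult",
    "rank_vertices",
    "spearman_rho",
    "detection_rate",
    "ard_summary",
    "sample_random",
    "sample_every_jth",
    "run_experiment",
    "plot_rho_boxes",
]


def rank_vertices(values) -> np.ndarray:
    """Descending tie-averaged ranks: rank 1 is the largest value.

    Tied values share the average of their positional ranks, so the ranks
    always sum to n(n+1)/2.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot rank an empty value vector")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    return rankdata(-arr, method="average")


def spearman_rho(ranks_a, ranks_b) -> float:
    """Spearman's rho as the Pearson correlation of two rank vectors.

    Returns NaN when either rank vector has zero variance (all tied), which
    callers report as missing.
    """
    ra = np.asarray(ranks_a, dtype=np.float64)
    rb = np.asarray(ranks_b, dtype=np.float64)
    if ra.shape != rb.shape or ra.ndim != 1 or ra.size < 2:
        raise ValueError("need two equal-length rank vectors of length >= 2")
    if ra.std() == 0.0 or rb.std() == 0.0:
        return float("nan")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def detection_rate(replicates) -> float:
    """Fraction of replicates whose estimated top set meets the true top set.

    Each replicate is a pair (true_top, estimated_top) of vertex sets with
    maximal centrality value; a tie at the top that contains the true top
    vertex counts as a match.
    """
    pairs = list(replicates)
    if not pairs:
        raise ValueError("no replicates")
    hits = sum(1 for true_top, est_top in pairs if set(true_top) & set(est_top))
    return hits / len(pairs)


def ard_summary(true_ranks, est_ranks):
    """Per-vertex absolute rank differences plus a quartile summary.

    Accepts arrays over the same vertex universe (pandas Series are aligned
    by index).  Returns ``(diffs, summary)`` with summary keys ``q1``,
    ``median``, ``q3``.
    """
    if isinstance(true_ranks, pd.Series) and isinstance(est_ranks, pd.Series):
        if set(true_ranks.index) != set(est_ranks.index):
            raise ValueError("rank vectors cover different vertex universes")
        est_ranks = est_ranks.reindex(true_ranks.index)
    ta = np.asarray(true_ranks, dtype=np.float64)
    ea = np.asarray(est_ranks, dtype=np.float64)
    if ta.shape != ea.shape:
        raise ValueError("rank vectors cover different vertex universes")
    diffs = np.abs(ta - ea)
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    return diffs, {"q1": float(q1), "median": float(med), "q3": float(q3)}


def _subsequence(seq: GraphSequence, positions) -> GraphSequence:
    return GraphSequence(
        seq.vertices, [seq.edges(k) for k in positions], directed=seq.directed
    )


def sample_random(seq: GraphSequence, alpha: float, rng=None):
    """Retain round(alpha * S) snapshots drawn uniformly, order preserved.

    Returns ``(subsequence, positions)`` with 1-based original positions,
    as needed for gap-based cloning.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    S = seq.n_snapshots
    n = int(round(alpha * S))
    if n < 1:
        raise ValueError(f"alpha={alpha} retains no snapshot of S={S}")
    rng = np.random.default_rng(rng)
    positions = tuple(int(p) for p in np.sort(rng.choice(S, size=n, replace=False)) + 1)
    return _subsequence(seq, positions), positions


def sample_every_jth(seq: GraphSequence, step: int, offset: int | None = None):
    """Systematic thinning: keep positions offset, offset+step, ... <= S.

    The default offset equals the step (e.g. every 4th snapshot of 37
    yields the nine positions 4, 8, ..., 36).
    """
    S = seq.n_snapshots
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > S:
        raise ValueError(f"step={step} exceeds S={S}")
    if offset is None:
        offset = step
    if not 1 <= offset <= S:
        raise ValueError("offset outside 1..S")
    positions = tuple(range(offset, S + 1, step))
    return _subsequence(seq, positions), positions


@dataclass
class ExperimentResult:
    """Long-format per-replicate scores plus a per-cell summary table."""

    replicates: pd.DataFrame
    summary: pd.DataFrame


_BASE_OF = {"tbc": "tbc", "ctbc": "tbc", "tcc": "tcc", "ctcc": "tcc"}


def _centrality_values(seq: GraphSequence, kind: str) -> pd.Series:
    census = ren.path_census(seq)
    if kind == "tbc":
        return centrality.tbc(census).values
    return centrality.tcc(census).values


def _top_set(values: pd.Series):
    return frozenset(values.index[values.to_numpy() == values.to_numpy().max()])


def run_experiment(
    params: GINParams,
    *,
    alphas=(0.3,),
    lifetimes=None,
    n_clones=None,
    replicates: int = 50,
    measures=("tbc", "ctbc"),
    seed: int = 0,
) -> ExperimentResult:
    """Simulate-and-score grid over edge lifetimes and observation rates.

    For every (lifetime, replicate): simulate a GIN, compute true ranks on
    the complete sequence, then for every alpha draw an incomplete
    subsequence and score the requested measures against the truth.  Clone
    plans are gap-based (one clone per unobserved snapshot) when
    ``n_clones`` is None; otherwise ``n_clones`` is a grid of fixed counts
    and each count is scored separately (the excess-of-cloning design).
    Everything derives from ``seed``; results are bit-reproducible.
    """
    unknown = set(measures) - set(_BASE_OF)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    if lifetimes is None:
        lifetimes = (params.edge_lifetime,)
    bases = sorted({_BASE_OF[m] for m in measures})
    n_clone_grid = None if n_clones is None else tuple(int(n) for n in n_clones)
    rows = []
    for lam in lifetimes:
        lam_params = replace(params, edge_lifetime=int(lam), seed=None)
        for rep in range(replicates):
            ss = np.random.SeedSequence([int(seed), int(lam), rep])
            sim_seed, sample_seed = ss.spawn(2)
            seq = simulate_gin(lam_params, seed=sim_seed)
            truth = {b: _centrality_values(seq, b) for b in bases}
            true_ranks = {b: rank_vertices(truth[b].to_numpy()) for b in bases}
            true_top = {b: _top_set(truth[b]) for b in bases}
            for alpha in alphas:
                rng = np.random.default_rng(sample_seed)
                sub, positions = sample_random(seq, alpha, rng=rng)
                plans = (
                    [("gaps", plan_from_gaps(positions, seq.n_snapshots))]
                    if n_clone_grid is None
                    else [(n_c, plan_fixed(sub, n_c)) for n_c in n_clone_grid]
                )
                for measure in measures:
                    base = _BASE_OF[measure]
                    if measure in ("tbc", "tcc"):
                        variants = [(pd.NA, _centrality_values(sub, base))]
                    else:
                        fn = centrality.ctbc if base == "tbc" else centrality.ctcc
                        variants = [(tag, fn(sub, plan).values) for tag, plan in plans]
                    for tag, est in variants:
                        est_ranks = rank_vertices(est.to_numpy())
                        diffs, ard = ard_summary(true_ranks[base], est_ranks)
                        rows.append(
                            {
                                "measure": measure,
                                "n_vertices": params.n_vertices,
                                "lifetime": int(lam),
                                "alpha": float(alpha),
                                "n_clones": tag,
                                "replicate": rep,
                                "rho": spearman_rho(true_ranks[base], est_ranks),
                                "top_match": bool(true_top[base] & _top_set(est)),
                                "ard_q1": ard["q1"],
                                "ard_median": ard["median"],
                                "ard_q3": ard["q3"],
                            }
                        )
    rep_df = pd.DataFrame(rows)
    grouped = rep_df.groupby(
        ["measure", "n_vertices", "lifetime", "alpha", "n_clones"], dropna=False
    )
    summary = grouped.agg(
        rho_q1=("rho", lambda s: s.quantile(0.25)),
        rho_median=("rho", "median"),
        rho_q3=("rho", lambda s: s.quantile(0.75)),
        detection_rate=("top_match", "mean"),
        ard_median=("ard_median", "median"),
        n=("rho", "size"),
    ).reset_index()
    return ExperimentResult(replicates=rep_df, summary=summary)


def plot_rho_boxes(result: ExperimentResult, by: str = "lifetime", ax=None):
    """Minimal box-plot helper: distribution of rho per measure and cell."""
    import matplotlib.pyplot as plt

    df = result.replicates
    if ax is None:
        _, ax = plt.subplots()
    cells = sorted(df[by].dropna().unique())
    measures = sorted(df["measure"].unique())
    width = 0.8 / max(len(measures), 1)
    for i, measure in enumerate(measures):
        data = [
            df[(df["measure"] == measure) & (df[by] == cell)]["rho"].dropna()
            for cell in cells
        ]
        pos = [j + i * width for j in range(len(cells))]
        ax.boxplot(data, positions=pos, widths=width * 0.9)
    ax.set_xticks(range(len(cells)))
    ax.set_xticklabels([str(c) for c in cells])
    ax.set_xlabel(by)
    ax.set_ylabel("Spearman rho vs true ranks")
    return ax
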