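"""Shared fixtures: worked-example sequences and the random-instance battery."""

import numpy as np
import pytest

from clonecent import (
    ClonePlan,
    GraphSequence,
    apply_clones,
    census_oracle,
    path_census,
)


def make_random_sequence(rng, n_vertices, n_snapshots, p, directed=False):
    """Erdos-Renyi snapshots over single-letter vertex labels."""
    verts = [chr(65 + i) for i in range(n_vertices)]
    snaps = []
    for _ in range(n_snapshots):
        edges = set()
        for i in range(n_vertices):
            for j in range(n_vertices):
                if i == j or (not directed and i > j):
                    continue
                if rng.random() < p:
                    edges.add((verts[i], verts[j]))
        snaps.append(edges)
    return GraphSequence(verts, snaps, directed=directed)


@pytest.fixture
def fig2_obs():
    """Observed incomplete sequence of the worked example: 4 vertices,
    E_1 = {A-C}, E_2 = {A-D, B-D}, E_3 empty."""
    return GraphSequence("ABCD", [{("A", "C")}, {("A", "D"), ("B", "D")}, set()])


@pytest.fixture
def fig3_cloned(fig2_obs):
    """The same sequence with the first two snapshots cloned once each."""
    cloned, _ = apply_clones(fig2_obs, ClonePlan((2, 2, 1)))
    return cloned


def battery_params(n_instances):
    """Deterministic parameter roll for the random-instance battery."""
    rng = np.random.default_rng(20170516)
    out = []
    for trial in range(n_instances):
        out.append(
            dict(
                n_vertices=int(rng.integers(3, 8)),
                n_snapshots=int(rng.integers(2, 7)),
                p=(0.1, 0.3, 0.6)[trial % 3],
                directed=bool(trial % 2),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


@pytest.fixture(scope="session")
def oracle_battery():
    """300 random small instances with both censuses precomputed.

    Shared by the sweep/oracle equivalence suite and the shortest-path
    structure (suffix/recovery) suites, so the expensive enumeration runs
    once per session.
    """
    instances = []
    for spec in battery_params(300):
        seed = spec.pop("seed")
        seq = make_random_sequence(np.random.default_rng(seed), **spec)
        instances.append((seq, census_oracle(seq), path_census(seq)))
    return instances
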