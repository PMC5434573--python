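"""Data model, DTG construction, path validation and the enumeration oracle."""

import numpy as np
import pytest

from clonecent import (
    HALT,
    HOP,
    UNREACHABLE,
    GraphSequence,
    TemporalPath,
    build_dtg,
    census_oracle,
    enumerate_paths_oracle,
    validate_path,
)
from clonecent.temporal_graph import OracleBudgetError

from conftest import make_random_sequence


class TestGraphSequence:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            GraphSequence("AB", [{("A", "A")}])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown endpoint"):
            GraphSequence("AB", [{("A", "Z")}])

    def test_needs_a_snapshot(self):
        with pytest.raises(ValueError):
            GraphSequence("AB", [])

    def test_undirected_canonicalisation_collapses_duplicates(self):
        seq = GraphSequence("AB", [[("B", "A"), ("A", "B")]])
        assert seq.edges(1) == frozenset({("A", "B")})

    def test_directed_orientations_are_distinct(self):
        seq = GraphSequence("AB", [[("B", "A"), ("A", "B")]], directed=True)
        assert seq.edges(1) == frozenset({("A", "B"), ("B", "A")})
        assert seq.has_edge("A", "B", 1) and seq.has_edge("B", "A", 1)

    def test_duplicate_vertices_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GraphSequence("ABA", [set()])


class TestBuildDtg:
    def test_empty_snapshot_has_only_halts(self):
        seq = GraphSequence("ABC", [set()])
        dtg = build_dtg(seq)
        assert dtg.n_columns == 1
        assert dtg.columns[0] == frozenset(
            {((v, 0), (v, 1)) for v in "ABC"}
        )

    def test_fig2_column_counts(self, fig2_obs):
        dtg = build_dtg(fig2_obs)
        assert dtg.n_columns == 3
        col2 = dtg.columns[1]
        halts = {a for a in col2 if a[0][0] == a[1][0]}
        hops = col2 - halts
        assert len(halts) == 4
        assert len(hops) == 4  # two undirected edges, both orientations

    def test_directed_hop_one_orientation(self):
        seq = GraphSequence("ab", [{("a", "b")}], directed=True)
        col1 = build_dtg(seq).columns[0]
        assert (("a", 0), ("b", 1)) in col1
        assert (("b", 0), ("a", 1)) not in col1


class TestValidatePath:
    def test_valid_cloned_path(self, fig3_cloned):
        path = TemporalPath(start=3, occurrences=("A", "D", "B"), moves=(HOP, HOP))
        assert validate_path(fig3_cloned, path)
        assert path.arrival == 4 and path.length == 2

    def test_absent_edge_fails(self, fig2_obs):
        path = TemporalPath(start=1, occurrences=("A", "B"), moves=(HOP,))
        assert not validate_path(fig2_obs, path)

    def test_halt_tag_must_stay_put(self, fig2_obs):
        path = TemporalPath(start=1, occurrences=("A", "C"), moves=(HALT,))
        assert not validate_path(fig2_obs, path)

    def test_move_count_must_match_columns(self, fig2_obs):
        # two moves squeezed against one occurrence step is malformed
        path = TemporalPath(start=1, occurrences=("A", "C"), moves=(HOP, HOP))
        assert not validate_path(fig2_obs, path)

    def test_overlong_and_unknown_inputs_return_false(self, fig2_obs):
        assert not validate_path(
            fig2_obs,
            TemporalPath(start=3, occurrences=("A", "A", "A"), moves=(HALT, HALT)),
        )
        assert not validate_path(
            fig2_obs, TemporalPath(start=1, occurrences=("A", "Z"), moves=(HOP,))
        )


class TestEnumerationOracle:
    def test_fig2_single_shortest_c_to_d(self, fig2_obs):
        paths = enumerate_paths_oracle(fig2_obs, "C", "D", 1)
        shortest = [p for p in paths if p.arrival == 2]
        assert len(shortest) == 1
        assert shortest[0].occurrences == ("C", "A", "D")

    def test_fig2_no_path_a_to_b(self, fig2_obs):
        for k in (1, 2, 3):
            assert enumerate_paths_oracle(fig2_obs, "A", "B", k) == []

    def test_cloned_sequence_reveals_two_paths(self, fig3_cloned):
        paths = enumerate_paths_oracle(fig3_cloned, "C", "B", 1)
        arr4 = {p.occurrences for p in paths if p.arrival == 4}
        assert arr4 == {("C", "A", "A", "D", "B"), ("C", "C", "A", "D", "B")}

    def test_budget_guard(self):
        seq = make_random_sequence(np.random.default_rng(0), 7, 6, 0.6)
        with pytest.raises(OracleBudgetError):
            enumerate_paths_oracle(seq, "A", "B", 1, budget=10)

    def test_invalid_arguments(self, fig2_obs):
        with pytest.raises(ValueError):
            enumerate_paths_oracle(fig2_obs, "A", "A", 1)
        with pytest.raises(ValueError):
            enumerate_paths_oracle(fig2_obs, "A", "B", 0)


class TestCensusOracle:
    def test_fig2_counts(self, fig2_obs):
        cen = census_oracle(fig2_obs)
        assert cen.m("C", 1, "D") == 2
        assert cen.sigma("C", 1, "D") == 1
        assert cen.sigma_through("C", "A", "D", 1) == 1
        assert cen.m("A", 1, "B") == UNREACHABLE

    def test_cloned_counts(self, fig3_cloned):
        cen = census_oracle(fig3_cloned)
        assert cen.sigma("C", 1, "B") == 2
        assert cen.m("C", 1, "B") == 4
        assert cen.sigma_through("C", "D", "B", 1) == 2
        assert cen.sigma_through("C", "A", "B", 1) == 2
        # both shortest A->B paths use the cloned A-C column or a halt
        assert cen.sigma("A", 1, "B") == 2
        # B-D sits in the first copy of the second observed snapshot
        assert cen.m("D", 3, "B") == 3

    def test_direct_edge_rule(self):
        """A direct edge at the start snapshot is the unique shortest path
        and has no intermediates."""
        rng = np.random.default_rng(3)
        for directed in (False, True):
            seq = make_random_sequence(rng, 5, 4, 0.4, directed=directed)
            cen = census_oracle(seq)
            for k in range(1, seq.n_snapshots + 1):
                for u, v in seq.edges(k):
                    pairs = [(u, v)] if directed else [(u, v), (v, u)]
                    for a, c in pairs:
                        assert cen.m(a, k, c) == k
                        assert cen.sigma(a, k, c) == 1
                        for b in seq.vertices:
                            if b not in (a, c):
                                assert cen.sigma_through(a, b, c, k) == 0


@pytest.fixture(scope="module")
def small_battery():
    rng = np.random.default_rng(42)
    out = []
    for trial in range(12):
        seq = make_random_sequence(
            rng, int(rng.integers(3, 7)), int(rng.integers(2, 6)),
            (0.15, 0.35)[trial % 2], directed=bool(trial % 2),
        )
        out.append((seq, census_oracle(seq)))
    return out


class TestPathStructure:
    """Structural invariants of shortest temporal paths, checked exhaustively."""

    def test_shortest_path_length_is_arrival_span(self, small_battery):
        for seq, cen in small_battery:
            for a in seq.vertices:
                for c in seq.vertices:
                    if a == c:
                        continue
                    for k in range(1, seq.n_snapshots + 1):
                        m = cen.m(a, k, c)
                        if m == UNREACHABLE:
                            continue
                        paths = enumerate_paths_oracle(seq, a, c, k, max_arrival=m)
                        assert paths and all(p.length == m - k + 1 for p in paths)

    def test_suffixes_of_shortest_paths_are_shortest(self, small_battery):
        """Every suffix of a shortest path, taken from any intermediate
        occurrence, is itself a shortest path from that vertex and start."""
        for seq, cen in small_battery:
            for a in seq.vertices:
                for c in seq.vertices:
                    if a == c:
                        continue
                    for k in range(1, seq.n_snapshots + 1):
                        m = cen.m(a, k, c)
                        if m == UNREACHABLE:
                            continue
                        for p in enumerate_paths_oracle(seq, a, c, k, max_arrival=m):
                            for i in range(1, len(p.occurrences) - 1):
                                b = p.occurrences[i]
                                start = k + i  # occurrence index k-1+i, next column
                                assert cen.m(b, start, c) == m

    def test_starting_later_never_arrives_earlier(self, small_battery):
        """m(a, k, c) <= m(a, k+1, c): a halt emulates any late start."""
        for seq, cen in small_battery:
            for a in seq.vertices:
                for c in seq.vertices:
                    if a == c:
                        continue
                    for k in range(1, seq.n_snapshots):
                        m_now, m_next = cen.m(a, k, c), cen.m(a, k + 1, c)
                        if m_next != UNREACHABLE:
                            assert m_now != UNREACHABLE and m_now <= m_next

    def test_pass_counts_bounded_by_totals(self, small_battery):
        for seq, cen in small_battery:
            for a in seq.vertices:
                for c in seq.vertices:
                    if a == c:
                        continue
                    for k in range(1, seq.n_snapshots + 1):
                        sig = cen.sigma(a, k, c)
                        assert (sig > 0) == (cen.m(a, k, c) != UNREACHABLE)
                        for b in seq.vertices:
                            if b not in (a, c):
                                assert 0 <= cen.sigma_through(a, b, c, k) <= sig
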