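"""Backtracking matcher: conditions, enumeration, stats, invariances."""

import math

import pytest

from rimatch.domains import compute_domains
from rimatch.graph import LabeledGraph, from_undirected_edges
from rimatch.matching import (
    MatchMode,
    candidate_targets,
    count_matches,
    enumerate_matches,
    find_matches,
    is_feasible,
)
from rimatch.oracle import brute_force_matches
from rimatch.ordering import VariableOrdering, greatest_constraint_first

from conftest import (
    complete_graph,
    cycle_graph,
    match_set,
    path_graph,
    random_connected_digraph,
    random_labeled_digraph,
    verify_mapping,
)

MONO = MatchMode("monomorphism")
IND = MatchMode("induced")


class TestCandidateTargets:
    def test_root_level_scans_all_target_vertices(self):
        pat = path_graph(2)
        tgt = complete_graph(5)
        o = greatest_constraint_first(pat)
        assert candidate_targets(tgt, o, {}, 0) == set(range(5))

    def test_isolated_parent_image_gives_empty_set(self):
        pat = path_graph(2)
        tgt = LabeledGraph("t", 3, True, ["A"] * 3, {(1, 2)})
        o = greatest_constraint_first(pat)
        partial = {o.mu[0]: 0}
        assert candidate_targets(tgt, o, partial, 1) == set()

    def test_candidates_are_parent_image_neighbors(self):
        pat = path_graph(3)  # mu = (1, 0, 2)
        tgt = complete_graph(3)
        o = greatest_constraint_first(pat)
        assert candidate_targets(tgt, o, {1: 0}, 1) == {1, 2}


class TestIsFeasible:
    def test_used_target_vertex_fails_condition_1(self):
        g = complete_graph(3)
        assert not is_feasible(g, g, {0: 2}, 1, 2, MONO)

    def test_label_mismatch_fails_condition_2(self):
        pat = LabeledGraph("p", 1, True, ["N"], set())
        tgt = LabeledGraph("t", 1, True, ["C"], set())
        assert not is_feasible(pat, tgt, {}, 0, 0, MONO)

    def test_insufficient_out_degree_fails_condition_3(self):
        pat = LabeledGraph("p", 4, True, ["A"] * 4, {(0, 1), (0, 2), (0, 3)})
        tgt = LabeledGraph("t", 3, True, ["A"] * 3, {(0, 1), (0, 2)})
        assert not is_feasible(pat, tgt, {}, 0, 0, MONO)

    def test_directed_degrees_checked_separately(self):
        pat = LabeledGraph("p", 2, True, ["A"] * 2, {(0, 1)})  # out-deg(0)=1
        tgt = LabeledGraph("t", 2, True, ["A"] * 2, {(1, 0)})  # out-deg(0)=0
        assert not is_feasible(pat, tgt, {}, 0, 0, MONO)
        assert is_feasible(pat, tgt, {}, 0, 1, MONO)

    def test_missing_target_edge_fails_condition_4(self):
        pat = path_graph(3)
        tgt = LabeledGraph(
            "t", 3, False, ["A"] * 3, {(0, 1), (1, 0)} | {(1, 2), (2, 1)}
        )
        # map pattern edge 1-0 onto non-adjacent targets 0 and 2
        assert not is_feasible(pat, tgt, {1: 0}, 0, 2, MONO)

    def test_induced_mode_rejects_extra_target_edge(self):
        pat = path_graph(3)  # endpoints 0 and 2 are non-adjacent
        tgt = complete_graph(3)
        partial = {1: 0, 0: 1}
        assert is_feasible(pat, tgt, partial, 2, 2, MONO)
        assert not is_feasible(pat, tgt, partial, 2, 2, IND)


class TestEnumeration:
    def test_identity_single_vertex(self):
        g = LabeledGraph("v", 1, True, ["C"], set())
        matches, stats = enumerate_matches(g, g)
        assert match_set(matches) == {(0,)}
        assert stats.n_matches == 1

    def test_triangle_in_k4_has_24_monomorphisms(self):
        n, stats = count_matches(complete_graph(3), complete_graph(4))
        assert n == 24
        assert stats.n_matches == 24
        assert stats.n_matches <= stats.visited_nodes

    def test_p3_in_k3_mono_6_induced_0(self):
        assert count_matches(path_graph(3), complete_graph(3), MONO)[0] == 6
        assert count_matches(path_graph(3), complete_graph(3), IND)[0] == 0

    def test_label_mismatch_kills_root_level(self):
        pat = LabeledGraph("p", 2, True, ["N", "N"], {(0, 1)})
        tgt = complete_graph(4, label="C")
        n, stats = count_matches(pat, tgt)
        assert n == 0
        assert stats.visited_nodes <= tgt.n_vertices

    def test_pattern_larger_than_target_yields_nothing(self):
        assert count_matches(complete_graph(4), complete_graph(3))[0] == 0

    def test_edgeless_target_blocks_any_edge_pattern(self):
        tgt = LabeledGraph("t", 5, True, ["A"] * 5, set())
        assert count_matches(path_graph(2), tgt)[0] == 0

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("m", [4, 5, 7])
    def test_complete_into_complete_closed_form(self, n, m):
        expected = math.factorial(m) // math.factorial(m - n)
        assert count_matches(complete_graph(n), complete_graph(m))[0] == expected

    def test_induced_cycle_in_cycle(self):
        # C4 occurs induced in C4 in 8 ways (4 rotations x 2 reflections)
        assert count_matches(cycle_graph(4), cycle_graph(4), IND)[0] == 8

    def test_edge_label_toggle_restricts_matches(self):
        pat = LabeledGraph("p", 2, True, ["A", "A"], {(0, 1)}, {(0, 1): "x"})
        tgt = LabeledGraph(
            "t", 3, True, ["A"] * 3, {(0, 1), (1, 2)}, {(0, 1): "x", (1, 2): "y"}
        )
        assert count_matches(pat, tgt, MONO)[0] == 2
        strict = MatchMode("monomorphism", edge_labels_checked=True)
        matches, _ = enumerate_matches(pat, tgt, strict)
        assert match_set(matches) == {(0, 1)}
        assert match_set(brute_force_matches(pat, tgt, strict)) == {(0, 1)}

    def test_disconnected_pattern_rejected(self):
        pat = LabeledGraph("p", 2, True, ["A", "A"], set())
        with pytest.raises(ValueError):
            count_matches(pat, complete_graph(3))

    def test_limit_truncates_stream(self):
        run = find_matches(complete_graph(3), complete_graph(5), limit=7)
        assert len(list(run)) == 7

    def test_timeout_flags_and_truncates(self):
        pat = path_graph(4)
        tgt = complete_graph(9)
        run = find_matches(pat, tgt, timeout=0.0)
        got = list(run)
        assert run.stats.timed_out
        assert run.stats.n_matches == len(got)
        full, _ = enumerate_matches(pat, tgt)
        assert len(got) < len(full)


class TestAgainstOracle:
    @pytest.mark.parametrize("mode", [MONO, IND], ids=["mono", "induced"])
    def test_random_instances_match_brute_force(self, rng, mode):
        for _ in range(40):
            tgt = random_labeled_digraph(rng, int(rng.integers(3, 9)), 0.35, ["A", "B"])
            pat = random_connected_digraph(rng, int(rng.integers(1, 5)), 0.3, ["A", "B"])
            expected = match_set(brute_force_matches(pat, tgt, mode))
            got, _ = enumerate_matches(pat, tgt, mode)
            assert match_set(got) == expected
            for m in got:
                assert verify_mapping(pat, tgt, m, mode)

    def test_induced_matches_subset_of_monomorphisms(self, rng):
        for _ in range(20):
            tgt = random_labeled_digraph(rng, 7, 0.4, ["A", "B"])
            pat = random_connected_digraph(rng, 3, 0.4, ["A", "B"])
            mono = match_set(enumerate_matches(pat, tgt, MONO)[0])
            ind = match_set(enumerate_matches(pat, tgt, IND)[0])
            assert ind <= mono


class TestOrderingAndDomainInvariance:
    @staticmethod
    def _all_valid_orderings(pattern):
        """Every permutation where each vertex after the first touches an
        earlier one, with the earliest-adjacent parent rule."""
        from itertools import permutations

        for perm in permutations(range(pattern.n_vertices)):
            parent = [None] * pattern.n_vertices
            ok = True
            for i in range(1, len(perm)):
                nb = pattern.neighbors(perm[i])
                earlier = [perm[j] for j in range(i) if perm[j] in nb]
                if not earlier:
                    ok = False
                    break
                parent[perm[i]] = earlier[0]
            if ok:
                yield VariableOrdering(mu=perm, parent=tuple(parent))

    def test_match_set_is_ordering_invariant(self, rng):
        for _ in range(5):
            tgt = random_labeled_digraph(rng, 6, 0.5, ["A", "B"])
            pat = random_connected_digraph(rng, 4, 0.4, ["A", "B"])
            reference = match_set(enumerate_matches(pat, tgt)[0])
            for o in self._all_valid_orderings(pat):
                got, _ = enumerate_matches(pat, tgt, ordering=o)
                assert match_set(got) == reference

    def test_domains_change_effort_not_matches(self, rng):
        for _ in range(30):
            tgt = random_labeled_digraph(rng, 8, 0.35, ["A", "B", "C"])
            pat = random_connected_digraph(rng, 4, 0.35, ["A", "B", "C"])
            table = compute_domains(pat, tgt)
            plain, plain_stats = enumerate_matches(pat, tgt)
            with_d, d_stats = enumerate_matches(pat, tgt, domains=table)
            assert match_set(with_d) == match_set(plain)
            assert d_stats.visited_nodes <= plain_stats.visited_nodes
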