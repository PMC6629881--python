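"""Parsimony engine tests: scoring against brute force, search against
exhaustive enumeration, index identities, bootstrap behaviour."""

import itertools

import numpy as np
import pytest

from fossilfit.charmatrix import append_taxon
from fossilfit.parsimony import (
    SearchConfig,
    bootstrap,
    collapse_zero_length_branches,
    encode_matrix,
    enumerate_binary_trees,
    exact_search,
    fitch_length,
    heuristic_search,
    parsimony_stats,
    character_step_bounds,
)
from fossilfit.synthetic_data import gen_matrix_on_tree, random_binary_tree
from fossilfit.trees import parse_newick
from tests.conftest import binary_matrix


def brute_force_length(tree, matrix):
    """Minimum changes over all explicit internal-state assignments."""
    S, ns = encode_matrix(matrix)
    n = tree.n_taxa
    internals = [x for x in tree.adj if x >= n]
    total = 0
    for j in range(matrix.n_characters):
        k = int(ns[j])
        best = None
        for combo in itertools.product(range(k), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            cost = 0
            for u, v in tree.edges():
                if u >= n and v >= n:
                    cost += assign[u] != assign[v]
                else:
                    leaf, internal = (u, v) if u < n else (v, u)
                    cost += not (S[j, leaf] >> assign[internal]) & 1
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestFitchLength:
    def test_invariant_matrix_scores_zero(self):
        m = binary_matrix("ABCDE", [[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]])
        t = random_binary_tree(list("ABCDE"), seed=3)
        assert fitch_length(t, m) == 0

    def test_quartet_matching_and_conflicting_trees(self, quartet_matrix):
        matched = parse_newick("((A,B),(C,D));")
        crossed = parse_newick("((A,C),(B,D));")
        # char 1 splits AB|CD, char 2 splits AC|BD: each tree fits one exactly
        assert fitch_length(matched, quartet_matrix) == 3
        assert fitch_length(crossed, quartet_matrix) == 3
        for tree in (matched, crossed):
            assert fitch_length(tree, quartet_matrix) == brute_force_length(
                tree, quartet_matrix
            )

    def test_matches_brute_force_on_random_cases(self):
        """Fitch equals the exhaustive internal-assignment oracle (200 cases)."""
        rng = np.random.default_rng(2024)
        for case in range(200):
            n = int(rng.integers(4, 7))
            tree = random_binary_tree([f"T{i}" for i in range(n)], seed=case)
            m = gen_matrix_on_tree(
                tree,
                n_characters=3,
                change_prob=0.4,
                missing_prob=0.2,
                seed=case + 10_000,
                n_states=int(rng.integers(2, 4)),
            )
            assert fitch_length(tree, m) == brute_force_length(tree, m)

    def test_all_missing_taxon_does_not_change_length(self):
        tree = random_binary_tree([f"T{i}" for i in range(6)], seed=5)
        m = gen_matrix_on_tree(tree, 15, 0.3, seed=99)
        base = exact_search(m).length
        grown = exact_search(append_taxon(m, "ghost", {})).length
        assert grown == base

    def test_unknown_leaf_rejected(self, quartet_matrix):
        t = parse_newick("((A,B),(C,X));")
        with pytest.raises(ValueError, match="without a matrix row"):
            fitch_length(t, quartet_matrix)


class TestExactSearch:
    def test_single_informative_split(self):
        m = binary_matrix("ABCD", [[0, 0, 1, 1]])
        ts = exact_search(m)
        assert ts.length == 1
        assert len(ts) == 1
        assert ts.trees[0].splits() == parse_newick("((A,B),(C,D));").splits()

    def test_homoplasy_free_matrix_recovers_tree(self):
        taxa = [f"T{i}" for i in range(6)]
        true = random_binary_tree(taxa, seed=11)
        # one clean binary character per nontrivial split
        cols = []
        n = len(taxa)
        for split in true.splits():
            cols.append([(split >> i) & 1 for i in range(n)])
        m = binary_matrix(taxa, cols)
        ts = exact_search(m)
        assert ts.length == len(cols)
        assert parsimony_stats(m, ts.length).CI == 1.0
        assert any(t.splits() == true.splits() for t in ts.trees)

    def test_equals_exhaustive_enumeration(self):
        """Branch-and-bound finds the same length and MPT set as scoring
        all 945 seven-taxon topologies."""
        taxa = [f"T{i}" for i in range(7)]
        for seed in range(5):
            tree = random_binary_tree(taxa, seed=seed)
            m = gen_matrix_on_tree(tree, 15, 0.3, missing_prob=0.1, seed=seed + 70)
            ts = exact_search(m)
            S, _ = encode_matrix(m)
            from fossilfit.parsimony import _fitch_steps

            best, mpts = None, set()
            count = 0
            for t in enumerate_binary_trees(taxa):
                count += 1
                ln = int(_fitch_steps(t, S).sum())
                if best is None or ln < best:
                    best, mpts = ln, {t.splits()}
                elif ln == best:
                    mpts.add(t.splits())
            assert count == 945
            assert ts.length == best
            assert {t.splits() for t in ts.trees} == mpts

    def test_refuses_oversized_matrix(self):
        taxa = [f"T{i}" for i in range(13)]
        m = binary_matrix(taxa, [[i % 2 for i in range(13)]])
        with pytest.raises(ValueError, match="exceeds max_taxa"):
            exact_search(m)


class TestHeuristicSearch:
    def test_matches_exact_on_seeded_benchmark(self):
        """Heuristic attains the exact minimum length on 30/30 seeded
        7-taxon matrices (and never goes below it)."""
        taxa = [f"T{i}" for i in range(7)]
        hits = 0
        for seed in range(1, 31):
            tree = random_binary_tree(taxa, seed=seed)
            m = gen_matrix_on_tree(tree, 20, 0.3, missing_prob=0.1, seed=seed + 500)
            exact = exact_search(m).length
            found = heuristic_search(m, SearchConfig(n_starts=3, ratchet_iterations=2, seed=seed)).length
            assert found >= exact
            hits += found == exact
        assert hits == 30

    def test_deterministic_given_seed(self):
        tree = random_binary_tree([f"T{i}" for i in range(8)], seed=2)
        m = gen_matrix_on_tree(tree, 25, 0.25, seed=42)
        cfg = SearchConfig(n_starts=2, ratchet_iterations=1, seed=9)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert a.length == b.length
        assert {t.splits() for t in a.trees} == {t.splits() for t in b.trees}

    def test_degenerate_matrix_returns_zero_length(self):
        m = binary_matrix("ABCDE", [[0, 0, 0, 0, 0]])
        ts = heuristic_search(m, SearchConfig(n_starts=1, ratchet_iterations=0, seed=1))
        assert ts.length == 0


class TestParsimonyStats:
    def test_hand_example_single_character(self):
        # 4 taxa, one binary character 0,0,1,1: min=1, max=2
        m = binary_matrix("ABCD", [[0, 0, 1, 1]])
        mins, maxs = character_step_bounds(m)
        assert (mins.tolist(), maxs.tolist()) == ([1], [2])
        st = parsimony_stats(m, 1)
        assert st.CI == 1.0 and st.RI == 1.0

    def test_index_identities_exact_arithmetic(self):
        """CI*TL = m and RI*(g-m) = g-TL on random matrices at the exact TL."""
        for seed in range(10):
            tree = random_binary_tree([f"T{i}" for i in range(6)], seed=seed)
            m = gen_matrix_on_tree(tree, 12, 0.35, missing_prob=0.15, seed=seed + 30)
            TL = exact_search(m).length
            st = parsimony_stats(m, TL)
            assert st.CI * st.TL == pytest.approx(st.m)
            assert st.RI * (st.g - st.m) == pytest.approx(st.g - st.TL)
            assert st.m <= TL <= st.g

    def test_polymorphic_cells_counted_generously(self):
        # A,B observed 0; C polymorphic {0,1}; D observed 1
        m = binary_matrix("ABCD", [[0, 0, {0, 1}, 1]])
        mins, maxs = character_step_bounds(m)
        # singleton states {0,1} -> min 1; best shared state 0 covers A,B,C -> max 4-3=1
        assert (mins.tolist(), maxs.tolist()) == ([1], [1])

    def test_tl_below_minimum_is_error(self):
        m = binary_matrix("ABCD", [[0, 0, 1, 1]])
        with pytest.raises(ValueError, match="below theoretical minimum"):
            parsimony_stats(m, 0)


class TestCollapse:
    def test_unsupported_branch_collapses(self):
        # no character supports any split: every internal branch collapses
        m = binary_matrix("ABCD", [[0, 0, 0, 0]])
        t = parse_newick("((A,B),(C,D));")
        collapsed = collapse_zero_length_branches(t, m)
        assert collapsed.splits() == frozenset()

    def test_supported_branch_retained(self, quartet_matrix):
        t = parse_newick("((A,B),(C,D));")
        collapsed = collapse_zero_length_branches(t, quartet_matrix)
        assert collapsed.splits() == t.splits()


class TestBootstrap:
    def test_universally_supported_split_is_certain(self):
        """A split implied by every character gets 100% support at any seed."""
        cols = [[0, 0, 1, 1, 1]] * 10
        m = binary_matrix("ABCDE", cols)
        for seed in (1, 99):
            bs = bootstrap(m, n_replicates=20, seed=seed)
            assert bs.support_of("AB") == 100.0

    def test_conflicting_characters_order_supports(self):
        """Characters supporting one split 9:1 over a conflicting one rank
        the bootstrap supports accordingly."""
        ab = [0, 0, 1, 1, 1]
        ac = [0, 1, 0, 1, 1]
        m = binary_matrix("ABCDE", [ab] * 9 + [ac])
        bs = bootstrap(m, n_replicates=100, seed=7)
        assert bs.support_of("AB") > bs.support_of("AC")
        assert bs.support_of("AB") > 90.0

    def test_deterministic_given_seed(self):
        m = binary_matrix("ABCDE", [[0, 0, 1, 1, 1], [0, 1, 0, 1, 1]] * 3)
        a = bootstrap(m, n_replicates=25, seed=3)
        b = bootstrap(m, n_replicates=25, seed=3)
        assert a.supports == b.supports
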