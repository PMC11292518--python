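import itertools

import numpy as np
import pytest

from aquaconv.alignment import AMINO_ACIDS, ProteinAlignment, read_fasta_alignment
from aquaconv.convergence import (
    classify_convergent_genes,
    ConvergenceTestResult,
    count_observed_convergent,
    expected_convergent,
    independent_branch_pairs,
    poisson_convergence_test,
    screen_specific_substitutions,
)
from aquaconv.likelihood import AncestralPosteriors
from aquaconv.model import SubstitutionModel
from aquaconv.tree import TraitConfig, read_newick


def _aln(rows: dict[str, str]) -> ProteinAlignment:
    return read_fasta_alignment("".join(f">{k}\n{v}\n" for k, v in rows.items()))


SIX_TRAIT = TraitConfig(
    foreground_species={"f1", "f2", "f3"},
    background_species={"b1", "b2"},
    exempt_species={"x"},
)


class TestScreen:
    def test_definition_case(self):
        aln = _aln({"f1": "T", "f2": "T", "f3": "T", "b1": "A", "b2": "A", "x": "W"})
        sites = screen_specific_substitutions(aln, SIX_TRAIT)
        assert len(sites) == 1
        assert sites[0].foreground_state == "T" and sites[0].background_state == "A"
        assert dict(sites[0].exempt_states) == {"x": "W"}

    def test_identical_column_not_candidate(self):
        aln = _aln({k: "A" for k in ["f1", "f2", "f3", "b1", "b2", "x"]})
        assert screen_specific_substitutions(aln, SIX_TRAIT) == []

    def test_gap_in_non_exempt_species_disqualifies(self):
        aln = _aln({"f1": "T", "f2": "T", "f3": "T", "b1": "-", "b2": "A", "x": "W"})
        assert screen_specific_substitutions(aln, SIX_TRAIT) == []

    def test_gap_in_exempt_species_allowed(self):
        aln = _aln({"f1": "T", "f2": "T", "f3": "T", "b1": "A", "b2": "A", "x": "-"})
        assert len(screen_specific_substitutions(aln, SIX_TRAIT)) == 1

    def test_empty_group_rejected(self):
        aln = _aln({"f1": "T", "b1": "A"})
        with pytest.raises(ValueError):
            screen_specific_substitutions(
                aln, TraitConfig(foreground_species={"f1"}, background_species=set())
            )

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        names = ["f1", "f2", "f3", "b1", "b2", "x"]
        codes = rng.integers(0, 22, size=(6, 30)).astype(np.uint8)
        aln = ProteinAlignment("g", names, codes)
        got = {s.column for s in screen_specific_substitutions(aln, SIX_TRAIT)}
        expected = set()
        for col in range(30):
            fg = codes[:3, col]
            bg = codes[3:5, col]
            if (
                len(set(fg)) == 1 and fg[0] < 20
                and len(set(bg)) == 1 and bg[0] < 20
                and fg[0] != bg[0]
            ):
                expected.add(col)
        assert got == expected

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 21, size=(6, 40)).astype(np.uint8)
        names = ["f1", "f2", "f3", "b1", "b2", "x"]
        aln = ProteinAlignment("g", names, codes)
        perm = rng.permutation(40)
        aln_p = ProteinAlignment("g", names, codes[:, perm])
        before = {s.column for s in screen_specific_substitutions(aln, SIX_TRAIT)}
        after = {s.column for s in screen_specific_substitutions(aln_p, SIX_TRAIT)}
        assert after == {int(np.flatnonzero(perm == c)[0]) for c in before}

    def test_adding_exempt_species_never_removes_candidates(self):
        rng = np.random.default_rng(5)
        names = ["f1", "f2", "f3", "b1", "b2", "x", "y"]
        codes = rng.integers(0, 21, size=(7, 60)).astype(np.uint8)
        aln = ProteinAlignment("g", names, codes)
        base = TraitConfig(
            foreground_species={"f1", "f2", "f3"},
            background_species={"b1", "b2", "y"},
            exempt_species={"x"},
        )
        wider = TraitConfig(
            foreground_species={"f1", "f2", "f3"},
            background_species={"b1", "b2"},
            exempt_species={"x", "y"},
        )
        before = {s.column for s in screen_specific_substitutions(aln, base)}
        after = {s.column for s in screen_specific_substitutions(aln, wider)}
        assert before <= after


class TestBranchPairs:
    def test_nesting_rule_on_mammal_tree(self, mammal_tree_and_trait):
        tree, trait = mammal_tree_and_trait
        pairs = independent_branch_pairs(tree, trait)
        names = {frozenset((tree.names[a], tree.names[b])) for a, b in pairs}
        assert frozenset(("Tursiops_truncatus", "Cetacea")) not in names
        assert frozenset(("Balaenoptera_musculus", "Cetacea")) not in names
        assert frozenset(("Trichechus_senegalensis", "Cetacea")) in names
        assert frozenset(("Tursiops_truncatus", "Balaenoptera_musculus")) in names
        assert len(pairs) == 4

    def test_single_branch_gives_no_pairs(self):
        tree = read_newick("((A:1,B:1)AB:1,C:1);")
        trait = TraitConfig(
            foreground_species={"A"}, background_species={"C"}, foreground_branches={"A"}
        )
        assert independent_branch_pairs(tree, trait) == []

    def test_three_independent_branches_give_three_pairs(self):
        tree = read_newick("((A:1,B:1)AB:1,(C:1,D:1)CD:1);")
        trait = TraitConfig(
            foreground_species={"A", "B", "C"},
            background_species={"D"},
            foreground_branches={"A", "B", "C"},
        )
        assert len(independent_branch_pairs(tree, trait)) == 3


def _point_mass_posteriors(tree, states_by_node):
    """Posteriors with probability one on given states: (node -> list of
    state letters, one per site)."""
    L = len(next(iter(states_by_node.values())))
    post = np.zeros((tree.n_nodes, L, 20))
    for v, letters in states_by_node.items():
        for s, ch in enumerate(letters):
            post[v, s, AMINO_ACIDS.index(ch)] = 1.0
    K = 4
    return AncestralPosteriors(tree, post, np.full((L, K), 1 / K), 0.0)


class TestObservedCount:
    @pytest.fixture
    def tree(self):
        return read_newick("((A:0.1,B:0.1)AB:0.1,(C:0.1,D:0.1)CD:0.1);")

    def test_parallel_change_counts(self, tree):
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        ab, cd = tree.node_by_name("AB"), tree.node_by_name("CD")
        post = _point_mass_posteriors(
            tree,
            {a: "T", c: "T", ab: "A", cd: "A",
             tree.node_by_name("B"): "A", tree.node_by_name("D"): "A",
             tree.root: "A"},
        )
        assert count_observed_convergent(post, tree, [(a, c)], [0]) == 1

    def test_strictly_convergent_change_counts(self, tree):
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        ab, cd = tree.node_by_name("AB"), tree.node_by_name("CD")
        post = _point_mass_posteriors(
            tree,
            {a: "T", c: "T", ab: "A", cd: "S",
             tree.node_by_name("B"): "A", tree.node_by_name("D"): "S",
             tree.root: "A"},
        )
        assert count_observed_convergent(post, tree, [(a, c)], [0]) == 1
        # the strict flag keeps it too (ancestors differ)
        assert count_observed_convergent(
            post, tree, [(a, c)], [0], strict_convergent_only=True
        ) == 1

    def test_parallel_excluded_under_strict_flag(self, tree):
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        ab, cd = tree.node_by_name("AB"), tree.node_by_name("CD")
        post = _point_mass_posteriors(
            tree,
            {a: "T", c: "T", ab: "A", cd: "A",
             tree.node_by_name("B"): "A", tree.node_by_name("D"): "A",
             tree.root: "A"},
        )
        assert count_observed_convergent(
            post, tree, [(a, c)], [0], strict_convergent_only=True
        ) == 0

    def test_no_substitution_on_one_branch_counts_zero(self, tree):
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        ab, cd = tree.node_by_name("AB"), tree.node_by_name("CD")
        post = _point_mass_posteriors(
            tree,
            {a: "T", c: "T", ab: "T", cd: "A",
             tree.node_by_name("B"): "T", tree.node_by_name("D"): "A",
             tree.root: "A"},
        )
        assert count_observed_convergent(post, tree, [(a, c)], [0]) == 0

    def test_site_out_of_range_rejected(self, tree):
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        post = _point_mass_posteriors(tree, {v: "A" for v in range(tree.n_nodes)})
        with pytest.raises(IndexError):
            count_observed_convergent(post, tree, [(a, c)], [5])


class TestExpectedCount:
    def test_zero_length_branches_give_zero(self, jtt_model):
        tree = read_newick("((A:0,B:0.1)AB:0.1,(C:0,D:0.1)CD:0.1);")
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        rng = np.random.default_rng(0)
        post_arr = rng.dirichlet(np.ones(20), size=(tree.n_nodes, 2))
        post = AncestralPosteriors(tree, post_arr, np.full((2, 4), 0.25), 0.0)
        E = expected_convergent(post, jtt_model, tree, [(a, c)])
        assert E == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_triple_sum(self, jtt_model):
        tree = read_newick("((A:0.3,B:0.1)AB:0.1,(C:0.5,D:0.1)CD:0.1);")
        a, c = tree.node_by_name("A"), tree.node_by_name("C")
        rng = np.random.default_rng(1)
        post_arr = rng.dirichlet(np.ones(20), size=(tree.n_nodes, 1))
        w = rng.dirichlet(np.ones(4), size=1)
        post = AncestralPosteriors(tree, post_arr, w, 0.0)
        E = expected_convergent(post, jtt_model, tree, [(a, c)])

        P1 = jtt_model.transition_matrices(float(tree.branch_length[a]))
        P2 = jtt_model.transition_matrices(float(tree.branch_length[c]))
        p1 = post_arr[tree.parent[a], 0]
        p2 = post_arr[tree.parent[c], 0]
        expected = 0.0
        for k in range(4):
            for a1, a2, d in itertools.product(range(20), repeat=3):
                if d == a1 or d == a2:
                    continue
                expected += w[0, k] * p1[a1] * p2[a2] * P1[k, a1, d] * P2[k, a2, d]
        assert E == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_branch_length(self, jtt_model):
        rng = np.random.default_rng(2)
        post_arr = rng.dirichlet(np.ones(20), size=(7, 1))
        w = np.full((1, 4), 0.25)
        values = []
        for t in [0.01, 0.05, 0.2, 0.5]:
            tree = read_newick(f"((A:{t},B:0.1)AB:0.1,(C:0.3,D:0.1)CD:0.1);")
            a, c = tree.node_by_name("A"), tree.node_by_name("C")
            post = AncestralPosteriors(tree, post_arr, w, 0.0)
            values.append(expected_convergent(post, jtt_model, tree, [(a, c)]))
        assert all(x < y for x, y in zip(values, values[1:]))


class TestPoissonTest:
    def test_zero_observed_gives_one(self):
        assert poisson_convergence_test(0, 3.7) == (1.0, False)

    def test_series_oracle(self):
        # P(X >= 3 | E=0.5) = 1 - e^-0.5 (1 + 0.5 + 0.5^2/2)
        p, flag = poisson_convergence_test(3, 0.5)
        expected = 1.0 - np.exp(-0.5) * (1 + 0.5 + 0.125)
        assert not flag
        assert p == pytest.approx(expected, rel=1e-12)

    def test_degenerate_expectation_flagged(self):
        p, flag = poisson_convergence_test(2, 0.0)
        assert p == 0.0 and flag

    def test_monotonicity(self):
        ps_in_o = [poisson_convergence_test(o, 1.0)[0] for o in range(6)]
        assert all(x >= y for x, y in zip(ps_in_o, ps_in_o[1:]))
        ps_in_e = [poisson_convergence_test(3, e)[0] for e in [0.1, 0.5, 1.0, 2.0]]
        assert all(x <= y for x, y in zip(ps_in_e, ps_in_e[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_convergence_test(-1, 1.0)


class TestClassification:
    def _result(self, gene, p, n_sites=1):
        return ConvergenceTestResult(
            gene_id=gene, branch_pairs=[], candidate_sites=[object()] * n_sites,
            observed=1, expected=0.5, p_value=p,
        )

    def test_strict_threshold(self):
        res = [self._result("a", 0.049), self._result("b", 0.05)]
        out = classify_convergent_genes(res)
        assert out.convergent == {"a"} and out.specific_only == {"b"}

    def test_empty_input(self):
        out = classify_convergent_genes([])
        assert out.convergent == set() and out.specific_only == set()

    def test_genes_without_candidates_unclassified(self):
        r = ConvergenceTestResult("g", [], [], 0, 0.0, 1.0)
        out = classify_convergent_genes([r])
        assert r.classification is None
        assert "g" not in out.convergent | out.specific_only
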