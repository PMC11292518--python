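import itertools

import numpy as np
import pandas as pd
import pytest

from aquaconv.rer import (
    RERAssociation,
    accelerated_gene_filter,
    binary_trait_association,
    build_master_tree,
    compute_rers,
)
from aquaconv.tree import read_newick

NWK = "((A:0.1,B:0.2)AB:0.15,(C:0.3,D:0.25)CD:0.1);"


def _tree_scaled(per_branch: dict[str, float] | None = None, scale: float = 1.0):
    t = read_newick(NWK)
    bl = t.branch_length.copy()
    bl[:-1] *= scale
    if per_branch:
        for name, f in per_branch.items():
            bl[t.node_by_name(name)] *= f
    return t.with_branch_lengths(bl)


class TestMasterTree:
    def test_branchwise_mean(self):
        trees = {"g1": _tree_scaled(scale=1.0), "g2": _tree_scaled(scale=3.0)}
        master = build_master_tree(trees)
        t = _tree_scaled()
        np.testing.assert_allclose(
            master.tree.branch_length[:-1], 2.0 * t.branch_length[:-1]
        )

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            build_master_tree({"g1": _tree_scaled()})

    def test_idempotent_on_identical_trees(self):
        trees = {f"g{i}": _tree_scaled() for i in range(5)}
        master = build_master_tree(trees)
        np.testing.assert_allclose(
            master.tree.branch_length[:-1], _tree_scaled().branch_length[:-1]
        )

    def test_topology_mismatch_names_gene(self):
        other = read_newick("((A:0.1,C:0.2):0.15,(B:0.3,D:0.25):0.1);")
        with pytest.raises(ValueError, match="g2"):
            build_master_tree({"g1": _tree_scaled(), "g2": other})


class TestComputeRers:
    def test_proportional_gene_has_zero_rers(self):
        trees = {"g1": _tree_scaled(scale=1.0), "g2": _tree_scaled(scale=4.0)}
        master = build_master_tree(trees)
        rers = compute_rers(trees, master)
        assert np.nanmax(np.abs(rers.to_numpy())) <= 1e-6

    def test_doubled_branch_is_most_positive(self):
        trees = {f"g{i}": _tree_scaled() for i in range(9)}
        trees["gx"] = _tree_scaled(per_branch={"C": 2.0})
        master = build_master_tree(trees)
        rers = compute_rers(trees, master)
        assert rers["gx"].idxmax() == "C"
        assert rers["gx"]["C"] > 0

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(0)
        trees = {}
        for i in range(6):
            t = _tree_scaled()
            bl = t.branch_length.copy()
            bl[:-1] *= rng.lognormal(0, 0.3, size=t.n_nodes - 1)
            trees[f"g{i}"] = t.with_branch_lengths(bl)
        master = build_master_tree(trees)
        rers = compute_rers(trees, master)
        # standardized residuals of an intercept fit are centred per gene
        sums = rers.sum(axis=0).to_numpy()
        assert np.abs(sums).max() < 1e-6 * rers.shape[0]

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = {}
        for i in range(5):
            t = _tree_scaled()
            bl = t.branch_length.copy()
            bl[:-1] *= rng.lognormal(0, 0.4, size=t.n_nodes - 1)
            base[f"g{i}"] = t.with_branch_lengths(bl)
        scaled = {
            g: t.with_branch_lengths(
                np.where(np.isfinite(t.branch_length), t.branch_length * 7.0, np.nan)
            )
            for g, t in base.items()
        }
        r1 = compute_rers(base, build_master_tree(base))
        r2 = compute_rers(scaled, build_master_tree(scaled))
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)

    def test_too_few_branches_gives_missing_column(self):
        t = _tree_scaled()
        bl = t.branch_length.copy()
        bl[:3] = np.nan
        bl[4] = np.nan
        sparse = t.with_branch_lengths(bl)
        trees = {"full": _tree_scaled(), "full2": _tree_scaled(scale=2.0), "sparse": sparse}
        master = build_master_tree(trees)
        with pytest.warns(UserWarning):
            rers = compute_rers(trees, master, min_branches=3)
        assert rers["sparse"].isna().all()


class TestAssociation:
    def _matrix(self, fg_vals, bg_vals):
        branches = [f"f{i}" for i in range(len(fg_vals))] + [
            f"b{i}" for i in range(len(bg_vals))
        ]
        return (
            pd.DataFrame({"gene": list(fg_vals) + list(bg_vals)}, index=branches),
            [f"f{i}" for i in range(len(fg_vals))],
        )

    def test_complete_separation_gives_rho_one(self):
        rers, fg = self._matrix([2.0, 3.0], [-1.0, 0.0, 1.0])
        (a,) = binary_trait_association(rers, fg)
        assert a.rho == pytest.approx(1.0)

    def test_reversed_separation_gives_rho_minus_one(self):
        rers, fg = self._matrix([-2.0, -3.0], [0.0, 1.0, 2.0])
        (a,) = binary_trait_association(rers, fg)
        assert a.rho == pytest.approx(-1.0)

    def test_insufficient_branches_flagged(self):
        rers, fg = self._matrix([1.0], [0.0, 0.5])
        (a,) = binary_trait_association(rers, fg)
        assert a.reason == "insufficient branches"
        assert np.isnan(a.rho)

    def test_exact_p_matches_exhaustive_permutation(self):
        # n <= 8 with no ties: the rank-sum null can be enumerated exactly
        rng = np.random.default_rng(4)
        vals = rng.normal(size=7)
        rers, fg = self._matrix(vals[:3], vals[3:])
        (a,) = binary_trait_association(rers, fg)

        def u_stat(fgv, bgv):
            return sum(1.0 for x in fgv for y in bgv if x > y)

        obs = u_stat(vals[:3], vals[3:])
        n1 = 3
        count = 0
        total = 0
        for comb in itertools.combinations(range(7), n1):
            fgv = [vals[i] for i in comb]
            bgv = [vals[i] for i in range(7) if i not in comb]
            u = u_stat(fgv, bgv)
            # two-sided: as or more extreme in either direction
            if min(u, n1 * 4 - u) <= min(obs, n1 * 4 - obs):
                count += 1
            total += 1
        assert a.p_value == pytest.approx(count / total, rel=1e-9)

    def test_null_pvalues_approximately_uniform(self, mammal_tree_and_trait):
        # gene trees = master branch lengths with multiplicative noise;
        # exchangeable foreground/background implies uniform p-values
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        t, trait = mammal_tree_and_trait
        n_branches = t.n_nodes - 1
        trees = {}
        for i in range(500):
            bl = t.branch_length.copy()
            bl[:-1] *= rng.lognormal(0, 0.35, size=n_branches)
            trees[f"g{i}"] = t.with_branch_lengths(bl)
        master = build_master_tree(trees)
        rers = compute_rers(trees, master)
        assocs = binary_trait_association(rers, trait.foreground_branches)
        pvals = [a.p_value for a in assocs if a.reason is None]
        assert kstest(pvals, "uniform").statistic < 0.1


class TestFilter:
    def _a(self, gene, rho, p):
        return RERAssociation(gene, rho, p, 4, 30)

    def test_rules(self):
        assocs = [
            self._a("in", 0.4, 0.01),
            self._a("wrong_direction", -0.4, 0.001),
            self._a("boundary_p", 0.4, 0.05),
            self._a("boundary_rho", 0.0, 0.01),
        ]
        assert accelerated_gene_filter(assocs) == {"in"}

    def test_flagged_genes_never_pass(self):
        a = RERAssociation("g", np.nan, np.nan, 1, 2, reason="insufficient branches")
        assert accelerated_gene_filter([a]) == set()
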