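"""Relative evolutionary rates (RERs) and binary-trait association.

A gene's RERs are the standardized residuals of a per-gene regression of
square-root-transformed gene branch lengths on the square-root-transformed
genome-wide average ("master") branch lengths.  A positive RER on a branch
means the gene evolved faster on that branch than the genome-wide trend
predicts.  Association with a binary trait is a Wilcoxon rank-sum test of
foreground-branch RERs against background-branch RERs, with a rank-biserial
effect size (Rho) signed positive when foreground branches are faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .tree import SpeciesTree

__all__ = [
    "MasterTree",
    "RERAssociation",
    "build_master_tree",
    "compute_rers",
    "binary_trait_association",
    "accelerated_gene_filter",
]


@dataclass
class MasterTree:
    """Topology with per-branch average lengths across genes."""

    tree: SpeciesTree
    n_genes_per_branch: np.ndarray


@dataclass
class RERAssociation:
    gene_id: str
    rho: float
    p_value: float
    n_foreground: int
    n_background: int
    reason: str | None = None  # set when the test could not be run


def _check_same_topology(ref: SpeciesTree, other: SpeciesTree, gene: str) -> None:
    if ref.n_nodes != other.n_nodes or ref.names != other.names or not np.array_equal(
        ref.parent, other.parent
    ):
        raise ValueError(f"gene {gene!r}: tree topology differs from the reference")


def build_master_tree(gene_trees: dict[str, SpeciesTree]) -> MasterTree:
    """Average branch lengths across genes (branch-wise arithmetic mean,
    ignoring genes where a branch is missing)."""
    if len(gene_trees) < 2:
        raise ValueError("need at least two gene trees to average")
    genes = list(gene_trees)
    ref = gene_trees[genes[0]]
    n = ref.n_nodes
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for g in genes:
        t = gene_trees[g]
        _check_same_topology(ref, t, g)
        bl = t.branch_length
        ok = np.isfinite(bl)
        total[ok] += bl[ok]
        count[ok] += 1
    mean = np.full(n, np.nan)
    present = count > 0
    mean[present] = total[present] / count[present]
    mean[ref.root] = np.nan
    return MasterTree(tree=ref.with_branch_lengths(mean), n_genes_per_branch=count)


def compute_rers(
    gene_trees: dict[str, SpeciesTree],
    master: MasterTree,
    *,
    min_branches: int = 3,
) -> pd.DataFrame:
    """Branches x genes matrix of relative-rate residuals.

    Per gene: sqrt-transform gene and master branch lengths, regress gene on
    master by ordinary least squares with an intercept over branches present
    in both, and report residuals standardized by the fit's residual
    standard deviation.  Genes with fewer than ``min_branches`` usable
    branches get an all-missing column (with a warning).
    """
    ref = master.tree
    branch_ids = [v for v in range(ref.n_nodes) if v != ref.root]
    m = np.sqrt(ref.branch_length[branch_ids])
    data = {}
    for gene, t in gene_trees.items():
        _check_same_topology(ref, t, gene)
        g = t.branch_length[branch_ids]
        usable = np.isfinite(g) & np.isfinite(m)
        col = np.full(len(branch_ids), np.nan)
        if usable.sum() < min_branches:
            warnings.warn(f"gene {gene!r}: fewer than {min_branches} usable branches")
            data[gene] = col
            continue
        if usable.sum() < 10:
            warnings.warn(f"gene {gene!r}: only {int(usable.sum())} branches in RER fit")
        y = np.sqrt(g[usable])
        x = m[usable]
        X = np.column_stack([np.ones(x.size), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(int(usable.sum()) - 2, 1)
        sd = float(np.sqrt((resid**2).sum() / dof))
        col[usable] = resid / sd if sd > 1e-12 else 0.0
        data[gene] = col
    labels = [ref.names[v] or f"node{v}" for v in branch_ids]
    return pd.DataFrame(data, index=pd.Index(labels, name="branch"))


def _rank_biserial(fg: np.ndarray, bg: np.ndarray) -> float:
    """Rank-biserial effect size from the Mann-Whitney U of fg vs bg:
    2*U1/(n1*n2) - 1, positive when foreground values are larger."""
    u1 = mannwhitneyu(fg, bg, alternative="two-sided").statistic
    return float(2.0 * u1 / (len(fg) * len(bg)) - 1.0)


def binary_trait_association(
    rers: pd.DataFrame,
    foreground_branches: set[str] | list[str],
) -> list[RERAssociation]:
    """Per gene, test foreground-branch RERs against background-branch RERs.

    Wilcoxon rank-sum, two-sided; exact null for small untied samples,
    otherwise the tie-corrected normal approximation.  Requires at least two
    foreground and two background branches with data.
    """
    fg_set = set(foreground_branches)
    missing = fg_set - set(rers.index)
    if missing:
        raise ValueError(f"foreground branches absent from RER matrix: {sorted(missing)}")
    is_fg = rers.index.isin(fg_set)
    out: list[RERAssociation] = []
    for gene in rers.columns:
        col = rers[gene].to_numpy()
        ok = np.isfinite(col)
        fg = col[ok & is_fg]
        bg = col[ok & ~is_fg]
        if len(fg) < 2 or len(bg) < 2:
            out.append(
                RERAssociation(gene, np.nan, np.nan, len(fg), len(bg), reason="insufficient branches")
            )
            continue
        test = mannwhitneyu(fg, bg, alternative="two-sided", method="auto")
        rho = float(2.0 * test.statistic / (len(fg) * len(bg)) - 1.0)
        out.append(RERAssociation(gene, rho, float(test.pvalue), len(fg), len(bg)))
    return out


def accelerated_gene_filter(
    assocs: list[RERAssociation], rho_min: float = 0.0, p_max: float = 0.05
) -> set[str]:
    """Genes with Rho > rho_min and p < p_max (both strict): convergently
    accelerated in the foreground lineages."""
    return {
        a.gene_id
        for a in assocs
        if a.reason is None and np.isfinite(a.rho) and a.rho > rho_min and a.p_value < p_max
    }
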