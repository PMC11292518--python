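"""Calibration studies: operating characteristics on synthetic data.

Each study simulates data under known truth on the packaged 19-mammal tree
and pushes it through the full inference path, reporting detection
sensitivity, false-positive behaviour and null-distribution calibration.
These are the package's standing evidence that the pipeline behaves as a
frequentist screen should; they are re-run by the test suite and by
``scripts/acceptance.py``.

Problem sizes follow the package's standard study design: 500 null genes of
500 columns for the convergence stage, 50 accelerated plus 200 null genes of
2,000 columns for the RER stage, and a million-site variant table for the
heterozygosity estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .brlen import estimate_branch_lengths
from .convergence import test_gene_convergence
from .model import SubstitutionModel
from .rer import (
    accelerated_gene_filter,
    binary_trait_association,
    build_master_tree,
    compute_rers,
)
from .selection import genome_heterozygosity
from .simulate import (
    fixture_tree_19_species,
    inject_convergence,
    simulate_accelerated_gene,
    simulate_alignment,
    simulate_variant_table,
)

__all__ = [
    "convergence_calibration",
    "rer_calibration",
    "heterozygosity_calibration",
]

# the calibration studies run the branch-length optimiser at a sweep
# tolerance matched to the ~1e-5 noise floor of its 1-D searches; tighter
# settings only chase that noise (lengths change by < 0.1%)
_CALIBRATION_BRLEN_TOL = 1e-4


def convergence_calibration(
    n_null: int = 500,
    n_injected: int = 50,
    n_sites: int = 500,
    n_injected_sites: int = 3,
    alpha: float = 1.0,
    p_threshold: float = 0.05,
    seed: int = 1,
) -> dict:
    """Type-I behaviour and sensitivity of the convergence test.

    Null genes are simulated with no injected convergence; the reported
    false-positive rate is the fraction of *screen-passing* null genes whose
    Poisson p falls below the threshold.  Injected genes carry
    ``n_injected_sites`` convergent columns each; sensitivity is the
    fraction called convergent.
    """
    tree, trait = fixture_tree_19_species()
    model_base = SubstitutionModel.jtt(alpha=alpha)
    rng = np.random.default_rng(seed)

    n_screen_passing = 0
    n_false = 0
    null_pvals = []
    for i in range(n_null):
        aln, _ = simulate_alignment(
            tree, model_base, n_sites, int(rng.integers(2**31)), gene_id=f"null{i:04d}"
        )
        res = test_gene_convergence(aln, tree, trait, SubstitutionModel.jtt_f(aln, alpha=alpha))
        if res.candidate_sites:
            n_screen_passing += 1
            null_pvals.append(res.p_value)
            if res.p_value < p_threshold:
                n_false += 1

    n_detected = 0
    for i in range(n_injected):
        aln, truth = simulate_alignment(
            tree, model_base, n_sites, int(rng.integers(2**31)), gene_id=f"conv{i:04d}"
        )
        aln, truth = inject_convergence(
            aln, truth, trait, n_injected_sites, int(rng.integers(2**31))
        )
        res = test_gene_convergence(aln, tree, trait, SubstitutionModel.jtt_f(aln, alpha=alpha))
        if res.candidate_sites and res.p_value < p_threshold:
            n_detected += 1

    return {
        "n_null": n_null,
        "n_screen_passing_null": n_screen_passing,
        "null_fpr": (n_false / n_screen_passing) if n_screen_passing else 0.0,
        "n_injected": n_injected,
        "sensitivity": n_detected / n_injected if n_injected else float("nan"),
    }


def rer_calibration(
    n_null: int = 200,
    n_accelerated: int = 50,
    n_sites: int = 2000,
    factor: float = 2.0,
    alpha: float = 1.0,
    rho_min: float = 0.0,
    p_threshold: float = 0.05,
    seed: int = 1,
) -> dict:
    """Sensitivity, false-positive rate and null calibration of the RER
    association.

    Gene trees are ML-estimated from simulated alignments.  Sensitivity and
    the false-positive rate are measured on the realistic mixture (master
    tree averaged over all genes, accelerated included).  Null p-value
    uniformity is measured against a master built from the null genes alone:
    with a fifth of genes accelerated, the mixture master's foreground
    branches are systematically inflated, which pushes null genes toward
    negative Rho — a direction the Rho > 0 rule discards, but one that would
    make a uniformity check on the contaminated run meaningless.
    """
    tree, trait = fixture_tree_19_species()
    model_base = SubstitutionModel.jtt(alpha=alpha)
    rng = np.random.default_rng(seed)

    gene_trees: dict[str, object] = {}
    labels: dict[str, str] = {}
    for i in range(n_null):
        gid = f"null{i:04d}"
        aln, _ = simulate_alignment(
            tree, model_base, n_sites, int(rng.integers(2**31)), gene_id=gid
        )
        fit = estimate_branch_lengths(
            tree, aln, SubstitutionModel.jtt_f(aln, alpha=alpha), tol=_CALIBRATION_BRLEN_TOL
        )
        gene_trees[gid] = fit.tree
        labels[gid] = "null"
    for i in range(n_accelerated):
        gid = f"accel{i:04d}"
        aln, _ = simulate_accelerated_gene(
            tree, factor, trait.foreground_branches, model_base, n_sites,
            int(rng.integers(2**31)), gene_id=gid,
        )
        fit = estimate_branch_lengths(
            tree, aln, SubstitutionModel.jtt_f(aln, alpha=alpha), tol=_CALIBRATION_BRLEN_TOL
        )
        gene_trees[gid] = fit.tree
        labels[gid] = "accelerated"

    # realistic mixture: master over all genes
    master = build_master_tree(gene_trees)
    rers = compute_rers(gene_trees, master)
    assocs = binary_trait_association(rers, trait.foreground_branches)
    called = accelerated_gene_filter(assocs, rho_min=rho_min, p_max=p_threshold)
    n_tp = sum(1 for g in called if labels[g] == "accelerated")
    n_fp = sum(1 for g in called if labels[g] == "null")

    # null calibration: master from null genes only
    null_trees = {g: t for g, t in gene_trees.items() if labels[g] == "null"}
    null_master = build_master_tree(null_trees)
    null_rers = compute_rers(null_trees, null_master)
    null_assocs = binary_trait_association(null_rers, trait.foreground_branches)
    null_pvals = np.array([a.p_value for a in null_assocs if a.reason is None])
    ks = kstest(null_pvals, "uniform").statistic if null_pvals.size else float("nan")

    return {
        "n_null": n_null,
        "n_accelerated": n_accelerated,
        "sensitivity": n_tp / n_accelerated if n_accelerated else float("nan"),
        "fpr": n_fp / n_null if n_null else float("nan"),
        "ks_null": float(ks),
    }


def heterozygosity_calibration(
    n_sites: int = 1_000_000,
    het_rate: float = 5e-4,
    depth_mean: float = 45.0,
    min_depth: int = 10,
    seed: int = 1,
) -> dict:
    """Recovery of a known heterozygosity rate through the depth filter."""
    sites = simulate_variant_table(n_sites, het_rate, depth_mean, seed)
    result = genome_heterozygosity(sites, min_depth=min_depth)
    se = float(np.sqrt(het_rate * (1 - het_rate) / max(result.n_sites, 1)))
    return {
        "estimate": result.ratio,
        "truth": het_rate,
        "binomial_se": se,
        "n_sites_passing": result.n_sites,
        "abs_error_in_se": abs(result.ratio - het_rate) / se if result.ratio is not None else float("nan"),
    }
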