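"""End-to-end orchestration: screen -> convergence test -> RER -> filters.

Stages communicate only through written tables, so deleting a downstream
table and re-running regenerates it identically; per-gene failures are
logged and quarantined rather than aborting the run.
"""

from __future__ import annotations

import glob
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import ProteinAlignment, read_fasta_file
from .brlen import estimate_branch_lengths
from .convergence import classify_convergent_genes, test_gene_convergence
from .model import SubstitutionModel
from .rer import accelerated_gene_filter, binary_trait_association, build_master_tree, compute_rers
from .selection import (
    genome_heterozygosity,
    read_scan_table,
    read_vcf_variants,
    select_positively_selected_genes,
    combine_gene_sets,
)
from .tree import SpeciesTree, TraitConfig, read_newick_file

log = logging.getLogger("aquaconv.pipeline")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    alignment_dir: str
    tree: str
    trait_config: str
    out_dir: str
    scan_table: str | None = None
    vcf: str | None = None
    alpha: float = 1.0
    n_categories: int = 4
    frequency_mode: str = "empirical"  # "empirical" (+F) or "model"
    poisson_p_max: float = 0.05
    rho_min: float = 0.0
    rer_p_max: float = 0.05
    beb_min: float = 0.5
    spacing_cutoff: float = 10.0
    fdr_max: float = 0.05
    min_depth: int = 10
    expected_over: str = "all"
    brlen_tol: float = 1e-4  # sweep tolerance of the branch-length optimiser
    seed: int = 1


@dataclass
class RunReport:
    n_genes: int = 0
    n_screen_passing: int = 0
    n_convergent: int = 0
    n_specific_only: int = 0
    n_accelerated: int = 0
    n_union: int = 0
    n_intersection: int = 0
    n_psg: int | None = None
    heterozygosity: float | None = None
    failed_genes: list[str] = field(default_factory=list)
    wall_clock_s: float = 0.0
    version: str = __version__
    config: dict = field(default_factory=dict)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def load_trait_config(path: str) -> TraitConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return TraitConfig(
        foreground_species=frozenset(raw["foreground_species"]),
        background_species=frozenset(raw["background_species"]),
        exempt_species=frozenset(raw.get("exempt_species", [])),
        foreground_branches=frozenset(raw.get("foreground_branches", [])),
    )


def _alignment_paths(config: PipelineConfig) -> list[str]:
    return sorted(
        glob.glob(os.path.join(config.alignment_dir, "*.fasta"))
        + glob.glob(os.path.join(config.alignment_dir, "*.fa"))
    )


def validate_config(config: PipelineConfig) -> list[str]:
    """List every problem that would prevent a run; empty means runnable.
    Never raises."""
    problems: list[str] = []
    if not os.path.isdir(config.alignment_dir):
        problems.append(f"alignment_dir does not exist: {config.alignment_dir}")
    elif not _alignment_paths(config):
        problems.append(f"no FASTA alignments in {config.alignment_dir}")
    for label, path in [("tree", config.tree), ("trait_config", config.trait_config)]:
        if not os.path.isfile(path):
            problems.append(f"{label} file missing: {path}")
    for label, path in [("scan_table", config.scan_table), ("vcf", config.vcf)]:
        if path is not None and not os.path.isfile(path):
            problems.append(f"{label} file missing: {path}")
    for name, val, lo, hi in [
        ("poisson_p_max", config.poisson_p_max, 0.0, 1.0),
        ("rer_p_max", config.rer_p_max, 0.0, 1.0),
        ("beb_min", config.beb_min, 0.0, 1.0),
        ("fdr_max", config.fdr_max, 0.0, 1.0),
    ]:
        if not (lo < val <= hi):
            problems.append(f"{name} out of range (0, 1]: {val}")
    if config.alpha <= 0:
        problems.append(f"alpha must be > 0: {config.alpha}")
    if config.n_categories < 1:
        problems.append("n_categories must be >= 1")
    if config.frequency_mode not in ("empirical", "model"):
        problems.append(f"unknown frequency_mode: {config.frequency_mode}")
    if problems:
        return problems
    # cross-file consistency
    try:
        tree = read_newick_file(config.tree)
        trait = load_trait_config(config.trait_config)
        trait.validate_against(tree)
        leaves = set(tree.leaf_names)
        for path in _alignment_paths(config):
            aln = read_fasta_file(path)
            missing = leaves - set(aln.names)
            if missing:
                problems.append(
                    f"{os.path.basename(path)}: missing species {sorted(missing)[:3]}"
                )
    except Exception as exc:
        problems.append(str(exc))
    return problems


def _gene_model(config: PipelineConfig, aln: ProteinAlignment) -> SubstitutionModel:
    if config.frequency_mode == "empirical":
        return SubstitutionModel.jtt_f(aln, alpha=config.alpha, n_categories=config.n_categories)
    return SubstitutionModel.jtt(alpha=config.alpha, n_categories=config.n_categories)


def run_convergence_stage(
    config: PipelineConfig, tree: SpeciesTree, trait: TraitConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Screen + Poisson test per gene; returns (sites table, tests table,
    failed gene ids)."""
    site_rows, test_rows, failed = [], [], []
    for path in _alignment_paths(config):
        aln = read_fasta_file(path)
        try:
            result = test_gene_convergence(
                aln, tree, trait, _gene_model(config, aln), expected_over=config.expected_over
            )
        except Exception as exc:
            log.warning("gene=%s stage=converge status=failed error=%s", aln.gene_id, exc)
            failed.append(aln.gene_id)
            continue
        for site in result.candidate_sites:
            site_rows.append(
                {
                    "gene": aln.gene_id,
                    "position": site.position,
                    "foreground_state": site.foreground_state,
                    "background_state": site.background_state,
                }
            )
        test_rows.append(
            {
                "gene": aln.gene_id,
                "n_candidate_sites": len(result.candidate_sites),
                "observed": result.observed,
                "expected": result.expected,
                "p_value": result.p_value,
            }
        )
        log.info(
            "gene=%s stage=converge n_sites=%d O=%d E=%.4g p=%.4g",
            aln.gene_id, len(result.candidate_sites), result.observed,
            result.expected, result.p_value,
        )
    sites = pd.DataFrame(site_rows, columns=["gene", "position", "foreground_state", "background_state"])
    tests = pd.DataFrame(
        test_rows, columns=["gene", "n_candidate_sites", "observed", "expected", "p_value"]
    )
    return sites, tests, failed


def run_rer_stage(
    config: PipelineConfig, tree: SpeciesTree, trait: TraitConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene branch lengths -> master tree -> RERs -> trait association."""
    gene_trees = {}
    failed = []
    for path in _alignment_paths(config):
        aln = read_fasta_file(path)
        try:
            fit = estimate_branch_lengths(
                tree, aln, _gene_model(config, aln), tol=config.brlen_tol
            )
        except Exception as exc:
            log.warning("gene=%s stage=rer status=failed error=%s", aln.gene_id, exc)
            failed.append(aln.gene_id)
            continue
        gene_trees[aln.gene_id] = fit.tree
        log.info(
            "gene=%s stage=rer lnL=%.2f converged=%s sweeps=%d",
            aln.gene_id, fit.log_likelihood, fit.converged, fit.n_sweeps,
        )
    master = build_master_tree(gene_trees)
    rers = compute_rers(gene_trees, master)
    assocs = binary_trait_association(rers, trait.foreground_branches)
    table = pd.DataFrame(
        [
            {
                "gene": a.gene_id,
                "rho": a.rho,
                "p_value": a.p_value,
                "n_foreground": a.n_foreground,
                "n_background": a.n_background,
                "flag": a.reason or "",
            }
            for a in assocs
        ]
    ).sort_values("gene").reset_index(drop=True)
    return table, failed


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, writing each stage's tables before the
    next begins; returns the run report (also written as JSON)."""
    t0 = time.time()
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    tree = read_newick_file(config.tree)
    trait = load_trait_config(config.trait_config)

    report = RunReport(config={k: v for k, v in asdict(config).items()})
    report.n_genes = len(_alignment_paths(config))

    sites, tests, failed_c = run_convergence_stage(config, tree, trait)
    sites.to_csv(os.path.join(config.out_dir, "convergence_sites.tsv"), sep="\t", index=False)
    from .convergence import ConvergenceTestResult

    results = [
        ConvergenceTestResult(
            gene_id=row.gene,
            branch_pairs=[],
            candidate_sites=[None] * int(row.n_candidate_sites),  # type: ignore[list-item]
            observed=int(row.observed),
            expected=float(row.expected),
            p_value=float(row.p_value),
        )
        for row in tests.itertuples()
    ]
    classes = classify_convergent_genes(results, threshold=config.poisson_p_max)
    tests = tests.assign(
        classification=[r.classification or "" for r in results]
    )
    tests.to_csv(os.path.join(config.out_dir, "convergence_tests.tsv"), sep="\t", index=False)

    rer_table, failed_r = run_rer_stage(config, tree, trait)
    rer_table.to_csv(os.path.join(config.out_dir, "rer_associations.tsv"), sep="\t", index=False)
    accelerated = accelerated_gene_filter(
        _assocs_from_table(rer_table), rho_min=config.rho_min, p_max=config.rer_p_max
    )

    combo = combine_gene_sets(classes.convergent, accelerated)
    report.n_screen_passing = int((tests["n_candidate_sites"] > 0).sum())
    report.n_convergent = len(classes.convergent)
    report.n_specific_only = len(classes.specific_only)
    report.n_accelerated = len(accelerated)
    report.n_union = combo["union"]
    report.n_intersection = combo["intersection"]
    report.failed_genes = sorted(set(failed_c) | set(failed_r))
    assert report.n_union == report.n_convergent + report.n_accelerated - report.n_intersection

    pd.DataFrame(
        sorted(
            {
                (g, g in classes.convergent, g in accelerated)
                for g in combo["union_genes"]
            }
        ),
        columns=["gene", "convergent_substitutions", "accelerated_rer"],
    ).to_csv(os.path.join(config.out_dir, "combined_genes.tsv"), sep="\t", index=False)

    if config.scan_table:
        records = read_scan_table(config.scan_table)
        psg = select_positively_selected_genes(
            records,
            fdr_max=config.fdr_max,
            beb_min=config.beb_min,
            max_median_interval=config.spacing_cutoff,
        )
        report.n_psg = len(psg["genes"])
        pd.DataFrame(
            [
                {
                    "gene": g,
                    "q_value": d["q"],
                    "n_sites": len(d["sites"]),
                    "spacing_ok": d["spacing_ok"],
                    "selected": g in psg["genes"],
                }
                for g, d in sorted(psg["detail"].items())
            ]
        ).to_csv(os.path.join(config.out_dir, "positively_selected_genes.tsv"), sep="\t", index=False)
    if config.vcf:
        het = genome_heterozygosity(read_vcf_variants(config.vcf), min_depth=config.min_depth)
        report.heterozygosity = het.ratio

    report.wall_clock_s = time.time() - t0
    with open(os.path.join(config.out_dir, "run_report.json"), "w") as fh:
        json.dump(asdict(report), fh, indent=2, default=str)
    return report


def _assocs_from_table(table: pd.DataFrame):
    from .rer import RERAssociation

    return [
        RERAssociation(
            gene_id=row.gene,
            rho=float(row.rho) if np.isfinite(row.rho) else np.nan,
            p_value=float(row.p_value) if np.isfinite(row.p_value) else np.nan,
            n_foreground=int(row.n_foreground),
            n_background=int(row.n_background),
            reason=row.flag or None,
        )
        for row in table.itertuples()
    ]
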