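"""Post-filters for branch-site positive-selection scans and small genome
statistics.

The codon-model fits themselves (null and alternative branch-site models)
are consumed from a tab-separated table of log-likelihoods and per-site
Bayes empirical Bayes (BEB) posterior probabilities; this module applies the
downstream rules: the likelihood-ratio test, Benjamini-Hochberg FDR
correction, the BEB site threshold, and the clustered-sites spacing filter.
It also provides the genome-QC arithmetic used in assembly reports
(consensus-quality conversion, assembly fractions, depth-filtered
heterozygosity) and exact gene-set combination counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BranchSiteScanRecord",
    "VariantSite",
    "HeterozygosityResult",
    "lrt_pvalue",
    "bh_fdr",
    "pss_select",
    "pss_spacing_filter",
    "genome_heterozygosity",
    "read_vcf_variants",
    "qv_to_error_rate",
    "assembly_fraction",
    "combine_gene_sets",
]

_NESTED_TOL = 1e-6


@dataclass
class BranchSiteScanRecord:
    """One gene's branch-site scan: null (ma0) and alternative (ma)
    log-likelihoods plus candidate sites with BEB posteriors."""

    gene_id: str
    lnl_null: float
    lnl_alt: float
    pss: list[tuple[int, float]]  # (1-based position, BEB probability)

    def __post_init__(self) -> None:
        if self.lnl_alt < self.lnl_null - _NESTED_TOL:
            raise ValueError(
                f"{self.gene_id}: alternative lnL below null lnL — models are nested"
            )
        positions = [p for p, _ in self.pss]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError(f"{self.gene_id}: PSS positions must be strictly increasing")
        if any(not (0.0 <= b <= 1.0) for _, b in self.pss):
            raise ValueError(f"{self.gene_id}: BEB probabilities must lie in [0, 1]")


@dataclass
class VariantSite:
    position: int
    depth: int
    genotype: str  # "hom-ref" | "het" | "hom-alt"


@dataclass
class HeterozygosityResult:
    ratio: float | None
    n_het: int
    n_sites: int
    reason: str | None = None


def lrt_pvalue(lnl_null: float, lnl_alt: float, df: int = 1) -> float:
    """Likelihood-ratio test of nested models: 2*(lnL_alt - lnL_null)
    against chi-square with ``df`` degrees of freedom."""
    if not (np.isfinite(lnl_null) and np.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    if lnl_alt < lnl_null - _NESTED_TOL:
        raise ValueError("alternative lnL below null lnL beyond tolerance")
    stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
    return float(chi2.sf(stat, df))


def lrt_pvalue_mixture(lnl_null: float, lnl_alt: float) -> float:
    """Boundary-aware variant: 50:50 mixture of a point mass at 0 and
    chi-square(1), halving the tail probability."""
    stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
    if stat == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, 1))


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def pss_select(record: BranchSiteScanRecord, beb_min: float = 0.5) -> list[int]:
    """Positions whose BEB posterior strictly exceeds ``beb_min``."""
    return [pos for pos, beb in record.pss if beb > beb_min]


def pss_spacing_filter(positions: list[int], max_median_interval: float = 10.0) -> bool:
    """Clustered-sites rule: returns True ("keep") unless the median
    interval between consecutive selected sites is <= the cutoff.

    Genes with fewer than two sites have no interval and are kept.
    """
    if list(positions) != sorted(positions):
        raise ValueError("positions must be sorted increasing")
    if len(positions) < 2:
        return True
    diffs = np.diff(np.asarray(positions, dtype=float))
    return bool(np.median(diffs) > max_median_interval)


def genome_heterozygosity(
    sites: Iterable[VariantSite], min_depth: int = 10
) -> HeterozygosityResult:
    """Ratio of heterozygous sites to all callable sites, after removing
    sites below the depth cutoff."""
    n_sites = 0
    n_het = 0
    for s in sites:
        if s.depth < min_depth:
            continue
        n_sites += 1
        if s.genotype == "het":
            n_het += 1
    if n_sites == 0:
        return HeterozygosityResult(None, 0, 0, reason="no sites pass the depth filter")
    return HeterozygosityResult(n_het / n_sites, n_het, n_sites)


def read_vcf_variants(path: str) -> Iterable[VariantSite]:
    """Stream VariantSite records from a VCF (GT and DP only)."""
    from cyvcf2 import VCF

    gt_names = {0: "hom-ref", 1: "het", 2: "het", 3: "hom-alt"}
    for rec in VCF(path):
        try:
            depth = int(rec.format("DP")[0][0])
        except (TypeError, KeyError):
            depth = int(rec.INFO.get("DP", 0))
        yield VariantSite(
            position=rec.POS, depth=depth, genotype=gt_names.get(rec.gt_types[0], "het")
        )


def qv_to_error_rate(qv: float) -> tuple[float, float]:
    """Convert a Phred-scaled consensus quality to errors per 10,000 bases.

    QV = -10*log10(per-base error), so the rate is 10^(4 - QV/10).  Returns
    (rounded-to-2-decimals, exact).
    """
    if not np.isfinite(qv):
        raise ValueError("QV must be finite")
    exact = 10.0 ** (4.0 - qv / 10.0)
    return round(exact, 2), exact


def assembly_fraction(part_mb: float, total_mb: float) -> float:
    """Percentage of the assembly contributed by ``part_mb``, at the
    3-decimal reporting precision of assembly tables."""
    if total_mb <= 0:
        raise ValueError("total size must be positive")
    if not (0 <= part_mb <= total_mb):
        raise ValueError("part must lie within [0, total]")
    return round(100.0 * part_mb / total_mb, 3)


def combine_gene_sets(set_a: set, set_b: set) -> dict:
    """Exact set algebra for combining two evidence lists of genes."""
    a, b = set(set_a), set(set_b)
    union = a | b
    inter = a & b
    assert len(union) == len(a) + len(b) - len(inter)
    return {
        "union": len(union),
        "intersection": len(inter),
        "a_only": len(a - b),
        "b_only": len(b - a),
        "union_genes": union,
        "intersection_genes": inter,
    }


def read_scan_table(path: str) -> list[BranchSiteScanRecord]:
    """Read a branch-site scan TSV: gene, lnL0, lnL1, and a semicolon-
    separated ``pos:beb`` list (empty field allowed)."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("gene"):
            raise ValueError("scan table must start with a header line")
        for ln in fh:
            if not ln.strip():
                continue
            gene, l0, l1, *rest = ln.rstrip("\n").split("\t")
            pss = []
            if rest and rest[0]:
                for item in rest[0].split(";"):
                    pos, beb = item.split(":")
                    pss.append((int(pos), float(beb)))
            records.append(
                BranchSiteScanRecord(
                    gene_id=gene, lnl_null=float(l0), lnl_alt=float(l1), pss=pss
                )
            )
    return records


def select_positively_selected_genes(
    records: list[BranchSiteScanRecord],
    *,
    fdr_max: float = 0.05,
    beb_min: float = 0.5,
    max_median_interval: float = 10.0,
) -> dict:
    """Full post-filter chain: LRT -> BH-FDR -> BEB site call -> spacing.

    Returns per-gene q-values, retained sites, and the surviving gene set.
    """
    pvals = [lrt_pvalue(r.lnl_null, r.lnl_alt) for r in records]
    qvals = bh_fdr(pvals) if records else np.array([])
    kept = set()
    detail = {}
    for r, p, q in zip(records, pvals, qvals):
        sites = pss_select(r, beb_min)
        spacing_ok = pss_spacing_filter(sites, max_median_interval)
        significant = q < fdr_max
        if significant and spacing_ok:
            kept.add(r.gene_id)
        detail[r.gene_id] = {
            "p": p,
            "q": float(q),
            "sites": sites,
            "spacing_ok": spacing_ok,
            "significant": bool(significant),
        }
    return {"genes": kept, "detail": detail}
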