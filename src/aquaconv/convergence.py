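"""Convergent amino-acid substitution detection.

Two steps, mirroring the screen-then-test design used for fully aquatic
mammals:

1. a strict site screen over extant sequences: a column is a candidate when
   every foreground species shares one residue F, every background species
   shares one residue B, and F != B; a designated exempt outgroup may carry
   anything;
2. an observed-versus-expected count of convergent substitutions on
   phylogenetically independent pairs of foreground branches, using marginal
   ancestral reconstructions, tested against a Poisson null.

Genes whose observed count is significantly above expectation are called
convergent; genes whose screened sites fail the test are labelled
trait-specific ("specific-only") substitutions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .alignment import AMINO_ACIDS, GAP_CODE, ProteinAlignment
from .likelihood import AncestralPosteriors
from .model import SubstitutionModel
from .tree import SpeciesTree, TraitConfig

__all__ = [
    "CandidateSite",
    "ConvergenceTestResult",
    "screen_specific_substitutions",
    "independent_branch_pairs",
    "count_observed_convergent",
    "expected_convergent",
    "poisson_convergence_test",
    "classify_convergent_genes",
    "GeneClassification",
]


@dataclass(frozen=True)
class CandidateSite:
    """A screened column: all foreground species carry F, all background
    species carry B, F != B; exempt species unconstrained."""

    gene_id: str
    column: int  # 0-based
    foreground_state: str
    background_state: str
    exempt_states: tuple[tuple[str, str], ...] = ()

    @property
    def position(self) -> int:
        """1-based position for reports."""
        return self.column + 1


@dataclass
class ConvergenceTestResult:
    gene_id: str
    branch_pairs: list[tuple[str, str]]
    candidate_sites: list[CandidateSite]
    observed: int
    expected: float
    p_value: float
    degenerate_expectation: bool = False
    classification: str | None = None  # "convergent" | "specific-only"


def screen_specific_substitutions(
    aln: ProteinAlignment, trait: TraitConfig
) -> list[CandidateSite]:
    """Strict foreground/background group-identity screen.

    Columns with a gap or unknown residue in any non-exempt species are
    skipped (the strictest reading of requiring identity within groups).
    """
    if not trait.foreground_species or not trait.background_species:
        raise ValueError("foreground and background species sets must be non-empty")
    present = set(aln.names)
    needed = trait.foreground_species | trait.background_species
    missing = needed - present
    if missing:
        raise ValueError(f"alignment lacks non-exempt species: {sorted(missing)}")

    fg = np.vstack([aln.row(s) for s in sorted(trait.foreground_species)])
    bg = np.vstack([aln.row(s) for s in sorted(trait.background_species)])
    exempt_names = sorted(trait.exempt_species & present)
    ex = (
        np.vstack([aln.row(s) for s in exempt_names])
        if exempt_names
        else np.empty((0, aln.length), dtype=np.uint8)
    )

    fg_ok = (fg < GAP_CODE).all(axis=0) & (fg == fg[0]).all(axis=0)
    bg_ok = (bg < GAP_CODE).all(axis=0) & (bg == bg[0]).all(axis=0)
    hits = fg_ok & bg_ok & (fg[0] != bg[0])

    lookup = AMINO_ACIDS + "-?"
    out = []
    for col in np.flatnonzero(hits):
        out.append(
            CandidateSite(
                gene_id=aln.gene_id,
                column=int(col),
                foreground_state=AMINO_ACIDS[fg[0, col]],
                background_state=AMINO_ACIDS[bg[0, col]],
                exempt_states=tuple(
                    (name, lookup[ex[i, col]]) for i, name in enumerate(exempt_names)
                ),
            )
        )
    return out


def independent_branch_pairs(
    tree: SpeciesTree, trait: TraitConfig
) -> list[tuple[int, int]]:
    """All unordered pairs of foreground branches where neither branch is
    ancestral to the other; deterministic order (sorted by node ids).

    Branches are identified by the node they lead to.
    """
    if not trait.foreground_branches:
        raise ValueError("no foreground branches configured")
    nodes = sorted(tree.node_by_name(b) for b in trait.foreground_branches)
    pairs = []
    for a, b in itertools.combinations(nodes, 2):
        if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
            continue
        pairs.append((a, b))
    return pairs


def count_observed_convergent(
    post: AncestralPosteriors,
    tree: SpeciesTree,
    pairs: list[tuple[int, int]],
    sites: list[int],
    *,
    strict_convergent_only: bool = False,
) -> int:
    """Observed convergent substitutions over candidate sites and branch pairs.

    For branch b ending at node v: ancestral state a = MAP state at
    parent(v), derived state d = MAP state at v (the observed residue when v
    is a tip).  A pair counts at a site when both branches substitute
    (a != d on each) and the derived states coincide.  With
    ``strict_convergent_only`` the ancestral states must also differ
    (excluding parallel substitutions).  A tip missing data at the site
    contributes no substitution.
    """
    if not sites:
        return 0
    sites_arr = np.asarray(sorted(sites), dtype=int)
    if sites_arr.size and (sites_arr.min() < 0 or sites_arr.max() >= post.node_posteriors.shape[1]):
        raise IndexError("candidate site index out of alignment range")
    map_states = post.map_states()

    # tips: use the observed residue; missing data masks the branch
    observed_ok = np.ones((tree.n_nodes, sites_arr.size), dtype=bool)
    # tip point-mass posteriors already encode the observed residue; detect
    # missing tips by their uniform posterior
    for v in tree.leaves:
        uniform = np.isclose(post.node_posteriors[v, sites_arr, :], 1.0 / 20.0).all(axis=1)
        observed_ok[v] = ~uniform

    O = 0
    for v1, v2 in pairs:
        p1, p2 = tree.parent[v1], tree.parent[v2]
        a1 = map_states[p1, sites_arr]
        a2 = map_states[p2, sites_arr]
        d1 = map_states[v1, sites_arr]
        d2 = map_states[v2, sites_arr]
        hit = (d1 == d2) & (a1 != d1) & (a2 != d2) & observed_ok[v1] & observed_ok[v2]
        if strict_convergent_only:
            hit &= a1 != a2
        O += int(hit.sum())
    return O


def expected_convergent(
    post: AncestralPosteriors,
    model: SubstitutionModel,
    tree: SpeciesTree,
    pairs: list[tuple[int, int]],
    sites: np.ndarray | None = None,
) -> float:
    """Model-expected number of convergent substitutions.

    E sums, over sites, branch pairs and rate categories, the probability
    that both branches substitute to the same derived state:

        sum_k w_k(s) sum_{a1,a2} q1(a1) q2(a2)
            sum_{d != a1, d != a2} P1k(a1,d) P2k(a2,d)

    with q_i the marginal ancestral posterior at the parent of branch i and
    P_ik the branch transition matrix in category k.  The two parent
    posteriors are treated as independent — the approximation inherent to
    counting on marginal reconstructions.
    """
    L = post.node_posteriors.shape[1]
    cols = np.arange(L) if sites is None else np.asarray(sorted(sites), dtype=int)
    if cols.size == 0 or not pairs:
        return 0.0
    w = post.category_weights[cols, :]  # (n, K)
    E = 0.0
    for v1, v2 in pairs:
        p1 = post.node_posteriors[tree.parent[v1], cols, :]  # (n, 20)
        p2 = post.node_posteriors[tree.parent[v2], cols, :]
        P1 = model.transition_matrices(float(tree.branch_length[v1]))  # (K,20,20)
        P2 = model.transition_matrices(float(tree.branch_length[v2]))
        for k in range(model.n_categories):
            u1 = p1 @ P1[k]  # predictive distribution of d on branch 1
            u2 = p2 @ P2[k]
            g1 = np.diag(P1[k])  # P(a -> a)
            g2 = np.diag(P2[k])
            term_all = (u1 * u2).sum(axis=1)
            term_d_eq_a1 = ((p1 * g1[None, :]) * u2).sum(axis=1)
            term_d_eq_a2 = ((p2 * g2[None, :]) * u1).sum(axis=1)
            term_both = (p1 * p2 * g1[None, :] * g2[None, :]).sum(axis=1)
            per_site = term_all - term_d_eq_a1 - term_d_eq_a2 + term_both
            E += float((w[:, k] * per_site).sum())
    return max(E, 0.0)


def poisson_convergence_test(observed: int, expected: float) -> tuple[float, bool]:
    """Upper-tail Poisson test: p = P(X >= O) for X ~ Poisson(E).

    Returns (p, degenerate) where degenerate marks the E = 0, O > 0 case
    (p reported as 0 — the null assigns the observation no probability).
    """
    if observed < 0 or expected < 0:
        raise ValueError("counts and expectations must be non-negative")
    if observed == 0:
        return 1.0, False
    if expected == 0:
        return 0.0, True
    return float(poisson.sf(observed - 1, expected)), False


@dataclass
class GeneClassification:
    convergent: set[str] = field(default_factory=set)
    specific_only: set[str] = field(default_factory=set)
    n_convergent_sites: int = 0
    n_specific_sites: int = 0


def classify_convergent_genes(
    results: list[ConvergenceTestResult], threshold: float = 0.05
) -> GeneClassification:
    """Partition screened genes by the Poisson test at p < threshold.

    Genes passing are convergent; genes whose screened sites fail the test
    keep the trait-specific ("specific-only") label.  Genes without any
    screened site belong to neither class.
    """
    out = GeneClassification()
    for r in results:
        if not r.candidate_sites:
            r.classification = None
            continue
        if r.p_value < threshold:
            r.classification = "convergent"
            out.convergent.add(r.gene_id)
            out.n_convergent_sites += len(r.candidate_sites)
        else:
            r.classification = "specific-only"
            out.specific_only.add(r.gene_id)
            out.n_specific_sites += len(r.candidate_sites)
    return out


def test_gene_convergence(
    aln: ProteinAlignment,
    tree: SpeciesTree,
    trait: TraitConfig,
    model: SubstitutionModel | None = None,
    *,
    expected_over: str = "all",
    strict_convergent_only: bool = False,
) -> ConvergenceTestResult:
    """Run the full per-gene screen-and-test.

    ``expected_over`` selects the columns the expectation is summed over:
    "all" (the per-gene null expectation, the default) or "candidates"
    (screened columns only).
    """
    from .likelihood import PruningEngine

    if model is None:
        model = SubstitutionModel.jtt_f(aln)
    sites = screen_specific_substitutions(aln, trait)
    pairs = independent_branch_pairs(tree, trait)
    pair_names = [
        (tree.names[a] or f"node{a}", tree.names[b] or f"node{b}") for a, b in pairs
    ]
    if not sites:
        return ConvergenceTestResult(
            gene_id=aln.gene_id,
            branch_pairs=pair_names,
            candidate_sites=[],
            observed=0,
            expected=0.0,
            p_value=1.0,
        )
    post = PruningEngine(tree, aln, model).posteriors(tree.branch_length)
    cols = [s.column for s in sites]
    O = count_observed_convergent(
        post, tree, pairs, cols, strict_convergent_only=strict_convergent_only
    )
    site_subset = None if expected_over == "all" else np.asarray(cols)
    E = expected_convergent(post, model, tree, pairs, sites=site_subset)
    p, degenerate = poisson_convergence_test(O, E)
    return ConvergenceTestResult(
        gene_id=aln.gene_id,
        branch_pairs=pair_names,
        candidate_sites=sites,
        observed=O,
        expected=E,
        p_value=p,
        degenerate_expectation=degenerate,
    )
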