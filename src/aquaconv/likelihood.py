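"""Phylogenetic likelihood and marginal ancestral reconstruction.

Implements Felsenstein's pruning algorithm for protein alignments under a
reversible empirical model with discrete-gamma rate variation, plus the
outside (up) pass that yields exact marginal posterior distributions over
ancestral states at every internal node.

Alignment columns are compressed to unique site patterns and all per-node
quantities are carried as (K, n_patterns, 20) arrays with per-pattern log
scaling factors, so likelihoods of long alignments neither underflow nor
require per-site Python loops.  Gap and unknown residues are treated as
missing data (a tip partial vector of ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import GAP_CODE, AMINO_ACIDS, ProteinAlignment
from .model import SubstitutionModel
from .tree import SpeciesTree

__all__ = [
    "AncestralPosteriors",
    "PruningEngine",
    "tree_log_likelihood",
    "marginal_ancestral_posteriors",
]

# alphabetical order of the one-letter codes, as indices into ARND... order;
# used to break ties in maximum-a-posteriori state calls deterministically
_ALPHA_RANK = np.argsort(np.argsort(list(AMINO_ACIDS)))


def _rescale(part: np.ndarray, sc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pull per-pattern magnitudes out of a partial-likelihood array into the
    log-scale accumulator; skipped while magnitudes are comfortably inside
    double range."""
    m = part.max(axis=2)
    if m.min() > 1e-120:
        return part, sc
    nz = m > 0
    part = np.where(nz[:, :, None], part / np.where(nz, m, 1.0)[:, :, None], 0.0)
    with np.errstate(divide="ignore"):
        sc = sc + np.where(nz, np.log(np.where(nz, m, 1.0)), -np.inf)
    return part, sc


@dataclass
class AncestralPosteriors:
    """Marginal ancestral state posteriors for one gene.

    ``node_posteriors[v, s]`` is the posterior distribution over the 20
    amino acids at node ``v`` and site ``s`` (tips are point masses on the
    observed residue, uniform for gap/unknown).  ``category_weights[s]`` are
    the posterior probabilities of the K gamma rate categories at site ``s``.
    """

    tree: SpeciesTree
    node_posteriors: np.ndarray  # (n_nodes, L, 20)
    category_weights: np.ndarray  # (L, K)
    log_likelihood: float

    def map_states(self) -> np.ndarray:
        """(n_nodes, L) most-probable state per node and site; ties broken
        by alphabetical amino-acid order."""
        post = self.node_posteriors
        best = post.max(axis=2, keepdims=True)
        is_max = post >= best - 1e-12
        rank = np.where(is_max, _ALPHA_RANK[None, None, :], np.inf)
        return rank.argmin(axis=2)


class PruningEngine:
    """Shared state for repeated likelihood evaluations on one gene.

    Holds the pattern-compressed alignment mapped onto the tree and caches
    the inside ("down") and outside ("up") conditional likelihoods for a
    given assignment of branch lengths.  Branch-length optimisation re-uses
    the same engine, swapping lengths in and out.
    """

    def __init__(self, tree: SpeciesTree, aln: ProteinAlignment, model: SubstitutionModel):
        missing = set(tree.leaf_names) - set(aln.names)
        if missing:
            raise ValueError(f"species missing from alignment: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.K = model.n_categories
        leaf_ids = tree.leaves
        rows = np.vstack([aln.codes[aln.names.index(tree.names[v])] for v in leaf_ids])
        patterns, inverse, counts = np.unique(
            rows.T, axis=0, return_inverse=True, return_counts=True
        )
        self.leaf_ids = leaf_ids
        self.leaf_pattern_codes = {v: patterns[:, i] for i, v in enumerate(leaf_ids)}
        self.pattern_index = inverse  # site -> pattern
        self.pattern_weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.L = aln.length

    # -- passes ------------------------------------------------------------

    def _edge_matrices(self, lengths: np.ndarray) -> dict[int, np.ndarray]:
        """P(r_k * t_v) per non-root node v, shape (K, 20, 20)."""
        return {
            v: self.model.transition_matrices(float(lengths[v]))
            for v in range(self.tree.n_nodes - 1)
        }

    def _tip_message(self, v: int, P: np.ndarray) -> np.ndarray:
        """Message a tip sends to its parent: (K, n_pat, 20)."""
        codes = self.leaf_pattern_codes[v]
        msg = np.empty((self.K, self.n_patterns, 20))
        observed = codes < GAP_CODE
        safe = np.where(observed, codes, 0)
        for k in range(self.K):
            msg[k] = P[k].T[safe]
        msg[:, ~observed, :] = 1.0
        return msg

    def tip_partial(self, v: int) -> np.ndarray:
        """Conditional likelihood at a tip itself: one-hot on the observed
        residue, all-ones for missing data; (K, n_patterns, 20)."""
        if not hasattr(self, "_tip_partial_cache"):
            self._tip_partial_cache: dict[int, np.ndarray] = {}
        if v not in self._tip_partial_cache:
            codes = self.leaf_pattern_codes[v]
            part = np.zeros((self.n_patterns, 20))
            observed = codes < GAP_CODE
            part[np.flatnonzero(observed), codes[observed]] = 1.0
            part[~observed] = 1.0
            self._tip_partial_cache[v] = np.broadcast_to(
                part[None, :, :], (self.K, self.n_patterns, 20)
            )
        return self._tip_partial_cache[v]

    def down_pass(self, lengths: np.ndarray):
        """Inside pass.  Returns (down, down_scale, messages, loglik_per_cat).

        ``down[v]`` is P(data below v | state at v) rescaled per pattern;
        ``messages[v]`` is down[v] propagated through v's branch, the factor
        v contributes to its parent.  Root-level per-category pattern
        log-likelihoods come back for category posteriors.
        """
        tree = self.tree
        P = self._edge_matrices(lengths)
        down: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        messages: dict[int, np.ndarray] = {}
        for v in tree.postorder():
            if not tree.children[v]:
                down[v] = None  # tips enter only through their message
                scale[v] = np.zeros((self.K, self.n_patterns))
                messages[v] = self._tip_message(v, P[v])
                continue
            part = np.ones((self.K, self.n_patterns, 20))
            sc = np.zeros((self.K, self.n_patterns))
            for c in tree.children[v]:
                part = part * messages[c]
                sc = sc + scale[c]
            part, sc = _rescale(part, sc)
            down[v] = part
            scale[v] = sc
            if v != tree.root:
                messages[v] = part @ P[v].transpose(0, 2, 1)
        root = tree.root
        with np.errstate(divide="ignore"):
            loglik_cat = np.log((down[root] * self.model.pi[None, None, :]).sum(axis=2)) + scale[root]
        return down, scale, messages, loglik_cat, P

    def up_pass(self, down, scale, messages, P):
        """Outside pass.  Returns (out, out_scale, out_excl, out_excl_scale).

        ``out[v]`` is P(data outside the subtree of v, state at v) up to
        scaling; ``out_excl[v]`` is the same quantity evaluated at the
        parent end of v's branch (before transmission through the branch) —
        the piece needed to optimise v's branch length in isolation.
        """
        tree = self.tree
        out: dict[int, np.ndarray] = {}
        out_scale: dict[int, np.ndarray] = {}
        out_excl: dict[int, np.ndarray] = {}
        out_excl_scale: dict[int, np.ndarray] = {}
        root = tree.root
        out[root] = np.broadcast_to(
            self.model.pi[None, None, :], (self.K, self.n_patterns, 20)
        ).copy()
        out_scale[root] = np.zeros((self.K, self.n_patterns))
        for p in tree.preorder():
            kids = tree.children[p]
            if not kids:
                continue
            for c in kids:
                part = out[p]
                sc = out_scale[p]
                for s in kids:
                    if s != c:
                        part = part * messages[s]
                        sc = sc + scale[s]
                part, sc = _rescale(part, sc)
                out_excl[c] = part
                out_excl_scale[c] = sc
                out[c] = part @ P[c]
                out_scale[c] = sc
        return out, out_scale, out_excl, out_excl_scale

    # -- summaries ---------------------------------------------------------

    def total_log_likelihood(self, loglik_cat: np.ndarray) -> float:
        """Mix categories with equal prior weight 1/K and sum over sites."""
        pat_ll = logsumexp(loglik_cat, axis=0) - np.log(self.K)
        if np.any(np.isneginf(pat_ll)):
            warnings.warn(
                "some alignment columns have zero likelihood under the model "
                "(log-likelihood is -inf)",
                RuntimeWarning,
            )
        return float((pat_ll * self.pattern_weights).sum())

    def log_likelihood(self, lengths: np.ndarray) -> float:
        *_, loglik_cat, _ = self.down_pass(lengths)
        return self.total_log_likelihood(loglik_cat)

    def branch_objective(self, out_excl_v, out_excl_scale_v, down_msg_src, down_scale_v):
        """Return f(t): the full-tree log-likelihood as a function of one
        branch length, all other branches held fixed."""
        A, sA = out_excl_v, out_excl_scale_v
        D, sD = down_msg_src, down_scale_v
        weights = self.pattern_weights
        K = self.K
        model = self.model

        def f(t: float) -> float:
            P = model.transition_matrices(t)  # (K, 20, 20)
            lik = ((A @ P) * D).sum(axis=2)
            with np.errstate(divide="ignore"):
                ll = np.log(lik) + sA + sD
            pat_ll = logsumexp(ll, axis=0) - np.log(K)
            return float((pat_ll * weights).sum())

        return f

    def posteriors(self, lengths: np.ndarray) -> AncestralPosteriors:
        """Exact marginal ancestral posteriors at every node, mixing rate
        categories with their site-specific posterior weights."""
        tree = self.tree
        down, scale, messages, loglik_cat, P = self.down_pass(lengths)
        out, out_scale, _, _ = self.up_pass(down, scale, messages, P)
        # site-specific category posteriors (equal 1/K prior)
        ll = loglik_cat - logsumexp(loglik_cat, axis=0, keepdims=True)
        w_cat = np.exp(ll)  # (K, n_pat)
        n_nodes = tree.n_nodes
        post_pat = np.empty((n_nodes, self.n_patterns, 20))
        for v in range(n_nodes):
            if not tree.children[v]:
                codes = self.leaf_pattern_codes[v]
                pv = np.zeros((self.n_patterns, 20))
                observed = codes < GAP_CODE
                pv[np.flatnonzero(observed), codes[observed]] = 1.0
                pv[~observed] = 1.0 / 20.0
                post_pat[v] = pv
            else:
                g = down[v] * out[v]  # (K, n_pat, 20)
                tot = g.sum(axis=2, keepdims=True)
                g = np.where(tot > 0, g / np.where(tot > 0, tot, 1.0), 1.0 / 20.0)
                post_pat[v] = np.einsum("kp,kpx->px", w_cat, g)
        idx = self.pattern_index
        return AncestralPosteriors(
            tree=tree,
            node_posteriors=post_pat[:, idx, :],
            category_weights=w_cat.T[idx, :],
            log_likelihood=self.total_log_likelihood(loglik_cat),
        )


def tree_log_likelihood(
    tree: SpeciesTree, aln: ProteinAlignment, model: SubstitutionModel
) -> float:
    """Log-likelihood (nats) of the alignment on the tree under the model,
    averaging the K gamma rate categories with equal prior weight."""
    engine = PruningEngine(tree, aln, model)
    return engine.log_likelihood(tree.branch_length)


def marginal_ancestral_posteriors(
    tree: SpeciesTree, aln: ProteinAlignment, model: SubstitutionModel
) -> AncestralPosteriors:
    """Marginal posterior distributions over ancestral amino acids at every
    internal node, given tips, tree and model."""
    engine = PruningEngine(tree, aln, model)
    return engine.posteriors(tree.branch_length)
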