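"""Per-gene maximum-likelihood branch-length estimation on a fixed topology.

Coordinate ascent: each branch in turn is optimised by bounded Brent search
of its one-dimensional likelihood profile.  A sweep walks the tree in
postorder, refreshing the inside (below-branch) conditional likelihoods with
the lengths already updated this sweep, while the outside caches are
refreshed once per sweep; because of that staleness the joint sweep step is
safeguarded by a line search back toward the previous lengths whenever it
fails to improve the full likelihood, so the reported log-likelihood is
non-decreasing across sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import ProteinAlignment
from .likelihood import PruningEngine, _rescale
from .model import SubstitutionModel
from .tree import SpeciesTree

__all__ = ["BranchLengthResult", "estimate_branch_lengths"]

MAX_BRANCH_LENGTH = 20.0


@dataclass
class BranchLengthResult:
    tree: SpeciesTree
    log_likelihood: float
    converged: bool
    n_sweeps: int


def _optimize_branch(f, t0: float, xatol: float) -> float:
    """Maximise f over [0, 20], searching a window around the current value
    first and widening it whenever the optimum lands on the window edge."""
    lo = 0.0 if t0 < 1e-3 else t0 * 0.25
    hi = min(MAX_BRANCH_LENGTH, max(t0 * 4.0, 0.02))
    for _ in range(4):
        res = minimize_scalar(
            lambda t: -f(t), bounds=(lo, hi), method="bounded",
            options={"xatol": xatol, "maxiter": 60},
        )
        x = float(res.x)
        at_hi = hi < MAX_BRANCH_LENGTH and x > hi - 2 * xatol
        at_lo = lo > 0.0 and x < lo + 2 * xatol
        if at_hi:
            lo, hi = hi * 0.9, min(MAX_BRANCH_LENGTH, hi * 16.0)
        elif at_lo:
            lo, hi = max(0.0, lo / 16.0), lo * 1.1
        else:
            return x
    res = minimize_scalar(
        lambda t: -f(t), bounds=(0.0, MAX_BRANCH_LENGTH), method="bounded",
        options={"xatol": xatol, "maxiter": 60},
    )
    return float(res.x)


def estimate_branch_lengths(
    topology: SpeciesTree,
    aln: ProteinAlignment,
    model: SubstitutionModel,
    *,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    xatol: float = 1e-5,
) -> BranchLengthResult:
    """Maximise the likelihood over branch lengths in [0, 20].

    The topology is fixed; stored branch lengths (or ``init``) seed the
    search, falling back to 0.1 where absent.  Convergence is declared when
    a sweep improves the log-likelihood by less than ``tol``; hitting
    ``max_sweeps`` first yields ``converged=False`` on the result, never an
    exception.
    """
    engine = PruningEngine(topology, aln, model)
    tree = topology
    n = tree.n_nodes
    if init is not None:
        lengths = np.asarray(init, dtype=float).copy()
    else:
        lengths = tree.branch_length.copy()
    bad = ~np.isfinite(lengths) | (lengths < 0)
    lengths[bad] = 0.1
    lengths[: n - 1] = np.clip(lengths[: n - 1], 0.0, MAX_BRANCH_LENGTH)
    lengths[tree.root] = np.nan

    down, scale, messages, loglik_cat, P = engine.down_pass(lengths)
    current_ll = engine.total_log_likelihood(loglik_cat)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        _, _, out_excl, out_excl_scale = engine.up_pass(down, scale, messages, P)
        proposal = lengths.copy()
        for v in range(n - 1):
            if tree.children[v]:
                part = np.ones_like(down[v])
                sc = np.zeros_like(scale[v])
                for c in tree.children[v]:
                    part = part * messages[c]
                    sc = sc + scale[c]
                D, sD = _rescale(part, sc)
            else:
                D, sD = engine.tip_partial(v), scale[v]
            f = engine.branch_objective(out_excl[v], out_excl_scale[v], D, sD)
            proposal[v] = _optimize_branch(f, float(lengths[v]), xatol)
            down[v], scale[v] = D, sD
            P[v] = engine.model.transition_matrices(proposal[v])
            messages[v] = D @ P[v].transpose(0, 2, 1)
        # root combine gives the full likelihood of the proposal for free
        part = np.ones_like(messages[0], shape=(engine.K, engine.n_patterns, 20))
        sc = np.zeros((engine.K, engine.n_patterns))
        for c in tree.children[tree.root]:
            part = part * messages[c]
            sc = sc + scale[c]
        part, sc = _rescale(part, sc)
        down[tree.root], scale[tree.root] = part, sc
        with np.errstate(divide="ignore"):
            loglik_cat = np.log((part * model.pi[None, None, :]).sum(axis=2)) + sc
        new_ll = engine.total_log_likelihood(loglik_cat)

        if new_ll < current_ll:
            # stale outside caches overshot; damp the joint step
            direction = proposal - lengths
            step, improved = 1.0, False
            while step > 1e-6:
                step *= 0.5
                trial = lengths + step * direction
                trial_ll = engine.log_likelihood(trial)
                if trial_ll >= current_ll:
                    proposal, new_ll, improved = trial, trial_ll, True
                    break
            if not improved:
                converged = True
                break
            down, scale, messages, loglik_cat, P = engine.down_pass(proposal)
        improvement = new_ll - current_ll
        lengths, current_ll = proposal, new_ll
        if improvement < tol:
            converged = True
            break
    result_tree = tree.with_branch_lengths(lengths)
    return BranchLengthResult(
        tree=result_tree,
        log_likelihood=current_ll,
        converged=converged,
        n_sweeps=sweeps,
    )
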