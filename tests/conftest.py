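"""Shared fixtures and the exhaustive-enumeration likelihood oracle.

The oracle computes site likelihoods and ancestral posteriors by summing
over every joint assignment of states to internal nodes (and to missing
tips), built independently of the pruning recursion so the two can be
compared on small trees.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from aquaconv.alignment import GAP_CODE
from aquaconv.model import SubstitutionModel
from aquaconv.tree import SpeciesTree


# ---------------------------------------------------------------------------
# enumeration oracle


def enumerate_site(tree: SpeciesTree, col: np.ndarray, model: SubstitutionModel):
    """Brute-force likelihood and posteriors for one alignment column.

    ``col`` holds one code per leaf in ``tree.leaves`` order.  Returns
    (site_log_likelihood, posteriors (n_nodes, 20), category_weights (K,)).
    """
    leaves = tree.leaves
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    missing = [v for i, v in enumerate(leaves) if col[i] >= GAP_CODE]
    free = internal + missing
    fixed = {v: int(col[i]) for i, v in enumerate(leaves) if col[i] < GAP_CODE}
    I = len(free)
    assert I <= 6, "oracle restricted to small state spaces"
    grids = np.array(list(itertools.product(range(20), repeat=I))).T.reshape(I, -1)
    idx = {v: i for i, v in enumerate(free)}

    def state_of(v):
        return grids[idx[v]] if v in idx else np.full(grids.shape[1], fixed[v])

    K = model.n_categories
    lik = np.zeros(K)
    post_k = np.zeros((K, tree.n_nodes, 20))
    for k in range(K):
        prob = model.pi[state_of(tree.root)].astype(float).copy()
        for v in range(tree.n_nodes - 1):
            P = model.transition_matrix(model.rates[k] * float(tree.branch_length[v]))
            prob *= P[state_of(tree.parent[v]), state_of(v)]
        lik[k] = prob.sum()
        for v in range(tree.n_nodes):
            if v in idx:
                post_k[k, v] = np.bincount(grids[idx[v]], weights=prob, minlength=20)
            else:
                post_k[k, v, fixed[v]] = lik[k]
    site_lik = lik.mean()  # equal 1/K prior over categories
    cat_w = (lik / K) / site_lik
    post = np.zeros((tree.n_nodes, 20))
    for k in range(K):
        if lik[k] > 0:
            post += (lik[k] / K) / site_lik * (post_k[k] / lik[k])
    return float(np.log(site_lik)), post, cat_w


def random_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    """Random rooted binary topology with U(0.02, 1.2) branch lengths."""
    # grow by repeatedly joining two remaining subtrees
    from aquaconv.tree import read_newick

    items = [f"L{i}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        la, lb = rng.uniform(0.02, 1.2, size=2)
        items.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return read_newick(items[0] + ";")


def random_model(rng: np.random.Generator, K: int | None = None) -> SubstitutionModel:
    pi = rng.dirichlet(np.full(20, 5.0))
    S = rng.uniform(0.05, 2.0, size=(20, 20))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0.0)
    alpha = float(rng.uniform(0.3, 2.5))
    K = K if K is not None else int(rng.choice([1, 2, 4]))
    return SubstitutionModel(pi=pi, alpha=alpha, n_categories=K, S=S)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def mammal_tree_and_trait():
    from aquaconv.simulate import fixture_tree_19_species

    return fixture_tree_19_species()


@pytest.fixture(scope="session")
def jtt_model():
    return SubstitutionModel.jtt(alpha=1.0)
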