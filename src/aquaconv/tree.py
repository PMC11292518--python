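"""Rooted species trees and trait configurations.

A :class:`SpeciesTree` is a rooted phylogeny stored in flat arrays indexed by
node id, with nodes numbered in postorder (leaves and internal nodes
interleaved as encountered; the root is always the last id).  Branches are
identified by the id, or the name, of the node they lead to, so "the branch
leading to the bottlenose dolphin" is simply the dolphin's node.

Newick parsing is delegated to dendropy; only the flattened representation
used by the likelihood machinery lives here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "TraitConfig", "read_newick", "write_newick"]


class TreeError(ValueError):
    """Raised for malformed or invalid tree input."""


@dataclass
class SpeciesTree:
    """Rooted tree in postorder arrays.

    Attributes
    ----------
    parent : np.ndarray
        ``parent[i]`` is the parent node id of node ``i`` (-1 for the root).
    children : list[list[int]]
        Child ids per node, in stored (deterministic) order.
    branch_length : np.ndarray
        Length of the branch subtending each node, in substitutions per
        site; ``nan`` for the root.
    names : list[str | None]
        Leaf species names; internal nodes carry their Newick label or None.
    """

    parent: np.ndarray
    children: list[list[int]]
    branch_length: np.ndarray
    names: list[str | None]

    def __post_init__(self) -> None:
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]  # type: ignore[misc]

    def node_by_name(self, name: str) -> int:
        for i, n in enumerate(self.names):
            if n == name:
                return i
        raise KeyError(f"no node named {name!r}")

    def postorder(self) -> list[int]:
        """Node ids, children before parents (identical to id order)."""
        return list(range(self.n_nodes))

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if node ``a`` lies on the path from ``b`` to the root (a != b)."""
        x = self.parent[b]
        while x != -1:
            if x == a:
                return True
            x = self.parent[x]
        return False

    def leaf_set(self, node: int) -> frozenset[str]:
        """Names of the leaves subtended by ``node``."""
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(self.names[v])
        return frozenset(out)  # type: ignore[arg-type]

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            branch_length=self.branch_length.copy(),
            names=list(self.names),
        )

    def with_branch_lengths(self, lengths: np.ndarray) -> "SpeciesTree":
        t = self.copy()
        t.branch_length = np.asarray(lengths, dtype=float).copy()
        t.branch_length[t.root] = np.nan
        return t

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_nodes
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        if not (len(self.parent) == len(self.children) == len(self.branch_length) == n):
            raise TreeError("node array lengths disagree")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1 or roots[0] != n - 1:
            raise TreeError("tree must have exactly one root, stored last")
        for i in range(n - 1):
            p = self.parent[i]
            if not (0 <= p < n) or p <= i:
                raise TreeError("node ids must be postorder (parents after children)")
            bl = self.branch_length[i]
            if not np.isfinite(bl) or bl < 0:
                raise TreeError(f"branch length of node {i} must be finite and >= 0")
        leaf_names = self.leaf_names
        if any(nm is None for nm in leaf_names):
            raise TreeError("every leaf must be named")
        if len(set(leaf_names)) != len(leaf_names):
            dups = sorted({x for x in leaf_names if leaf_names.count(x) > 1})
            raise TreeError(f"duplicate leaf names: {dups}")


@dataclass
class TraitConfig:
    """Binary-trait configuration: which lineages carry the trait.

    ``foreground_species`` are the trait-bearing extant species,
    ``background_species`` those without it, and ``exempt_species`` an
    outgroup excused from the group-identity requirement of the site screen
    (here the marsupial, whose genetic distance from placentals makes the
    identity requirement uninformative).  ``foreground_branches`` name the
    branches (by node name) used in branch-pair counting and in the RER
    association; they may include internal branches such as the cetacean
    ancestor.
    """

    foreground_species: frozenset[str]
    background_species: frozenset[str]
    exempt_species: frozenset[str] = field(default_factory=frozenset)
    foreground_branches: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.foreground_species = frozenset(self.foreground_species)
        self.background_species = frozenset(self.background_species)
        self.exempt_species = frozenset(self.exempt_species)
        self.foreground_branches = frozenset(self.foreground_branches)
        for a, b in [
            (self.foreground_species, self.background_species),
            (self.foreground_species, self.exempt_species),
            (self.background_species, self.exempt_species),
        ]:
            if a & b:
                raise ValueError(f"species sets overlap: {sorted(a & b)}")

    def validate_against(self, tree: SpeciesTree) -> None:
        leaves = set(tree.leaf_names)
        missing = (self.foreground_species | self.background_species | self.exempt_species) - leaves
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        names = {n for n in tree.names if n is not None}
        bad = set(self.foreground_branches) - names
        if bad:
            raise ValueError(f"foreground branches not in tree: {sorted(bad)}")
        # every foreground species must sit under at least one foreground branch
        fg_nodes = [tree.node_by_name(b) for b in self.foreground_branches]
        covered = set()
        for v in fg_nodes:
            covered |= tree.leaf_set(v)
        lacking = self.foreground_species - covered
        if lacking:
            raise ValueError(
                f"foreground species subtend no foreground branch: {sorted(lacking)}"
            )


def read_newick(text: str) -> SpeciesTree:
    """Parse a Newick string into a :class:`SpeciesTree`.

    Branch lengths are required on all non-root nodes; internal node labels
    are kept so that internal branches can be referenced by name.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    dnodes = [nd for nd in dtree.postorder_node_iter()]
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    bl = np.full(n, np.nan)
    names: list[str | None] = [None] * n
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            children[parent[i]].append(i)
            bl[i] = nd.edge.length if nd.edge.length is not None else np.nan
            if not np.isfinite(bl[i]):
                raise TreeError(f"missing branch length on node {i}")
        if nd.taxon is not None:
            names[i] = nd.taxon.label
        elif nd.label:
            names[i] = nd.label
    for c in children:
        c.sort()
    return SpeciesTree(parent=parent, children=children, branch_length=bl, names=names)


def _newick_node(tree: SpeciesTree, v: int) -> str:
    label = tree.names[v] or ""
    if " " in label:
        label = label.replace(" ", "_")
    if tree.children[v]:
        inner = ",".join(_newick_node(tree, c) for c in tree.children[v])
        s = f"({inner}){label}"
    else:
        s = label
    if tree.parent[v] != -1:
        s += f":{tree.branch_length[v]:.10g}"
    return s


def write_newick(tree: SpeciesTree) -> str:
    """Serialize a tree back to Newick (round-trips topology and lengths)."""
    return _newick_node(tree, tree.root) + ";"


def read_newick_file(path: str) -> SpeciesTree:
    with io.open(path) as fh:
        return read_newick(fh.read())
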