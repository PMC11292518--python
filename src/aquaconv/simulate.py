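"""Synthetic data with known truth for every pipeline stage.

Generates protein alignments evolved on a 19-mammal species tree under
JTT+gamma, with optional injected convergent sites on the fully aquatic
lineages (manatee, dolphin, blue whale) and optional rate acceleration
restricted to foreground branches, plus branch-site scan tables and diploid
variant tables.  All generators are pure functions of their parameters and
an integer seed.

The packaged tree follows the accepted placental topology for the 19
species used in aquatic-mammal comparative scans; its branch lengths are
synthetic but scaled to plausible amino-acid substitutions per site — no
output of this module reproduces any real divergence estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, ProteinAlignment, write_fasta_alignment
from .model import SubstitutionModel
from .selection import VariantSite
from .tree import SpeciesTree, TraitConfig, read_newick

__all__ = [
    "SimulationTruth",
    "fixture_tree_19_species",
    "simulate_alignment",
    "inject_convergence",
    "simulate_accelerated_gene",
    "simulate_variant_table",
    "write_vcf",
    "make_fixture_dataset",
]

# 19-species mammal tree: marsupial outgroup (Tasmanian devil), Atlantogenata
# (sloth + manatee/elephant), Euarchontoglires, and Laurasiatheria with the
# cetaceans nested in Cetartiodactyla.  Internal branches that analyses refer
# to carry labels; "Cetacea" is the common ancestor of dolphin and blue whale.
FIXTURE_NEWICK = (
    "(Sarcophilus_harrisii:0.30,"
    "((Choloepus_didactylus:0.09,"
    "(Trichechus_senegalensis:0.055,Elephas_maximus:0.06)Tethytheria:0.035"
    ")Atlantogenata:0.012,"
    "(((Homo_sapiens:0.035,Macaca_mulatta:0.04)Primates:0.045,"
    "(Mus_musculus:0.08,Rattus_norvegicus:0.075)Rodentia:0.10)Euarchontoglires:0.012,"
    "((Rhinolophus_ferrumequinum:0.07,Phyllostomus_discolor:0.075)Chiroptera:0.03,"
    "(((Felis_catus:0.045,Canis_lupus_familiaris:0.05)Carnivora:0.025,"
    "Equus_caballus:0.055)Zooamata:0.008,"
    "(Camelus_ferus:0.05,(Sus_scrofa:0.055,"
    "((Bos_taurus:0.035,Capra_hircus:0.035)Bovidae:0.03,"
    "(Tursiops_truncatus:0.022,Balaenoptera_musculus:0.02)Cetacea:0.035"
    ")Cetruminantia:0.01)Artiofabula:0.012)Cetartiodactyla:0.015"
    ")Fereuungulata:0.008)Scrotifera:0.01)Boreoeutheria:0.012"
    ")Placentalia:0.28);"
)

FOREGROUND_SPECIES = frozenset(
    {"Trichechus_senegalensis", "Tursiops_truncatus", "Balaenoptera_musculus"}
)
EXEMPT_SPECIES = frozenset({"Sarcophilus_harrisii"})
FOREGROUND_BRANCHES = frozenset(
    {"Trichechus_senegalensis", "Tursiops_truncatus", "Balaenoptera_musculus", "Cetacea"}
)


def fixture_tree_19_species() -> tuple[SpeciesTree, TraitConfig]:
    """The packaged 19-mammal tree and its fully-aquatic trait configuration.

    Foreground: African manatee, bottlenose dolphin, blue whale (plus the
    cetacean-ancestor branch for branch-level analyses); exempt: the
    marsupial Tasmanian devil; background: the remaining 15 species.
    """
    tree = read_newick(FIXTURE_NEWICK)
    leaves = set(tree.leaf_names)
    trait = TraitConfig(
        foreground_species=FOREGROUND_SPECIES,
        background_species=frozenset(leaves - FOREGROUND_SPECIES - EXEMPT_SPECIES),
        exempt_species=EXEMPT_SPECIES,
        foreground_branches=FOREGROUND_BRANCHES,
    )
    trait.validate_against(tree)
    return tree, trait


@dataclass
class SimulationTruth:
    """Everything needed to recompute downstream expectations without
    re-simulation: the generating tree, all ancestral states, per-site rate
    categories, injected convergent columns, and branch acceleration."""

    tree: SpeciesTree
    states: np.ndarray  # (n_nodes, L) generating state at every node
    categories: np.ndarray  # (L,) gamma category index per site
    seed: int
    injected_sites: list[tuple[int, str, str]] = field(default_factory=list)  # (col, derived, background)
    acceleration: dict[str, float] = field(default_factory=dict)


def simulate_alignment(
    tree: SpeciesTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    gene_id: str = "gene",
) -> tuple[ProteinAlignment, SimulationTruth]:
    """Evolve a protein alignment on the tree: root states from pi, one
    gamma category per site, states propagated through P(r_k * t) down each
    branch."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    K = model.n_categories
    cats = rng.integers(0, K, size=n_sites)
    n = tree.n_nodes
    states = np.empty((n, n_sites), dtype=np.uint8)
    states[tree.root] = rng.choice(20, size=n_sites, p=model.pi)
    for v in tree.preorder():
        if v == tree.root:
            continue
        P = model.transition_matrices(float(tree.branch_length[v]))
        cum = np.cumsum(P, axis=2)
        u = rng.random(n_sites)
        parent_states = states[tree.parent[v]]
        child = np.empty(n_sites, dtype=np.uint8)
        for k in range(K):
            idx = np.flatnonzero(cats == k)
            if idx.size:
                rows = cum[k][parent_states[idx]]
                child[idx] = (u[idx, None] > rows).sum(axis=1)
        states[v] = child
    leaf_ids = tree.leaves
    names = [tree.names[v] for v in leaf_ids]
    codes = states[leaf_ids]
    aln = ProteinAlignment(gene_id=gene_id, names=names, codes=codes.copy())  # type: ignore[arg-type]
    truth = SimulationTruth(tree=tree.copy(), states=states, categories=cats, seed=seed)
    return aln, truth


def inject_convergence(
    aln: ProteinAlignment,
    truth: SimulationTruth,
    trait: TraitConfig,
    n_conv_sites: int,
    seed: int,
) -> tuple[ProteinAlignment, SimulationTruth]:
    """Rewrite columns so every foreground species carries a shared derived
    state d and every background species a single state B != d, with d also
    differing from the generating states at the foreground branches' parent
    nodes (so the derived state is genuinely derived).  Exempt species are
    left untouched.  Columns are rewritten, not re-simulated: the screen and
    the substitution counts inspect states, not histories.
    """
    L = aln.length
    if n_conv_sites > L:
        raise ValueError("more convergent sites requested than columns available")
    if n_conv_sites == 0:
        return aln, truth
    tree = truth.tree
    rng = np.random.default_rng(seed)
    cols = rng.choice(L, size=n_conv_sites, replace=False)
    fg_nodes = [tree.node_by_name(b) for b in sorted(trait.foreground_branches)]
    parent_nodes = [tree.parent[v] for v in fg_nodes]
    codes = aln.codes.copy()
    fg_rows = [aln.names.index(s) for s in sorted(trait.foreground_species)]
    bg_rows = [aln.names.index(s) for s in sorted(trait.background_species)]
    new_truth = SimulationTruth(
        tree=truth.tree,
        states=truth.states,
        categories=truth.categories,
        seed=truth.seed,
        injected_sites=list(truth.injected_sites),
        acceleration=dict(truth.acceleration),
    )
    for col in sorted(int(c) for c in cols):
        ancestral = {int(truth.states[p, col]) for p in parent_nodes}
        b_state = int(rng.choice(20, p=None))
        allowed = [x for x in range(20) if x not in ancestral and x != b_state]
        if not allowed:
            raise ValueError(f"column {col}: no derived state available")
        d_state = int(rng.choice(allowed))
        codes[fg_rows, col] = d_state
        codes[bg_rows, col] = b_state
        new_truth.injected_sites.append(
            (col, AMINO_ACIDS[d_state], AMINO_ACIDS[b_state])
        )
    new_aln = ProteinAlignment(gene_id=aln.gene_id, names=list(aln.names), codes=codes)
    return new_aln, new_truth


def simulate_accelerated_gene(
    tree: SpeciesTree,
    factor: float,
    foreground_branches: frozenset[str] | set[str],
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    gene_id: str = "gene",
) -> tuple[ProteinAlignment, SimulationTruth]:
    """Simulate a gene whose foreground branch lengths are multiplied by
    ``factor`` before simulation (factor 1 reproduces the neutral path)."""
    if factor <= 0:
        raise ValueError("acceleration factor must be > 0")
    scaled = tree.copy()
    for name in foreground_branches:
        v = scaled.node_by_name(name)
        scaled.branch_length[v] *= factor
    aln, truth = simulate_alignment(scaled, model, n_sites, seed, gene_id=gene_id)
    truth.acceleration = {name: factor for name in sorted(foreground_branches)}
    return aln, truth


def simulate_variant_table(
    n_sites: int, het_rate: float, depth_mean: float, seed: int
) -> list[VariantSite]:
    """Diploid variant table: Bernoulli(het_rate) heterozygous calls with
    Poisson(depth_mean) per-site depth."""
    if not (0.0 <= het_rate <= 1.0):
        raise ValueError("het_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    depths = rng.poisson(depth_mean, size=n_sites)
    het = rng.random(n_sites) < het_rate
    return [
        VariantSite(position=i + 1, depth=int(depths[i]), genotype="het" if het[i] else "hom-ref")
        for i in range(n_sites)
    ]


def write_vcf(sites: list[VariantSite], path: str, chrom: str = "chr1") -> None:
    """Write a minimal VCF carrying only GT and DP."""
    gt = {"hom-ref": "0/0", "het": "0/1", "hom-alt": "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for s in sites:
            alt = "C" if s.genotype == "hom-ref" else "C"
            fh.write(
                f"{chrom}\t{s.position}\t.\tA\t{alt}\t.\tPASS\t.\tGT:DP\t"
                f"{gt[s.genotype]}:{s.depth}\n"
            )


def make_fixture_dataset(
    out_dir: str,
    *,
    n_null: int = 20,
    n_convergent: int = 5,
    n_accelerated: int = 5,
    n_sites: int = 2000,
    n_injected_sites: int | None = None,
    acceleration_factor: float = 2.0,
    alpha: float = 1.0,
    seed: int = 1,
) -> dict:
    """Materialise a complete demo dataset: per-gene FASTA alignments, the
    species tree, the trait configuration, a branch-site scan table and a
    variant table.  Returns the manifest (paths plus the truth labels)."""
    import os

    import yaml

    if n_injected_sites is None:
        # keep the injected signal density at ~3 convergent columns per 500
        # sites regardless of gene length
        n_injected_sites = max(3, round(0.006 * n_sites))
    os.makedirs(out_dir, exist_ok=True)
    aln_dir = os.path.join(out_dir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    tree, trait = fixture_tree_19_species()
    model = SubstitutionModel.jtt(alpha=alpha)
    rng = np.random.default_rng(seed)
    manifest: dict = {"genes": {}, "truth": {"convergent": [], "accelerated": []}}

    def _write(aln: ProteinAlignment) -> None:
        with open(os.path.join(aln_dir, f"{aln.gene_id}.fasta"), "w") as fh:
            fh.write(write_fasta_alignment(aln))

    for i in range(n_null):
        gid = f"null{i:03d}"
        aln, _ = simulate_alignment(tree, model, n_sites, int(rng.integers(2**31)), gene_id=gid)
        _write(aln)
        manifest["genes"][gid] = "null"
    for i in range(n_convergent):
        gid = f"conv{i:03d}"
        aln, truth = simulate_alignment(tree, model, n_sites, int(rng.integers(2**31)), gene_id=gid)
        aln, truth = inject_convergence(aln, truth, trait, n_injected_sites, int(rng.integers(2**31)))
        _write(aln)
        manifest["genes"][gid] = "convergent"
        manifest["truth"]["convergent"].append(gid)
    for i in range(n_accelerated):
        gid = f"accel{i:03d}"
        aln, _ = simulate_accelerated_gene(
            tree, acceleration_factor, trait.foreground_branches, model, n_sites,
            int(rng.integers(2**31)), gene_id=gid,
        )
        _write(aln)
        manifest["genes"][gid] = "accelerated"
        manifest["truth"]["accelerated"].append(gid)

    tree_path = os.path.join(out_dir, "species_tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(FIXTURE_NEWICK + "\n")
    trait_path = os.path.join(out_dir, "trait_config.yaml")
    with open(trait_path, "w") as fh:
        yaml.safe_dump(
            {
                "foreground_species": sorted(trait.foreground_species),
                "background_species": sorted(trait.background_species),
                "exempt_species": sorted(trait.exempt_species),
                "foreground_branches": sorted(trait.foreground_branches),
            },
            fh,
        )
    # branch-site scan table: a few significant genes with spread-out or
    # clustered sites, the rest null
    scan_path = os.path.join(out_dir, "branch_site_scan.tsv")
    with open(scan_path, "w") as fh:
        fh.write("gene\tlnl_null\tlnl_alt\tpss\n")
        fh.write("psg_spread\t-5000.0\t-4980.0\t10:0.92;200:0.88;500:0.75\n")
        fh.write("psg_clustered\t-5000.0\t-4978.0\t10:0.92;15:0.88;22:0.75;100:0.9\n")
        fh.write("psg_null\t-5000.0\t-4999.8\t42:0.55\n")
    vcf_path = os.path.join(out_dir, "variants.vcf")
    write_vcf(simulate_variant_table(20000, 5e-4, 45.0, int(rng.integers(2**31))), vcf_path)
    manifest.update(
        {
            "alignment_dir": aln_dir,
            "tree": tree_path,
            "trait_config": trait_path,
            "scan_table": scan_path,
            "vcf": vcf_path,
        }
    )
    return manifest
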