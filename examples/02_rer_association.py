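"""Relative evolutionary rates and binary-trait association.

Simulates a handful of genes — one with doubled substitution rates on the
fully aquatic branches — estimates per-gene branch lengths by maximum
likelihood, and tests each gene's RERs against the trait.
"""

import aquaconv as aq

tree, trait = aq.fixture_tree_19_species()
model = aq.SubstitutionModel.jtt(alpha=1.0)

gene_trees = {}
for i in range(6):
    gid = f"null{i}"
    aln, _ = aq.simulate_alignment(tree, model, 2000, seed=20 + i, gene_id=gid)
    gene_trees[gid] = aq.estimate_branch_lengths(tree, aln, model, tol=1e-4).tree
aln, _ = aq.simulate_accelerated_gene(
    tree, 2.0, trait.foreground_branches, model, 2000, seed=30, gene_id="accelerated"
)
gene_trees["accelerated"] = aq.estimate_branch_lengths(tree, aln, model, tol=1e-4).tree

master = aq.build_master_tree(gene_trees)
rers = aq.compute_rers(gene_trees, master)
assocs = aq.binary_trait_association(rers, trait.foreground_branches)

print(f"{'gene':<14}{'Rho':>8}{'p':>12}")
for a in assocs:
    print(f"{a.gene_id:<14}{a.rho:>8.3f}{a.p_value:>12.4g}")
print("accelerated genes:", sorted(aq.accelerated_gene_filter(assocs)))
print()
print(
    "Rho is the rank-biserial effect of foreground vs background RERs\n"
    "(positive = trait lineages evolve faster for that gene); genes with\n"
    "Rho > 0 and p < 0.05 are called convergently accelerated."
)
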