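"""Screen a gene for trait-specific amino-acid sites and test convergence.

Simulates one gene on the 19-mammal tree, plants three convergent columns on
the fully aquatic lineages (manatee, dolphin, blue whale), then runs the
strict site screen and the observed/expected Poisson test.
"""

import aquaconv as aq

tree, trait = aq.fixture_tree_19_species()
model = aq.SubstitutionModel.jtt(alpha=1.0)

aln, truth = aq.simulate_alignment(tree, model, n_sites=500, seed=11, gene_id="demo")
aln, truth = aq.inject_convergence(aln, truth, trait, n_conv_sites=3, seed=12)

result = aq.test_gene_convergence(aln, tree, trait, aq.SubstitutionModel.jtt_f(aln))

print(f"gene {result.gene_id}: {len(result.candidate_sites)} screened site(s)")
for site in result.candidate_sites:
    print(
        f"  position {site.position}: foreground {site.foreground_state} "
        f"vs background {site.background_state}"
    )
print(f"observed convergent substitutions O = {result.observed}")
print(f"expected under the model         E = {result.expected:.3f}")
print(f"Poisson upper-tail p             p = {result.p_value:.4f}")
print()
print(
    "O counts substitutions to a shared derived state on independent pairs of\n"
    "foreground branches (ancestral states from marginal reconstruction); E is\n"
    "the model-expected count over all columns. p < 0.05 calls the gene\n"
    "convergent; here the three planted columns drive O well above E."
)
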