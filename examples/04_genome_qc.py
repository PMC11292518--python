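"""Small genome-QC statistics: consensus quality, assembly fractions,
depth-filtered heterozygosity, and combining gene evidence lists."""

from aquaconv.selection import (
    assembly_fraction,
    combine_gene_sets,
    genome_heterozygosity,
    qv_to_error_rate,
)
from aquaconv.simulate import simulate_variant_table

rounded, exact = qv_to_error_rate(44.90)
print(f"QV 44.90  ->  {rounded} errors per 10,000 bp (exact {exact:.4f})")
print(f"2.75 Mb of 3,185.65 Mb  ->  {assembly_fraction(2.75, 3185.65)}% unplaced")

sites = simulate_variant_table(n_sites=200_000, het_rate=5e-4, depth_mean=45.0, seed=1)
het = genome_heterozygosity(sites, min_depth=10)
print(
    f"heterozygosity: {het.n_het} het / {het.n_sites} depth-passing sites "
    f"= {het.ratio:.3e} (simulated truth 5.0e-4)"
)

a = {f"g{i}" for i in range(30)}
b = {f"g{i}" for i in range(25, 45)}
combo = combine_gene_sets(a, b)
print(
    f"evidence lists of {len(a)} and {len(b)} genes: union {combo['union']}, "
    f"shared {combo['intersection']}"
)
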