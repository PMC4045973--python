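"""Generate a synthetic allotetraploid study and look at its structure.

Builds references for the two diploid progenitor genomes (A and B),
fragments two accessions' transcripts into contigs with read depths,
and simulates a doubled-haploid genotype matrix over the true map.
"""

from allomap.simulate import SimConfig, simulate_truth_set

config = SimConfig(n_blocks=8, genes_per_block=6, seed=42)
truth = simulate_truth_set(config)

print(f"A-genome reference genes: {len(truth.reference_A)}")
print(f"B-genome reference genes: {len(truth.reference_B)}")
print(f"contigs over two accessions: {len(truth.contigs)}")
print(f"true allelic variants: {len(truth.truth_variants)}")
n_a = sum(v.genome == "A" for v in truth.truth_variants)
n_b = sum(v.genome == "B" for v in truth.truth_variants)
print(f"  A genome {n_a}, B genome {n_b}  (A is the more polymorphic subgenome)")
print(f"linkage groups in the true map: {len(truth.true_map)}")
print(f"DH genotype matrix: {truth.dh_genotypes.shape[0]} loci x "
      f"{truth.dh_genotypes.shape[1]} individuals")
# The copy-number inventory drives the marker categories: genes unique to
# the B genome, single-copy in both genomes, or multi-copy.
single_both = sum(1 for k in truth.copy_number.values()
                  if k["A"] == 1 and k["B"] == 1)
print(f"gene families single-copy in both genomes: {single_both}")
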