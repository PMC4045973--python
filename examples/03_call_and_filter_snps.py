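"""Call allelic SNPs between two accessions' gene models and apply the
co-dominant (KASP) assay filters, then render a marker sequence.

The marker window is 101 bp: the target site as [X/Y], homoeologue- or
paralogue-specific sites in lower case (IUPAC code), and both 50-bp
flanks required to be conserved between the accessions.
"""

import numpy as np

from allomap.snp import (FilterConfig, HomoeologueProjection, align_alleles,
                         call_snps, classify_variant, design_marker_sequence,
                         kaspar_filter)

rng = np.random.default_rng(1)
gene = "".join(rng.choice(list("ACGT"), 400))

# accession 2 differs at position 200 (allelic SNP); the B-genome
# homoeologue differs at position 180 (an HSV inside the marker window)
allele2 = gene[:199] + ("A" if gene[199] != "A" else "G") + gene[200:]
homoeo = gene[:179] + ("C" if gene[179] != "C" else "T") + gene[180:]

aln = align_alleles(gene, allele2, gene_model_id="demo", depths=(12, 9))
variants = call_snps(aln)
proj = HomoeologueProjection(gene, homoeo)
for v in variants:
    cls = classify_variant(v, proj)
    ok, reasons = kaspar_filter(v, aln, junctions=[], config=FilterConfig())
    print(f"position {v.position}: {v.allele_1}/{v.allele_2}  class={cls}  "
          f"filter={'pass' if ok else 'fail ' + ';'.join(reasons)}")

v = variants[0]
site = {180: (gene[179], homoeo[179])}
rec = design_marker_sequence(v, gene, site, "BJ_VH_0001")
print("marker window:", rec.marker_sequence)
# the bracketed token marks the assayed SNP; the single lower-case IUPAC
# letter 20 bases to its left is the HSV the primers must tolerate
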