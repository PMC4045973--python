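# Methods

This note records the models, parameter choices and numerical
conventions behind `allomap`, and what the synthetic benchmark does and
does not establish about real data.

## The synthetic study model

The generator (`allomap.simulate`) encodes the assumed history of a
Brassica-like allotetraploid as a chain of substitution events:

1. **Ancestor.** `n_blocks` (default 24, lettered A–X) ancestral blocks
   of `genes_per_block` genes; each gene is a random stop-free CDS of
   `gene_length` bases (default 900) and carries an *A. thaliana*-style
   ortholog ID laid out collinearly along five chromosomes.
2. **Triplication and fractionation.** Each gene is copied into the
   LF/MF1/MF2 subgenomes with independent Bernoulli retention (defaults
   0.9 / 0.6 / 0.4, mirroring the observed ranking "least / medium /
   most fractionated"; with the later lineage loss these defaults give
   roughly the observed mix of single-, two- and three-copy families).
3. **Divergence.** Sequence divergence is applied per branch as uniform
   random substitution (each hit site changes to one of the three other
   bases, so the expected mismatch fraction equals the rate; a
   Jukes–Cantor-style model without indels — the marker chemistry
   targets substitutions, and an `indel_rate` hook exists but defaults
   to 0). Pairwise divergences: paralogues 0.12, homoeologues 0.07
   (the ~12 vs ~7 Mya separation of the triplicated subgenomes vs the
   A/B lineages), accession polymorphism 0.005 in the A genome and
   0.003 in the B genome — the A subgenome of the two accessions is the
   more variable one, and both rates sit well below the homoeologue
   divergence, which is what makes two-step assignment work. Each
   present-day pair receives half its divergence per branch.
4. **Lineage-specific loss.** After the lineage split each gene copy is
   independently lost from either lineage with probability 0.08; this
   produces B-genome-specific families (the B-unique marker category)
   and the single-copy-in-both category that drives homoeology
   inference.
5. **Genome layout and rearrangement.** (block, class) segments are
   dealt round-robin onto 10 A-genome and 8 B-genome linkage groups;
   `n_rearrangements` (default 8 per genome — this design of study
   observes on the order of a dozen blocks whose fragmentation differs
   between the genomes, which a handful of events cannot produce)
   random split/translocation events are applied and logged, and the
   log replays exactly — fragmentation recovery is scored against it.
   A logged split is only *expected* to be recovered when each of its
   segments carries at least two mapped markers; splits with
   single-marker segments may still be detected on the A genome (the
   single-marker rule) but are not required.
6. **Contigs.** Each transcript yields 1–2 non-overlapping substrings
   covering a noisy fraction of its length (mean `contig_coverage_mean`
   = 0.8, s.d. 0.1; a mean of 1.0 degenerates to full-length contigs);
   per-contig depth is Poisson(20) floored at 1. Depth is per contig,
   not per base: the depth filter applies the contig's mean at the SNP.
   The coverage distribution is a free parameter of the generator, not
   a claim about any particular assembler.
7. **DH meiosis.** One recombinant gamete per linkage group per
   individual, simulated as a Markov walk whose adjacent-interval
   recombination fraction is the inverse Kosambi transform
   r = ½ tanh(d/50) of the cM gap. This stationary renewal
   approximation reproduces two-point distances by construction but
   carries no explicit interference model beyond Kosambi's. Genotypes
   are a/b with 2 % missing at random. Inter-locus gaps are uniform
   1–6 cM.

Fixed seed ⇒ bit-identical outputs; all randomness flows from one
`SeedSequence` spawned per stage.

**What passing on synthetic data shows.** The benchmark establishes
internal correctness (the caller finds exactly the planted differences;
the filter equals its definition; grouping/ordering recover a known
map; fragmentation calls match logged rearrangements) under the stated
divergence structure. It does not exercise assembly chimeras,
alignment-indel noise, paralogue collapse in the assembly, sequencing
error, or segregation distortion with a biological cause — all of which
real transcriptome data contain.

## Assignment

The keep rule is the contrapositive reading of the published removal
rule: a contig survives only with a hit of >80 % identity over >100
aligned bases (both strict). Identity is matches / alignment columns of
the best semi-global alignment on either strand (edlib); spans are
reported 1-based closed on the reference and strand-normalized before
coverage unions. Translated search runs through NCBI BLAST+ (genuine
Karlin–Altschul E-values; threshold 1e−5); BLASTN only nominates
candidate references, never decides identity. An exact tie between the
best A and best B identity is called `ambiguous` and excluded
downstream — conservative for marker design. Gene models are keyed by
the winning genome's best nucleotide hit; secondary hits within 5 %
identity are recorded, not resolved (chimeric contigs are flagged, not
interpreted). Orphan contigs (no protein hit) are removed if they match
the A-genome reference, kept as B-specific if they match only the B
transcriptome, else removed as unclassified.

## Variant calling and marker design

Allelic gene models are compared per accession via their longest
assigned contig. The overlap alignment is the best local alignment
extended ungapped to the ends of the mutual overlap (so edge
substitutions are kept as columns); an alignment is discarded when the
overlap is shorter than the 101-bp window or mismatches at >20 % of
columns — the latter rejects pairings of fragments that do not truly
overlap, which would otherwise masquerade as SNP-dense alignments.

Classification is per site: accessions differ within a genome →
allelic SNP; accessions agree but the projected homoeologue base
differs → HSV; a within-genome paralogue differs → PSV; a site whose
homoeologue projection falls in a gap is flagged undetermined rather
than guessed. Homoeologue and paralogue states are taken from the
reference sequences of the same family (same subgenome class for the
homoeologue).

The assay filter requires depth ≥ 7 in **both** accessions (the
conservative reading — the published threshold names no line), 50
conserved columns (no mismatch or gap) on each side, and no exon–intron
junction inside the 101-bp window \[p−50, p+50\] (1-based closed, on
the accession-1 model). HSV/PSV sites in the flanks do not break flank
conservation — they are constant between the accessions and are encoded
as lower-case IUPAC degeneracy in the marker sequence. Indels never
become markers; an indel column breaks flank conservation. Other
allelic SNPs inside the window also fail the flank rule. B-genome
models borrow the exon structure of their A homoeologue (exon
boundaries are conserved between subgenomes); with no structure
available the junction check is unevaluable and the variant fails
conservatively. Copy-number categories follow the three-way rule
(B-unique / single-copy both / multi-copy); families present only in
the A genome fall outside the published categories and are excluded as
`A_only`. One marker is emitted per gene model.

## Linkage mapping

Distortion screening is chi-square against 1:1 at α = 0.05 without
multiplicity correction (no procedure is specified by the study design;
the choice is recorded in the run config). Markers with >50 % missing
calls are dropped with a warning; missing genotypes are pairwise
deleted. The two-point estimate is r̂ = recombinants / complete pairs,
capped at 0.5; LOD is the binomial likelihood ratio at the constrained
MLE, and r̂ ≥ 0.5 carries LOD 0 — in a phase-known DH cross apparent
repulsion is noise, and letting it count as linkage would join
unrelated groups through chance-repulsed pairs. Grouping is connected
components at LOD ≥ 4.0.

Ordering is a deliberate heuristic replacement for multipoint
regression mapping: greedy nearest-neighbour seeded at the most distal
pair, refined by 2-opt on the sum of adjacent recombination fractions,
positions cumulative Kosambi over adjacent r̂, orientation
canonicalized to the lexicographically smaller end marker. Map lengths
are therefore comparable, not identical, to those of multipoint
software; sampling noise at n = 123 inflates cumulative length (convex
transform of a noisy estimate). Group recovery at LOD 4.0 is exact for
the tested seeds; with many markers a chance cross-group pair can
exceed LOD 4 (per-pair probability ≈ 7.5 × 10⁻⁶ at n = 123) and merge
two groups, which is a property of the threshold, not the
implementation.

## Block painting and comparison

At IDs parse from `At[1-5]g\d{5}` (case-insensitive), ordered by
(chromosome, number); block intervals are closed, and a marker on an
endpoint is inside. Because the triplicated copies of a block share one
At interval, candidate blocks are narrowed by the marker's subgenome
class (known from its source reference gene); remaining ambiguity
starts a run deterministically and is re-anchored by unambiguous
neighbours. A single intervening marker of another block splits a run.
Evidence rules: ≥ 1 marker per call on the A genome, ≥ 2 on the B
genome. Orientation is the sign of the Spearman correlation between At
order and cM order (undetermined on ties).

Homoeology links require ≥ 2 shared single-copy (category-ii) families
between same-block calls whose At spans overlap — "same block region"
is operationalized as span overlap, not span identity. For
fragmentation, calls merge to one segment per linkage group (a block
interrupted in place is still one unit there; fragmentation means parts
on different LGs); classes are intact_both, split in one genome (more
segments than the other), split_both, duplicated (two segments within a
genome overlapping ≥ 50 % of the shorter At span — the recorded
operationalization of "duplicated on two LGs"), or absent_in_one.
Motifs are maximal ordered runs of adjacent block letters per LG,
compared reversal-invariantly across genomes and reported under a
canonical (lexicographically smaller of motif/reverse) key.

The shipped `data/published_blocks.tsv` encodes only block intervals
whose bounds and classes are explicitly printed in the study this
design follows (blocks A, B, N, Q, S, U, X and their sub-blocks);
per-block bounds inside the G–H–I arrangement and the class of block C
are not printed and are therefore not fabricated — users supply a full
ancestral-karyotype table for real analyses. Synthetic runs derive
their block table from the simulated reference layout.

## Problem sizes and tolerances

The reference synthetic study used by the acceptance script and the
end-to-end tests is 24 blocks × 21 gene families (~500 ancestral
genes, ~1,800 reference transcripts, ~4,300 contigs) with 123 DH
individuals — large enough that assignment accuracy, oracle agreement
and fragmentation recovery are measured on thousands of decisions while
a full run stays in the low minutes on one CPU. Statistical generator
checks use 3σ bands at their stated sample sizes; closed-form
quantities (Kosambi, LOD) are asserted to 1e−9 or tighter; oracle
comparisons (SNP caller vs haplotype scan, filter vs window re-scan)
are exact.

## CLI

The command-line layer is a thin wrapper over the stage functions with
files as the inter-stage interface (exit codes 0/1/2 = ok / user error
/ internal). Per-stage counts are logged into the run report so the
marker-development funnel is reconstructible — and is independently
recounted — from the written tables alone. One top-level seed is
recorded in the report; all stage randomness derives from it.
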