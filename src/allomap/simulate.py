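"""Synthetic allotetraploid transcriptome generator with known truth.

Emulates the genomic history assumed by the downstream analysis: a
triplicated crucifer-like ancestor whose three subgenomes (LF, MF1, MF2)
were differentially fractionated, a split into two diploid lineages (the
A and B genomes of the allotetraploid), and two cultivated accessions of
the allotetraploid whose A genomes are more polymorphic than their B
genomes.  Every simulated object carries its truth label so that
subgenome assignment, variant classification, linkage mapping and block
painting can all be scored exactly.

Divergence levels are expressed as expected substitutions per site
between a pair of present-day sequences; each branch of the pair
receives half of that divergence.  The default paralogue level (0.12)
exceeds the homoeologue level (0.07), which in turn exceeds the
accession-level polymorphism rates, reproducing the separation that the
two-step contig classification relies on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

BLOCK_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWX"
SUBGENOME_CLASSES = ("LF", "MF1", "MF2")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# codons excluding TAA, TAG, TGA
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]

DEFAULT_ACCESSIONS = ("line_1", "line_2")


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic allotetraploid study.

    Rates are substitutions per site between present-day sequence pairs.
    ``allelic_snp_rate_A`` must exceed ``allelic_snp_rate_B`` to mirror
    the greater diversity of the A subgenome between the two accessions.
    """

    n_blocks: int = 24
    genes_per_block: int = 8
    gene_length: int = 900
    retention_probs: dict = field(default_factory=lambda: {"LF": 0.9, "MF1": 0.6, "MF2": 0.4})
    paralogue_divergence: float = 0.12
    homoeologue_divergence: float = 0.07
    allelic_snp_rate_A: float = 0.005
    allelic_snp_rate_B: float = 0.003
    lineage_loss_prob: float = 0.08
    n_rearrangements: int = 8
    contig_coverage_mean: float = 0.8
    depth_mean: float = 20.0
    indel_rate: float = 0.0
    missing_genotype_rate: float = 0.02
    n_dh: int = 123
    n_lgs_A: int = 10
    n_lgs_B: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_blocks <= 24:
            raise ConfigError("n_blocks must be in 1..24")
        if self.gene_length % 3 or self.gene_length < 150:
            raise ConfigError("gene_length must be a multiple of 3 and >= 150")
        for cls in SUBGENOME_CLASSES:
            p = self.retention_probs.get(cls)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(f"retention probability for {cls} must be in [0,1]")
        for name in ("lineage_loss_prob", "contig_coverage_mean", "missing_genotype_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")
        if self.contig_coverage_mean <= 0.0:
            raise ConfigError("contig_coverage_mean must be in (0,1]")
        rates = (self.allelic_snp_rate_A, self.allelic_snp_rate_B)
        if not self.paralogue_divergence > self.homoeologue_divergence > max(rates):
            raise ConfigError(
                "require paralogue_divergence > homoeologue_divergence > allelic rates"
            )
        if self.n_rearrangements < 0:
            raise ConfigError("n_rearrangements must be >= 0")
        if self.n_dh < 1:
            raise ConfigError("n_dh must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass
class ReferenceGene:
    """One gene of a diploid reference: sequence plus placement metadata."""

    id: str
    genome: str                 # "A" or "B"
    family_id: str              # ancestral gene id shared by all copies
    block_id: str               # ancestral block letter
    subgenome_class: str        # LF / MF1 / MF2
    at_id: str                  # A. thaliana ortholog id, e.g. At1g02220
    sequence: str               # CDS / transcript, transcript coordinates
    exon_lengths: list = field(default_factory=list)

    @property
    def junctions(self) -> list:
        """Exon-intron junction positions in transcript coordinates.

        A junction sits after the last base of each exon except the final
        one; position is that last base (1-based).
        """
        out, pos = [], 0
        for length in self.exon_lengths[:-1]:
            pos += length
            out.append(pos)
        return out


@dataclass
class SimContig:
    id: str
    accession: str
    sequence: str
    mean_depth: float
    # truth fields
    true_genome: str
    true_gene: str          # reference gene copy id the contig derives from
    true_start: int         # 1-based start on the transcript
    true_end: int


@dataclass
class TruthVariant:
    genome: str
    family_id: str
    gene_id: str            # reference copy id within the genome
    position: int           # 1-based on the transcript
    allele_1: str
    allele_2: str
    var_class: str          # allelic_SNP (truth list covers the allelic class)


@dataclass
class TruthSet:
    config: SimConfig
    reference_A: list
    reference_B: list
    contigs: list
    truth_assignment: dict          # contig id -> "A"/"B"
    truth_variants: list
    true_map: dict                  # lg id -> list of (locus id, cM)
    dh_genotypes: "object"          # pandas DataFrame, rows loci, cols individuals
    haplotypes: dict                # (genome, gene id, accession) -> sequence
    layout_A: dict                  # lg id -> list of segment dicts
    layout_B: dict
    events_A: list
    events_B: list
    copy_number: dict               # family id -> {"A": k, "B": k}


# ---------------------------------------------------------------------------
# elementary operations


def _rand_cds(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    idx = rng.integers(0, len(_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_CODONS[i] for i in idx)


def diverge_sequence(sequence: str, divergence: float, rng) -> str:
    """Mutate ``sequence`` by uniform random substitution.

    Each site is substituted with probability ``divergence``; the new
    base is drawn uniformly from the three alternatives, so the expected
    mismatch fraction against the input equals ``divergence``.  Length is
    preserved (no indels).
    """
    if not 0.0 <= divergence < 0.75:
        raise ConfigError("divergence must be in [0, 0.75)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    if hit.any():
        # shift by 1..3 in base space: always lands on a different base
        codes = np.searchsorted(BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = BASES[(codes + shift) % 4]
    return arr.tobytes().decode()


def triplicate_and_fractionate(ancestor_genes: list, retention_probs: dict, rng) -> list:
    """Expand ordered ancestral genes into 0-3 retained subgenome copies.

    Retention of each LF/MF1/MF2 copy is an independent Bernoulli draw
    with the class's probability.  Returns ``(gene, subgenome_class)``
    pairs preserving ancestral order within each class.
    """
    for cls in SUBGENOME_CLASSES:
        p = retention_probs.get(cls)
        if p is None or not 0.0 <= p <= 1.0:
            raise ConfigError(f"retention probability for {cls} must be in [0,1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = []
    for gene in ancestor_genes:
        for cls in SUBGENOME_CLASSES:
            if rng.random() < retention_probs[cls]:
                out.append((gene, cls))
    return out


def apply_rearrangements(layout: dict, n_events: int, rng) -> tuple:
    """Apply random block translocations/splits to a genome layout.

    ``layout`` maps LG id -> ordered list of segments; each segment is a
    dict with keys ``block_id``, ``subgenome_class`` and ``genes`` (an
    ordered gene-id list).  Returns ``(new_layout, event_log)``; the log
    can be replayed with :func:`replay_events`.
    """
    if n_events < 0:
        raise ConfigError("n_events must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    layout = {lg: [dict(seg, genes=list(seg["genes"])) for seg in segs]
              for lg, segs in layout.items()}
    events = []
    lgs = sorted(layout)
    for _ in range(n_events):
        kind = "split" if rng.random() < 0.5 else "translocation"
        if kind == "split":
            candidates = [(lg, i) for lg in lgs for i, seg in enumerate(layout[lg])
                          if len(seg["genes"]) >= 2]
            if not candidates:
                kind = "translocation"
            else:
                lg, i = candidates[rng.integers(len(candidates))]
                seg = layout[lg][i]
                cut = int(rng.integers(1, len(seg["genes"])))
                dest = lgs[rng.integers(len(lgs))]
                moved = dict(seg, genes=seg["genes"][cut:])
                seg["genes"] = seg["genes"][:cut]
                at = int(rng.integers(len(layout[dest]) + 1))
                layout[dest].insert(at, moved)
                events.append({"kind": "split", "lg": lg, "segment": i, "cut": cut,
                               "dest": dest, "dest_pos": at})
                continue
        if kind == "translocation":
            candidates = [(lg, i) for lg in lgs for i in range(len(layout[lg]))]
            lg, i = candidates[rng.integers(len(candidates))]
            seg = layout[lg].pop(i)
            dest = lgs[rng.integers(len(lgs))]
            at = int(rng.integers(len(layout[dest]) + 1))
            layout[dest].insert(at, seg)
            events.append({"kind": "translocation", "lg": lg, "segment": i,
                           "dest": dest, "dest_pos": at})
    return layout, events


def replay_events(layout: dict, events: list) -> dict:
    """Re-apply a logged event sequence to a base layout."""
    layout = {lg: [dict(seg, genes=list(seg["genes"])) for seg in segs]
              for lg, segs in layout.items()}
    for ev in events:
        if ev["kind"] == "split":
            seg = layout[ev["lg"]][ev["segment"]]
            moved = dict(seg, genes=seg["genes"][ev["cut"]:])
            seg["genes"] = seg["genes"][:ev["cut"]]
            layout[ev["dest"]].insert(ev["dest_pos"], moved)
        else:
            seg = layout[ev["lg"]].pop(ev["segment"])
            layout[ev["dest"]].insert(ev["dest_pos"], seg)
    return layout


def fragment_to_contigs(transcripts: dict, coverage_mean: float, depth_mean: float,
                        rng, accession: str = "acc") -> list:
    """Break transcripts into partial-length contigs with mean read depths.

    ``transcripts`` maps id -> (genome, sequence).  Each transcript yields
    one or two non-overlapping substrings whose total length is a noisy
    fraction of the transcript (mean ``coverage_mean``); per-contig depth
    is Poisson(``depth_mean``) floored at 1.
    """
    if not transcripts:
        raise ConfigError("empty transcript set")
    if not 0.0 < coverage_mean <= 1.0:
        raise ConfigError("coverage_mean must be in (0,1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    contigs = []
    for tid in sorted(transcripts):
        genome, seq = transcripts[tid]
        L = len(seq)
        # mean 1.0 with support bounded above by 1 forces full coverage
        frac = 1.0 if coverage_mean >= 1.0 else float(
            np.clip(rng.normal(coverage_mean, 0.10), 0.15, 1.0))
        span = max(60, int(round(frac * L)))
        span = min(span, L)
        start = int(rng.integers(0, L - span + 1))
        pieces = [(start, start + span)]
        if span >= 240 and rng.random() < 0.25:
            cut = start + int(rng.integers(span // 4, 3 * span // 4))
            gap = int(rng.integers(0, 30))
            if cut + gap < start + span - 30:
                pieces = [(start, cut), (cut + gap, start + span)]
        for k, (s, e) in enumerate(pieces, start=1):
            depth = max(1, int(rng.poisson(depth_mean)))
            contigs.append(SimContig(
                id=f"{accession}|{tid}|c{k}",
                accession=accession,
                sequence=seq[s:e],
                mean_depth=float(depth),
                true_genome=genome,
                true_gene=tid,
                true_start=s + 1,
                true_end=e,
            ))
    return contigs


def kosambi_inverse_cm(d_cm: float) -> float:
    """Recombination fraction for a Kosambi map distance in cM."""
    return 0.5 * float(np.tanh(d_cm / 50.0))


def simulate_dh_genotypes(true_map: dict, n_dh: int, rng,
                          missing_rate: float = 0.0):
    """Simulate a doubled-haploid genotype matrix from a true map.

    One recombinant gamete per LG per individual; the crossover process
    is a stationary Markov walk along each LG whose adjacent-interval
    recombination fraction equals the inverse Kosambi transform of the
    cM gap (an approximation that ignores higher-order interference).
    Alleles are ``a``/``b``; ``-`` marks missing data.
    """
    import pandas as pd

    if n_dh < 1:
        raise ConfigError("n_dh must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    rows, index = [], []
    for lg in sorted(true_map):
        loci = true_map[lg]
        pos = [p for _, p in loci]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ConfigError(f"unsorted map positions on {lg}")
        gaps = np.diff(pos)
        rfs = 0.5 * np.tanh(gaps / 50.0)
        g = np.empty((len(loci), n_dh), dtype=np.int8)
        g[0] = rng.random(n_dh) < 0.5
        for i, r in enumerate(rfs, start=1):
            flip = rng.random(n_dh) < r
            g[i] = g[i - 1] ^ flip
        rows.append(g)
        index.extend(m for m, _ in loci)
    geno = np.concatenate(rows, axis=0)
    out = np.where(geno == 0, "a", "b").astype(object)
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        out[mask] = "-"
    cols = [f"DH{j + 1:03d}" for j in range(n_dh)]
    return pd.DataFrame(out, index=index, columns=cols)


# ---------------------------------------------------------------------------
# full truth-set construction


def _at_id(chrom: int, number: int) -> str:
    return f"At{chrom}g{number:05d}"


def _base_layout(genes_by_segment: dict, n_lgs: int, prefix: str) -> dict:
    """Deal (block, class) segments round-robin onto LGs in a fixed order."""
    layout = {f"{prefix}{i + 1}": [] for i in range(n_lgs)}
    lgs = sorted(layout)
    for j, key in enumerate(sorted(genes_by_segment)):
        block_id, cls = key
        layout[lgs[j % n_lgs]].append(
            {"block_id": block_id, "subgenome_class": cls,
             "genes": list(genes_by_segment[key])})
    return layout


def simulate_truth_set(config: SimConfig) -> TruthSet:
    """Generate the full synthetic study: references, contigs, truth tables."""
    root = np.random.SeedSequence(config.seed)
    (ss_anc, ss_frac, ss_par, ss_hom, ss_acc, ss_loss, ss_rearr,
     ss_contig, ss_map, ss_dh) = root.spawn(10)
    rng_anc = np.random.default_rng(ss_anc)
    rng_frac = np.random.default_rng(ss_frac)
    rng_par = np.random.default_rng(ss_par)
    rng_hom = np.random.default_rng(ss_hom)
    rng_acc = np.random.default_rng(ss_acc)
    rng_loss = np.random.default_rng(ss_loss)
    rng_rearr = np.random.default_rng(ss_rearr)
    rng_map = np.random.default_rng(ss_map)
    rng_dh = np.random.default_rng(ss_dh)

    acc1, acc2 = DEFAULT_ACCESSIONS

    # 1. ancestor: ordered genes in labelled blocks with At ortholog ids
    ancestors = []   # (family_id, block_id, at_id, sequence)
    per_chrom_slot = {}
    for bi in range(config.n_blocks):
        block = BLOCK_LETTERS[bi]
        chrom = (bi * 5) // config.n_blocks + 1
        slot = per_chrom_slot.get(chrom, 0)
        per_chrom_slot[chrom] = slot + 1
        for g in range(config.genes_per_block):
            number = (slot * config.genes_per_block + g + 1) * 50
            fam = f"anc_{block}_{g + 1:03d}"
            ancestors.append((fam, block, _at_id(chrom, number),
                              _rand_cds(rng_anc, config.gene_length)))

    # 2. triplicate + fractionate into the hexaploid template
    retained = triplicate_and_fractionate(
        [fam for fam, _, _, _ in ancestors], config.retention_probs, rng_frac)
    anc_by_fam = {fam: (block, at, seq) for fam, block, at, seq in ancestors}
    hexaploid = {}   # (family, class) -> template sequence
    for fam, cls in retained:
        _, _, seq = anc_by_fam[fam]
        hexaploid[(fam, cls)] = diverge_sequence(
            seq, config.paralogue_divergence / 2.0, rng_par)

    # 3. lineage split with per-lineage copy loss, exon structures shared
    #    between homoeologues (same ancestral gene structure)
    exon_struct = {}
    for (fam, cls) in sorted(hexaploid):
        n_ex = int(rng_hom.integers(1, 6))
        cuts = sorted(rng_hom.choice(
            np.arange(30, config.gene_length - 30), size=n_ex - 1, replace=False)) \
            if n_ex > 1 else []
        bounds = [0, *map(int, cuts), config.gene_length]
        exon_struct[(fam, cls)] = [b - a for a, b in zip(bounds, bounds[1:])]

    genomes = {"A": {}, "B": {}}   # (fam, cls) -> lineage ancestor sequence
    for key in sorted(hexaploid):
        for genome in ("A", "B"):
            if rng_loss.random() < config.lineage_loss_prob:
                continue
            genomes[genome][key] = diverge_sequence(
                hexaploid[key], config.homoeologue_divergence / 2.0, rng_hom)

    copy_number = {}
    for fam, _, _, _ in ancestors:
        ka = sum(1 for (f, _) in genomes["A"] if f == fam)
        kb = sum(1 for (f, _) in genomes["B"] if f == fam)
        if ka or kb:
            copy_number[fam] = {"A": ka, "B": kb}

    # 4. reference lines and the two accessions
    rates = {"A": config.allelic_snp_rate_A, "B": config.allelic_snp_rate_B}
    reference = {"A": [], "B": []}
    haplotypes = {}
    gene_ids = {}
    for genome in ("A", "B"):
        for (fam, cls) in sorted(genomes[genome]):
            block, at, _ = anc_by_fam[fam]
            gid = f"ref{genome}_{fam[4:]}_{cls}"
            gene_ids[(genome, fam, cls)] = gid
            lineage_seq = genomes[genome][(fam, cls)]
            ref_seq = diverge_sequence(lineage_seq, rates[genome] / 2.0, rng_acc)
            reference[genome].append(ReferenceGene(
                id=gid, genome=genome, family_id=fam, block_id=block,
                subgenome_class=cls, at_id=at, sequence=ref_seq,
                exon_lengths=exon_struct[(fam, cls)]))
            for acc in (acc1, acc2):
                haplotypes[(genome, gid, acc)] = diverge_sequence(
                    lineage_seq, rates[genome] / 2.0, rng_acc)

    # 5. truth variants: allelic differences between the two accessions
    truth_variants = []
    for genome in ("A", "B"):
        for gene in reference[genome]:
            h1 = haplotypes[(genome, gene.id, acc1)]
            h2 = haplotypes[(genome, gene.id, acc2)]
            for i, (x, y) in enumerate(zip(h1, h2), start=1):
                if x != y:
                    truth_variants.append(TruthVariant(
                        genome=genome, family_id=gene.family_id, gene_id=gene.id,
                        position=i, allele_1=x, allele_2=y,
                        var_class="allelic_SNP"))

    # 6. genome layouts + rearrangements
    seg_genes = {"A": {}, "B": {}}
    for genome in ("A", "B"):
        for gene in reference[genome]:
            seg_genes[genome].setdefault(
                (gene.block_id, gene.subgenome_class), []).append(gene.id)
    base_A = _base_layout(seg_genes["A"], config.n_lgs_A, "A")
    base_B = _base_layout(seg_genes["B"], config.n_lgs_B, "B")
    layout_A, events_A = apply_rearrangements(base_A, config.n_rearrangements, rng_rearr)
    layout_B, events_B = apply_rearrangements(base_B, config.n_rearrangements, rng_rearr)

    # 7. true genetic map: cumulative positions with random inter-locus gaps
    true_map = {}
    for layout in (layout_A, layout_B):
        for lg in sorted(layout):
            loci, pos = [], 0.0
            for seg in layout[lg]:
                for gid in seg["genes"]:
                    if loci:
                        pos += float(rng_map.uniform(1.0, 6.0))
                    loci.append((gid, round(pos, 3)))
            if loci:
                true_map[lg] = loci

    dh = simulate_dh_genotypes(true_map, config.n_dh, rng_dh,
                               missing_rate=config.missing_genotype_rate)

    # 8. contigs for both accessions
    contigs = []
    for acc, child in zip((acc1, acc2), ss_contig.spawn(2)):
        transcripts = {}
        for genome in ("A", "B"):
            for gene in reference[genome]:
                transcripts[gene.id] = (genome, haplotypes[(genome, gene.id, acc)])
        contigs.extend(fragment_to_contigs(
            transcripts, config.contig_coverage_mean, config.depth_mean,
            np.random.default_rng(child), accession=acc))
    truth_assignment = {c.id: c.true_genome for c in contigs}

    return TruthSet(
        config=config,
        reference_A=reference["A"],
        reference_B=reference["B"],
        contigs=contigs,
        truth_assignment=truth_assignment,
        truth_variants=truth_variants,
        true_map=true_map,
        dh_genotypes=dh,
        haplotypes=haplotypes,
        layout_A=layout_A,
        layout_B=layout_B,
        events_A=events_A,
        events_B=events_B,
        copy_number=copy_number,
    )


def synthetic_block_table(truth: TruthSet):
    """Derive a block-definition table from the A-genome reference layout.

    Mirrors how published ancestral-block tables are anchored: each
    contiguous (block, class) segment of the reference genome becomes one
    row with its observed At-ortholog interval; segments of a block split
    across LGs get sub-labels a/b/c in reference order.
    """
    import pandas as pd
    from .blocks import parse_at_id

    at_of = {g.id: g.at_id for g in truth.reference_A}
    rows = []
    for lg in sorted(truth.layout_A):
        for seg in truth.layout_A[lg]:
            ats = sorted(parse_at_id(at_of[g]) for g in seg["genes"] if g in at_of)
            if not ats:
                continue
            rows.append({"block_id": seg["block_id"],
                         "subgenome_class": seg["subgenome_class"],
                         "reference_lg": lg,
                         "at_start": str(ats[0]), "at_end": str(ats[-1])})
    df = pd.DataFrame(rows)
    df["sub_label"] = ""
    for (block, cls), idx in df.groupby(["block_id", "subgenome_class"]).groups.items():
        if len(idx) > 1:
            order = df.loc[idx].sort_values("at_start").index
            for k, i in enumerate(order):
                df.loc[i, "sub_label"] = "abcdefgh"[k]
    return df[["block_id", "sub_label", "subgenome_class", "reference_lg",
               "at_start", "at_end"]]
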