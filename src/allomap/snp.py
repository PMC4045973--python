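"""Allelic SNP discovery, variant classification and KASP marker design.

Variants between the two accessions' allelic gene models come in three
classes that must be told apart before a co-dominant assay can be
designed in an allotetraploid:

* allelic SNP — the accessions differ within one subgenome; the
  mappable marker class.
* HSV (homoeologue-specific variant) — the A and B homoeologues differ
  at a site where both accessions agree within each genome.
* PSV (paralogue-specific variant) — paralogous copies within one
  genome differ while the accessions agree.

Marker sequences follow the co-dominant assay convention: the target
allelic site is written ``[X/Y]``; HSV/PSV positions inside the window
are written in lower case (IUPAC degenerate code when both states must
be tolerated by the primer); all other bases are upper case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

IUPAC_PAIR = {
    frozenset("AG"): "r", frozenset("CT"): "y", frozenset("CG"): "s",
    frozenset("AT"): "w", frozenset("GT"): "k", frozenset("AC"): "m",
}

MARKER_PREFIX = "BJ_VH_"
COPY_CATEGORIES = ("i_B_unique", "ii_single_copy_both", "iii_multi_copy", "A_only")


@dataclass
class Column:
    pos1: int      # 1-based on accession-1 model, 0 for a gap in seq1
    pos2: int
    base1: str     # "-" for a gap
    base2: str

    @property
    def is_gap(self) -> bool:
        return self.base1 == "-" or self.base2 == "-"

    @property
    def is_match(self) -> bool:
        return not self.is_gap and self.base1 == self.base2


@dataclass
class AllelicAlignment:
    gene_model_id: str
    accession_1_id: str
    accession_2_id: str
    columns: list
    depth_1: float = 0.0
    depth_2: float = 0.0

    def __bool__(self) -> bool:
        return bool(self.columns)

    def column_at(self, pos1: int) -> Optional[Column]:
        for col in self.columns:
            if col.pos1 == pos1:
                return col
        return None


@dataclass
class Variant:
    gene_model_id: str
    position: int            # 1-based on the accession-1 gene model
    allele_1: str
    allele_2: str
    depth_1: float = 0.0
    depth_2: float = 0.0
    var_class: Optional[str] = None    # allelic_SNP / HSV / PSV / undetermined
    genome: str = ""
    filter_pass: Optional[bool] = None
    filter_reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.depth_1 < 0 or self.depth_2 < 0:
            raise ValueError("depths must be >= 0")


@dataclass
class FilterConfig:
    min_depth: float = 7.0
    flank_len: int = 50
    require_conserved_flanks: bool = True

    @property
    def window_len(self) -> int:
        return 2 * self.flank_len + 1


@dataclass
class MarkerRecord:
    marker_id: str
    category: str
    marker_sequence: str
    gene_model_id: str
    gene_A: str = ""
    gene_B: str = ""
    at_ortholog: str = ""
    block_id: str = ""
    variant_position: int = 0
    genome: str = ""
    mapped_lg: str = ""
    mapped_cm: Optional[float] = None


_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -7
_aligner.extend_gap_score = -2


def align_alleles(seq1: str, seq2: str, gene_model_id: str = "",
                  accessions=("line_1", "line_2"), depths=(0.0, 0.0),
                  window_len: int = 101,
                  max_mismatch_frac: float = 0.2) -> AllelicAlignment:
    """Align the overlapping region of two allelic gene-model sequences.

    The best local alignment is extended ungapped to the ends of the
    mutual overlap so edge substitutions are retained as columns.  If the
    overlap is shorter than ``window_len``, or the extended overlap
    mismatches at more than ``max_mismatch_frac`` of its columns (two
    fragments that do not truly overlap), the alignment is empty.
    """
    empty = AllelicAlignment(gene_model_id, accessions[0], accessions[1], [],
                             depths[0], depths[1])
    if not seq1 or not seq2:
        return empty
    alignments = _aligner.align(seq1, seq2)
    try:
        aln = alignments[0]
    except IndexError:
        return empty
    blocks1, blocks2 = aln.aligned
    columns = []
    prev1 = prev2 = None
    for (s1, e1), (s2, e2) in zip(blocks1, blocks2):
        if prev1 is not None:
            for p in range(prev1, s1):        # deletion in seq2
                columns.append(Column(p + 1, 0, seq1[p], "-"))
            for p in range(prev2, s2):        # insertion in seq2
                columns.append(Column(0, p + 1, "-", seq2[p]))
        for i in range(e1 - s1):
            columns.append(Column(s1 + i + 1, s2 + i + 1, seq1[s1 + i], seq2[s2 + i]))
        prev1, prev2 = e1, e2
    if not columns:
        return empty
    # ungapped extension of the terminal columns to the full overlap
    head = columns[0]
    while head.pos1 > 1 and head.pos2 > 1:
        p1, p2 = head.pos1 - 1, head.pos2 - 1
        head = Column(p1, p2, seq1[p1 - 1], seq2[p2 - 1])
        columns.insert(0, head)
    tail = columns[-1]
    while 0 < tail.pos1 < len(seq1) and 0 < tail.pos2 < len(seq2):
        p1, p2 = tail.pos1 + 1, tail.pos2 + 1
        tail = Column(p1, p2, seq1[p1 - 1], seq2[p2 - 1])
        columns.append(tail)
    if len(columns) < window_len:
        return empty
    mismatch_frac = sum(not c.is_match for c in columns) / len(columns)
    if mismatch_frac > max_mismatch_frac:
        return empty
    return AllelicAlignment(gene_model_id, accessions[0], accessions[1],
                            columns, depths[0], depths[1])


def call_snps(alignment: AllelicAlignment) -> list:
    """One Variant per substitution column; indel columns are excluded."""
    out = []
    for col in alignment.columns:
        if not col.is_gap and col.base1 != col.base2:
            out.append(Variant(
                gene_model_id=alignment.gene_model_id,
                position=col.pos1, allele_1=col.base1, allele_2=col.base2,
                depth_1=alignment.depth_1, depth_2=alignment.depth_2))
    return out


class HomoeologueProjection:
    """Maps accession-1 model positions onto an aligned homoeologue."""

    def __init__(self, seq_self: str, seq_homoeo: str):
        self.map = {}
        if not seq_self or not seq_homoeo:
            return
        aln = align_alleles(seq_self, seq_homoeo, window_len=1)
        for col in aln.columns:
            if col.pos1 > 0:
                self.map[col.pos1] = col.base2 if not col.is_gap else "-"

    def base_at(self, pos: int) -> Optional[str]:
        return self.map.get(pos)


def classify_site(acc1_g: str, acc2_g: str, homoeo_base: Optional[str],
                  paralogue_bases=()) -> str:
    """Classify one site of a gene model within its genome.

    ``acc1_g``/``acc2_g`` are the two accessions' bases within the focal
    genome; ``homoeo_base`` is the (accession-concordant) base of the
    other genome's homoeologue at the projected site, ``None`` when
    unprojectable.  ``paralogue_bases`` are bases of within-genome
    paralogues at the site.
    """
    if acc1_g != acc2_g:
        return "allelic_SNP"
    if any(p != acc1_g for p in paralogue_bases if p not in ("-", None)):
        return "PSV"
    if homoeo_base in ("-", None):
        return "undetermined" if homoeo_base == "-" else "concordant"
    if homoeo_base != acc1_g:
        return "HSV"
    return "concordant"


def classify_variant(variant: Variant,
                     homoeologue: Optional[HomoeologueProjection],
                     paralogue_bases=()) -> str:
    """Assign the variant class; see :func:`classify_site`.

    A site whose homoeologue projection falls in a gap is flagged
    ``undetermined`` rather than guessed.
    """
    homoeo_base = homoeologue.base_at(variant.position) if homoeologue else None
    cls = classify_site(variant.allele_1, variant.allele_2, homoeo_base,
                        paralogue_bases)
    variant.var_class = cls if cls != "concordant" else "undetermined"
    return variant.var_class


def kaspar_filter(variant: Variant, alignment: AllelicAlignment,
                  junctions: Optional[list],
                  config: FilterConfig = FilterConfig()) -> tuple:
    """Sequence-suitability screen for a co-dominant (KASP) assay.

    Pass iff both accessions' read depths reach ``min_depth``, the
    ``flank_len`` alignment columns on each side of the site exist and
    are conserved (no mismatch, no gap), and the window of
    ``2*flank_len + 1`` bases contains no exon-intron junction.
    ``junctions`` are 1-based gene-model positions; ``None`` means the
    exon structure is unknown and the junction check fails conservatively.
    """
    reasons = []
    if variant.depth_1 < config.min_depth or variant.depth_2 < config.min_depth:
        reasons.append("depth")
    idx = next((i for i, c in enumerate(alignment.columns)
                if c.pos1 == variant.position), None)
    if idx is None:
        reasons.append("flank")
    elif config.require_conserved_flanks:
        f = config.flank_len
        left = alignment.columns[max(0, idx - f):idx]
        right = alignment.columns[idx + 1:idx + 1 + f]
        if len(left) < f or len(right) < f or \
                not all(c.is_match for c in left + right):
            reasons.append("flank")
    if junctions is None:
        reasons.append("junction_unevaluable")
    else:
        lo, hi = variant.position - config.flank_len, variant.position + config.flank_len
        if any(lo <= j <= hi for j in junctions):
            reasons.append("junction")
    variant.filter_pass = not reasons
    variant.filter_reasons = reasons
    return variant.filter_pass, reasons


def classify_copy_category(k_A: int, k_B: int) -> str:
    """Copy-number category of a gene model across the two subgenomes."""
    if k_A < 0 or k_B < 0:
        raise ValueError("copy counts must be >= 0")
    if k_A == 0 and k_B == 0:
        raise ValueError("gene model absent from both genomes")
    if k_B == 0:
        return "A_only"
    if k_A == 0:
        return "i_B_unique"
    if k_A == 1 and k_B == 1:
        return "ii_single_copy_both"
    return "iii_multi_copy"


def design_marker_sequence(variant: Variant, model_seq: str,
                           variable_sites: dict, marker_id: str,
                           category: str = "", registry: Optional[set] = None,
                           flank_len: int = 50, **meta) -> MarkerRecord:
    """Render the marker window for a passing allelic SNP.

    ``variable_sites`` maps gene-model positions (within the window) to
    the pair of bases segregating there for a non-allelic reason
    (HSV/PSV); these are emitted as lower-case IUPAC degenerate codes.
    """
    p = variant.position
    if p - flank_len < 1 or p + flank_len > len(model_seq):
        raise ValueError("window extends past the gene model end")
    key = (variant.gene_model_id, p)
    if registry is not None:
        if key in registry:
            raise ValueError(f"duplicate marker for variant {key}")
        registry.add(key)
    parts = []
    for pos in range(p - flank_len, p + flank_len + 1):
        base = model_seq[pos - 1].upper()
        if pos == p:
            parts.append(f"[{variant.allele_1.upper()}/{variant.allele_2.upper()}]")
        elif pos in variable_sites:
            pair = frozenset(b.upper() for b in variable_sites[pos])
            code = IUPAC_PAIR.get(pair, base.lower()) if len(pair) == 2 else base.lower()
            parts.append(code)
        else:
            parts.append(base)
    return MarkerRecord(
        marker_id=marker_id, category=category, marker_sequence="".join(parts),
        gene_model_id=variant.gene_model_id, variant_position=p,
        genome=variant.genome, **meta)


def validate_marker_record(record: MarkerRecord, known_sites=None) -> None:
    """Check the marker-sequence conventions (one bracket, lower-case sites)."""
    seq = record.marker_sequence
    if seq.count("[") != 1 or seq.count("]") != 1:
        raise ValueError(f"{record.marker_id}: expected exactly one [X/Y] token")
    inner = seq[seq.index("[") + 1:seq.index("]")]
    if len(inner) != 3 or inner[1] != "/":
        raise ValueError(f"{record.marker_id}: malformed bracket token {inner!r}")
    if known_sites is not None:
        p = record.variant_position
        bracket_start = seq.index("[")
        bracket_end = seq.index("]")
        for i, ch in enumerate(seq):
            if not (ch.isalpha() and ch.islower()):
                continue
            if bracket_start < i < bracket_end:
                continue
            pos = p - bracket_start + i if i < bracket_start \
                else p + (i - bracket_end)
            if pos not in known_sites:
                raise ValueError(
                    f"{record.marker_id}: lower-case base at {pos} not a recorded site")


def funnel_report(stages: list) -> "object":
    """Validate and tabulate a marker-development funnel.

    ``stages`` is an ordered list of (name, count).  Counts must be
    monotone non-increasing; the removed column reconstructs
    kept + removed = previous stage.
    """
    import pandas as pd

    if not stages:
        raise ValueError("no stages registered")
    names = [n for n, _ in stages]
    counts = [int(c) for _, c in stages]
    for (na, a), (nb, b) in zip(stages, stages[1:]):
        if b > a:
            raise ValueError(f"funnel increases from {na} ({a}) to {nb} ({b})")
        if a < 0 or b < 0:
            raise ValueError("negative stage count")
    removed = [0] + [a - b for a, b in zip(counts, counts[1:])]
    return pd.DataFrame({"stage": names, "count": counts, "removed": removed})
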