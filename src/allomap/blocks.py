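"""Ancestral gene-block painting of linkage maps and A/B comparison.

The 24 collinear ancestral crucifer blocks (A-X) are defined as closed
intervals of *A. thaliana* gene IDs.  Markers carrying an At ortholog
are assigned to every block interval containing the ID; runs of
consecutive same-block markers on a linkage group become block calls
under per-genome evidence rules (a single marker suffices on the
well-covered A genome, two or more are required on the B genome).
Homoeologous blocks between the genomes are inferred from shared
single-copy (category-ii) markers, and per-block segmentation is
compared to classify fragmentation differences.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

AT_ID_RE = re.compile(r"^At([1-5])g(\d{5})$", re.IGNORECASE)


@functools.total_ordering
@dataclass(frozen=True)
class AtGeneId:
    chromosome: int
    number: int

    def __post_init__(self):
        if not 1 <= self.chromosome <= 5:
            raise ValueError("At chromosome must be 1-5")
        if not 0 <= self.number <= 99999:
            raise ValueError("At gene number must have 5 digits")

    def __lt__(self, other):
        return (self.chromosome, self.number) < (other.chromosome, other.number)

    def __str__(self):
        return f"At{self.chromosome}g{self.number:05d}"


def parse_at_id(text: str) -> AtGeneId:
    m = AT_ID_RE.match(text.strip())
    if not m:
        raise ValueError(f"not an A. thaliana gene id: {text!r}")
    return AtGeneId(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class BlockDefinition:
    block_id: str
    subgenome_class: str
    reference_lg: str
    at_start: AtGeneId
    at_end: AtGeneId
    sub_label: str = ""

    def __post_init__(self):
        if self.at_start.chromosome != self.at_end.chromosome:
            raise ValueError(f"block {self.block_id}: interval spans chromosomes")
        if self.at_end < self.at_start:
            raise ValueError(f"block {self.block_id}: start > end")

    @property
    def key(self) -> tuple:
        return (self.block_id, self.subgenome_class)

    def contains(self, at: AtGeneId) -> bool:
        return self.at_start <= at <= self.at_end


def block_table_to_definitions(table: pd.DataFrame) -> list:
    return [BlockDefinition(
        block_id=row.block_id, subgenome_class=row.subgenome_class,
        reference_lg=row.reference_lg, at_start=parse_at_id(row.at_start),
        at_end=parse_at_id(row.at_end),
        sub_label=getattr(row, "sub_label", "") or "")
        for row in table.itertuples()]


def assign_marker_block(at_id: AtGeneId, definitions: list) -> list:
    """All block definitions whose closed At interval contains the id."""
    return [d for d in definitions if d.contains(at_id)]


@dataclass
class BlockCall:
    lg_id: str
    genome: str
    block_id: str
    subgenome_class: str
    supporting_markers: list
    cm_start: float
    cm_end: float
    at_span: tuple                       # (min AtGeneId, max AtGeneId)
    orientation: str = "undetermined"    # + / - / undetermined

    @property
    def key(self) -> tuple:
        return (self.block_id, self.subgenome_class)


DEFAULT_MIN_MARKERS = {"A": 1, "B": 2}


def call_blocks(markers: pd.DataFrame, genome: str,
                definitions: list,
                min_markers: Optional[dict] = None) -> list:
    """Call blocks from a painted linkage group's ordered markers.

    ``markers`` needs columns ``marker_id``, ``lg_id``, ``position_cM``
    and ``at_id``; an optional ``subgenome_class`` column restricts a
    marker's candidates to that class (the triplicated copies of a block
    share one At interval, so the class of the source reference gene is
    what tells them apart).  Maximal runs of consecutive markers
    attributable to the same (block, subgenome class) become calls when
    the run reaches the genome's evidence threshold.  A marker whose At
    id falls in several candidate intervals joins whichever candidate
    continues the current run; an unambiguous marker of another block
    breaks a run.
    Orientation is the sign of the rank correlation between At order and
    cM order (undetermined for ties or single markers).
    """
    minm = dict(DEFAULT_MIN_MARKERS)
    if min_markers:
        minm.update(min_markers)
    need = minm[genome]
    calls = []
    for lg_id, sub in markers.groupby("lg_id"):
        sub = sub.sort_values("position_cM")
        runs = []          # list of (key, [rows])
        for row in sub.itertuples():
            try:
                at = parse_at_id(row.at_id)
            except ValueError:
                continue
            cands = {d.key for d in assign_marker_block(at, definitions)}
            cls = getattr(row, "subgenome_class", "")
            if isinstance(cls, str) and cls:
                narrowed = {k for k in cands if k[1] == cls}
                cands = narrowed or cands
            if not cands:
                continue
            if runs and runs[-1][0] in cands:
                runs[-1][1].append((row, at))
            else:
                # open a new run; a marker ambiguous between candidates
                # starts the lexicographically first one (deterministic) —
                # later unambiguous markers re-anchor the run structure
                runs.append((sorted(cands)[0], [(row, at)]))
        for key, members in runs:
            if len(members) < need:
                continue
            ats = [at for _, at in members]
            cms = [r.position_cM for r, _ in members]
            orientation = "undetermined"
            if len(members) >= 2 and len(set(ats)) > 1 and len(set(cms)) > 1:
                at_order = sorted(set(ats))
                ranks = [at_order.index(a) for a in ats]
                rho = stats.spearmanr(ranks, cms).statistic
                if rho > 0:
                    orientation = "+"
                elif rho < 0:
                    orientation = "-"
            calls.append(BlockCall(
                lg_id=lg_id, genome=genome, block_id=key[0],
                subgenome_class=key[1],
                supporting_markers=[r.marker_id for r, _ in members],
                cm_start=float(min(cms)), cm_end=float(max(cms)),
                at_span=(min(ats), max(ats)), orientation=orientation))
    return calls


@dataclass
class HomoeologyLink:
    block_call_A: BlockCall
    block_call_B: BlockCall
    shared_single_copy_markers: list

    def __post_init__(self):
        if self.block_call_A.block_id != self.block_call_B.block_id:
            raise ValueError("homoeology link requires the same block id")


def _spans_overlap(a: tuple, b: tuple) -> bool:
    return (a[0].chromosome == b[0].chromosome
            and a[0] <= b[1] and b[0] <= a[1])


def infer_homoeology(calls_A: list, calls_B: list,
                     marker_families: dict, category_ii: set,
                     min_shared: int = 2) -> list:
    """Link same-block calls on the two genomes via shared category-ii markers.

    ``marker_families`` maps marker id -> gene-family id; a family counts
    as shared when category-ii markers from it support a call on both
    genomes and the two calls' At spans overlap.  A call may link to
    several LGs (block triplication).
    """
    links = []
    for ca in calls_A:
        fams_a = {marker_families[m] for m in ca.supporting_markers
                  if m in marker_families and marker_families[m] in category_ii}
        for cb in calls_B:
            if ca.key != cb.key or not _spans_overlap(ca.at_span, cb.at_span):
                continue
            fams_b = {marker_families[m] for m in cb.supporting_markers
                      if m in marker_families and marker_families[m] in category_ii}
            shared = sorted(fams_a & fams_b)
            if len(shared) >= min_shared:
                links.append(HomoeologyLink(ca, cb, shared))
    return links


@dataclass
class FragmentationRecord:
    block_id: str
    subgenome_class: str
    segments_A: list                 # (lg_id, at_span) per merged segment
    segments_B: list
    classification: str              # intact_both / split_in_A / split_in_B /
                                     # split_both / duplicated / absent_in_one


def _merge_calls(calls: list) -> tuple:
    """Merge a block's calls into one segment per LG.

    Fragmentation means parts of a block on *different* LGs; same-LG
    interruptions by inserted blocks keep the block one unit there, so
    all same-LG calls collapse to a single spanning segment.
    """
    by_lg = {}
    for c in calls:
        by_lg.setdefault(c.lg_id, []).append(c)
    segments = []
    for lg, cs in sorted(by_lg.items()):
        segments.append((lg, (min(c.at_span[0] for c in cs),
                              max(c.at_span[1] for c in cs))))
    # duplication: two segments (necessarily on different LGs after merging)
    # whose At spans overlap by >= 50% of the shorter span
    duplicated = False
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            (l1, s1), (l2, s2) = segments[i], segments[j]
            if s1[0].chromosome != s2[0].chromosome:
                continue
            lo = max(s1[0].number, s2[0].number)
            hi = min(s1[1].number, s2[1].number)
            if hi < lo:
                continue
            shorter = min(s1[1].number - s1[0].number, s2[1].number - s2[0].number)
            if shorter == 0 or (hi - lo) / shorter >= 0.5:
                duplicated = True
    return segments, duplicated


def fragmentation_compare(block_id: str, subgenome_class: str,
                          calls_A: list, calls_B: list) -> FragmentationRecord:
    """Compare a block's segmentation between the two genomes."""
    mine_A = [c for c in calls_A if c.key == (block_id, subgenome_class)]
    mine_B = [c for c in calls_B if c.key == (block_id, subgenome_class)]
    seg_A, dup_A = _merge_calls(mine_A)
    seg_B, dup_B = _merge_calls(mine_B)
    if not seg_A or not seg_B:
        cls = "absent_in_one"
    elif dup_A or dup_B:
        cls = "duplicated"
    elif len(seg_A) >= 2 and len(seg_A) > len(seg_B):
        cls = "split_in_A"
    elif len(seg_B) >= 2 and len(seg_B) > len(seg_A):
        cls = "split_in_B"
    elif len(seg_A) >= 2 and len(seg_B) >= 2:
        cls = "split_both"
    else:
        cls = "intact_both"
    return FragmentationRecord(block_id, subgenome_class, seg_A, seg_B, cls)


def lg_motifs(calls: list) -> dict:
    """Ordered block-letter adjacency motif of each LG (by cM midpoint)."""
    by_lg = {}
    for c in calls:
        by_lg.setdefault(c.lg_id, []).append(c)
    out = {}
    for lg, cs in by_lg.items():
        cs = sorted(cs, key=lambda c: (c.cm_start + c.cm_end) / 2.0)
        motif = []
        for c in cs:
            if not motif or motif[-1] != c.block_id:
                motif.append(c.block_id)
        out[lg] = tuple(motif)
    return out


def association_motifs(calls_A: list, calls_B: list, min_len: int = 2) -> dict:
    """Per-genome LG motifs plus cross-genome shared motifs.

    A shared motif is a maximal contiguous block sequence (length >=
    ``min_len``) occurring on an LG of each genome, compared
    reversal-invariantly.
    """
    motifs_A = lg_motifs(calls_A)
    motifs_B = lg_motifs(calls_B)

    def subseqs(motif):
        for i in range(len(motif)):
            for j in range(i + min_len, len(motif) + 1):
                yield motif[i:j]

    shared = {}
    for lg_a, ma in motifs_A.items():
        subs_a = set(subseqs(ma))
        for lg_b, mb in motifs_B.items():
            hits = [s for s in subseqs(mb) if s in subs_a or s[::-1] in subs_a]
            # keep only maximal hits
            maximal = [h for h in hits
                       if not any(len(o) > len(h) and _contains(o, h) for o in hits)]
            for h in maximal:
                canon = min(h, h[::-1])
                shared.setdefault(canon, []).append((lg_a, lg_b))
    return {"A": motifs_A, "B": motifs_B, "shared": shared}


def _contains(big: tuple, small: tuple) -> bool:
    n, m = len(big), len(small)
    rev = small[::-1]
    return any(big[i:i + m] in (small, rev) for i in range(n - m + 1))
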