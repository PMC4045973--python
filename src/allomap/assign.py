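"""Two-step classification of allotetraploid contigs into subgenomes.

Step 1 groups contigs to reference gene families by translated search
against the A-genome (B. rapa-like) protein set.  Step 2 compares each
grouped contig at the nucleotide level with the A-genome CDS set and the
B-genome transcriptome and assigns it to the genome of its
maximum-identity hit.  Contigs without a hit better than the keep rule
(>80% identity over >100 aligned bases, the contrapositive of the
published removal rule) are removed.  Contigs with no protein hit at all
are screened separately: matches to the A-genome reference are removed,
remaining matches to the B transcriptome become B-specific contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .align import (BlastNucleotideIndex, BlastProteinIndex, IdentityResult,
                    nucleotide_identity)

VERDICTS = ("A", "B", "B_specific", "ambiguous", "removed")


@dataclass
class Contig:
    id: str
    accession: str
    sequence: str
    mean_depth: float = 0.0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"contig {self.id}: empty sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"contig {self.id}: alphabet must be ACGTN")
        if self.mean_depth < 0:
            raise ValueError(f"contig {self.id}: negative depth")


@dataclass
class AssignConfig:
    evalue_max: float = 1e-5
    min_identity_pct: float = 80.0   # exclusive keep threshold
    min_aligned_len: int = 100       # exclusive keep threshold
    secondary_hit_margin_pct: float = 5.0

    def __post_init__(self):
        if self.evalue_max <= 0 or self.min_identity_pct <= 0 or self.min_aligned_len <= 0:
            raise ValueError("assignment thresholds must be positive")


@dataclass
class Assignment:
    contig_id: str
    verdict: str
    gene_model_id: Optional[str] = None
    best_identity: Optional[IdentityResult] = None
    step: str = "nucleotide"        # protein / nucleotide / orphan
    reason: str = ""
    secondary_hits: list = field(default_factory=list)

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"invalid verdict {self.verdict}")
        if self.verdict in ("A", "B") and not self.gene_model_id:
            raise ValueError("A/B verdict requires a gene_model_id")
        if self.verdict == "removed" and not self.reason:
            raise ValueError("removed verdict requires a reason")


def _passes_keep_rule(hit: IdentityResult, config: AssignConfig) -> bool:
    return (hit.identity_pct > config.min_identity_pct
            and hit.aligned_length > config.min_aligned_len)


def assign_contig(contig: Contig, hits_A: list, hits_B: list,
                  config: AssignConfig = AssignConfig()) -> Assignment:
    """Assign one contig from its nucleotide-identity hits on both references.

    Removed unless some hit exceeds the keep rule; otherwise the genome
    of the maximum-identity passing hit wins, with an exact tie between
    the best A and best B identity yielding ``ambiguous``.
    """
    passing_A = [h for h in hits_A if _passes_keep_rule(h, config)]
    passing_B = [h for h in hits_B if _passes_keep_rule(h, config)]
    if not passing_A and not passing_B:
        return Assignment(contig.id, "removed", reason="below_identity_threshold")
    best_A = max(passing_A, key=lambda h: (h.identity_pct, h.aligned_length),
                 default=None)
    best_B = max(passing_B, key=lambda h: (h.identity_pct, h.aligned_length),
                 default=None)
    if best_A and best_B and best_A.identity_pct == best_B.identity_pct:
        return Assignment(contig.id, "ambiguous",
                          best_identity=best_A, reason="tied_best_identity")
    if best_B is None or (best_A is not None
                          and best_A.identity_pct > best_B.identity_pct):
        verdict, best, pool = "A", best_A, passing_A
    else:
        verdict, best, pool = "B", best_B, passing_B
    secondary = sorted(
        {h.reference_id for h in pool
         if h.reference_id != best.reference_id
         and best.identity_pct - h.identity_pct <= config.secondary_hit_margin_pct})
    return Assignment(contig.id, verdict, gene_model_id=best.reference_id,
                      best_identity=best, secondary_hits=secondary)


def classify_orphans(contigs: list, genome_reference: dict, b_transcriptome: dict,
                     config: AssignConfig = AssignConfig(),
                     genome_index: BlastNucleotideIndex = None,
                     b_index: BlastNucleotideIndex = None) -> list:
    """Screen contigs that had no protein hit.

    A match to the (A) genome reference above the keep rule removes the
    contig; otherwise a match to the B transcriptome marks it
    B-specific; anything else is removed as unclassified.
    """
    out = []
    genome_index = genome_index or (BlastNucleotideIndex(genome_reference)
                                    if genome_reference else None)
    b_index = b_index or (BlastNucleotideIndex(b_transcriptome)
                          if b_transcriptome else None)
    queries = {c.id: c.sequence for c in contigs}
    g_hits = genome_index.search(queries) if (genome_index and queries) else None
    b_hits = b_index.search(queries) if (b_index and queries) else None

    def best_identity(contig, hits_df, refs):
        if hits_df is None:
            return None
        cands = hits_df[hits_df["qid"] == contig.id]["sid"].head(6)
        best = None
        for sid in cands:
            res = nucleotide_identity(contig.sequence, refs[sid], sid)
            if best is None or (res.identity_pct, res.aligned_length) > (
                    best.identity_pct, best.aligned_length):
                best = res
        return best

    for contig in contigs:
        g_best = best_identity(contig, g_hits, genome_reference)
        if g_best is not None and _passes_keep_rule(g_best, config):
            out.append(Assignment(contig.id, "removed", step="orphan",
                                  best_identity=g_best, reason="matches_genome_reference"))
            continue
        b_best = best_identity(contig, b_hits, b_transcriptome)
        if b_best is not None and _passes_keep_rule(b_best, config):
            out.append(Assignment(contig.id, "B_specific", step="orphan",
                                  gene_model_id=b_best.reference_id,
                                  best_identity=b_best))
            continue
        out.append(Assignment(contig.id, "removed", step="orphan",
                              reason="unclassified"))
    return out


def group_gene_models(assignments: list) -> dict:
    """Group A/B-verdict contigs by (accession-agnostic) gene model.

    Returns {"A": {gene_model_id: [assignment, ...]}, "B": {...}}.
    """
    groups = {"A": {}, "B": {}}
    for a in assignments:
        if a.verdict in ("A", "B"):
            groups[a.verdict].setdefault(a.gene_model_id, []).append(a)
    return groups


def coverage_report(groups: dict, reference_lengths: dict,
                    bin_edges=(0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0)) -> pd.DataFrame:
    """Histogram of per-gene-model coverage fractions.

    Coverage is the union of contig-to-reference aligned spans divided by
    the reference length; the histogram counts gene models and sums to
    their number.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or edges[0] < 0 or edges[-1] > 1:
        raise ValueError("bin edges must be ascending within [0,1]")
    rows = []
    for genome, models in groups.items():
        for gene_id, assigns in models.items():
            length = reference_lengths[gene_id]
            if length <= 0:
                raise ValueError(f"zero-length reference {gene_id}")
            rows.append((genome, gene_id,
                         coverage_fraction(assigns, length)))
    df = pd.DataFrame(rows, columns=["genome", "gene_model_id", "coverage"])
    counts, _ = np.histogram(df["coverage"], bins=edges) if len(df) else (
        np.zeros(len(edges) - 1, dtype=int), None)
    # right-closed top bin so coverage 1.0 is counted
    hist = pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "n_gene_models": counts})
    return df, hist


def coverage_fraction(assignments: list, reference_length: int) -> float:
    """Union of 1-based closed aligned spans over the reference length."""
    spans = sorted((a.best_identity.ref_start, a.best_identity.ref_end)
                   for a in assignments
                   if a.best_identity is not None and a.best_identity.aligned_length > 0)
    covered, cur = 0, None
    for s, e in spans:
        if cur is None:
            cur = [s, e]
        elif s <= cur[1] + 1:
            cur[1] = max(cur[1], e)
        else:
            covered += cur[1] - cur[0] + 1
            cur = [s, e]
    if cur is not None:
        covered += cur[1] - cur[0] + 1
    return min(1.0, covered / reference_length)


def run_assignment(contigs: list, proteins_A: dict, cds_A: dict,
                   transcripts_B: dict,
                   config: AssignConfig = AssignConfig()) -> list:
    """Full two-step batch classification of a contig set.

    Every contig receives exactly one verdict; the per-step counts form
    the top of the marker-development funnel.
    """
    protein_index = BlastProteinIndex(proteins_A)
    combined = {f"A|{k}": v for k, v in cds_A.items()}
    combined.update({f"B|{k}": v for k, v in transcripts_B.items()})
    nt_index = BlastNucleotideIndex(combined)

    queries = {c.id: c.sequence for c in contigs}
    prot_hits = protein_index.search(queries, evalue_max=config.evalue_max)
    with_hit = set(prot_hits["qid"])
    grouped = [c for c in contigs if c.id in with_hit]
    orphans = [c for c in contigs if c.id not in with_hit]

    nt_hits = nt_index.search({c.id: c.sequence for c in grouped}) \
        if grouped else pd.DataFrame(columns=["qid", "sid"])
    by_contig = dict(tuple(nt_hits.groupby("qid"))) if len(nt_hits) else {}

    assignments = []
    for contig in grouped:
        hits_A, hits_B = [], []
        cand = by_contig.get(contig.id)
        sids = list(cand["sid"].head(10)) if cand is not None else []
        for sid in sids:
            genome, ref_id = sid.split("|", 1)
            refs = cds_A if genome == "A" else transcripts_B
            res = nucleotide_identity(contig.sequence, refs[ref_id], ref_id)
            (hits_A if genome == "A" else hits_B).append(res)
        assignments.append(assign_contig(contig, hits_A, hits_B, config))

    # orphan branch reuses the A CDS set as the genome-reference screen
    a_index = BlastNucleotideIndex(cds_A)
    b_index = BlastNucleotideIndex(transcripts_B)
    assignments.extend(classify_orphans(
        orphans, cds_A, transcripts_B, config,
        genome_index=a_index, b_index=b_index))
    return assignments


def assignments_to_frame(assignments: list) -> pd.DataFrame:
    rows = []
    for a in assignments:
        b = a.best_identity
        rows.append({
            "contig_id": a.contig_id, "verdict": a.verdict,
            "gene_model_id": a.gene_model_id or "",
            "identity_pct": round(b.identity_pct, 3) if b else "",
            "aligned_length": b.aligned_length if b else "",
            "ref_start": b.ref_start if b else "",
            "ref_end": b.ref_end if b else "",
            "strand": b.strand if b else "",
            "step": a.step, "reason": a.reason,
            "secondary_hits": ";".join(a.secondary_hits),
        })
    return pd.DataFrame(rows)
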