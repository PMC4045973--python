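"""Alignment engines behind contig classification and variant calling.

Two engines are wrapped here:

* NCBI BLAST+ (``blastx``/``blastn`` on PATH) for database search — the
  translated protein search and the nucleotide candidate search.  BLAST
  reports genuine Karlin–Altschul E-values for the best local alignment
  over six-frame translations, which is exactly the contract the
  classification step needs.
* edlib for the authoritative percent-identity computation between a
  contig and a nominated reference sequence, so identity and aligned
  length have a single engine-independent definition (alignment columns
  of the best semi-global alignment on either strand).
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from .io import write_fasta

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class MissingToolError(RuntimeError):
    pass


def _require(tool: str) -> str:
    path = shutil.which(tool)
    if path is None:
        raise MissingToolError(f"required executable not found on PATH: {tool}")
    return path


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class IdentityResult:
    """Best-alignment identity of a contig against one reference sequence."""

    reference_id: str
    identity_pct: float
    aligned_length: int
    strand: str                  # "+" or "-"
    ref_start: int = 0           # 1-based closed span on the reference,
    ref_end: int = 0             # strand-normalized (start <= end)


def _cigar_stats(cigar: str):
    columns = matches = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return columns, matches


def _identity_one_strand(query: str, target: str, reference_id: str, strand: str):
    # semi-global: the shorter sequence is aligned within the longer one
    swapped = len(query) > len(target)
    q, t = (target, query) if swapped else (query, target)
    res = edlib.align(q, t, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    # among cost-ties prefer the pure-substitution placement (span equals
    # the query length); edlib's first location can otherwise trade a
    # terminal mismatch for an indel and shift the span by one
    loc = None
    for cand in res["locations"]:
        if cand[1] - cand[0] + 1 == len(q):
            loc = cand
            break
    if loc is not None:
        sub = t[loc[0]:loc[1] + 1]
        columns = len(q)
        matches = sum(a == b for a, b in zip(q, sub))
    else:
        columns, matches = _cigar_stats(res["cigar"])
        loc = res["locations"][0]
    if columns == 0:
        return None
    if swapped:
        # the reference sat fully inside the contig: span is the whole reference
        ref_start, ref_end = 1, len(target)
    else:
        ref_start, ref_end = loc[0] + 1, loc[1] + 1
    return IdentityResult(
        reference_id=reference_id,
        identity_pct=100.0 * matches / columns,
        aligned_length=columns,
        strand=strand,
        ref_start=ref_start,
        ref_end=ref_end,
    )


def nucleotide_identity(contig_seq: str, reference_seq: str,
                        reference_id: str = "ref") -> IdentityResult:
    """Best semi-global alignment identity on either strand.

    identity_pct = matches / alignment_columns x 100; aligned_length is
    the number of alignment columns.  When no alignment exists (empty
    input) an empty result with aligned_length 0 is returned.
    """
    if not contig_seq or not reference_seq:
        return IdentityResult(reference_id, 0.0, 0, "+")
    best = None
    for strand, seq in (("+", contig_seq), ("-", reverse_complement(contig_seq))):
        res = _identity_one_strand(seq, reference_seq, reference_id, strand)
        if res is None:
            continue
        if best is None or (res.identity_pct, res.aligned_length) > (
                best.identity_pct, best.aligned_length):
            best = res
    return best or IdentityResult(reference_id, 0.0, 0, "+")


class BlastProteinIndex:
    """A protein database searchable with translated (six-frame) queries."""

    def __init__(self, proteins: dict):
        if not proteins:
            raise ValueError("protein set must be non-empty")
        _require("makeblastdb")
        _require("blastx")
        self._tmp = tempfile.TemporaryDirectory(prefix="allomap_blastp_")
        fasta = Path(self._tmp.name) / "db.faa"
        write_fasta(fasta, proteins)
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot",
             "-out", str(Path(self._tmp.name) / "db")],
            check=True, capture_output=True)
        self._db = str(Path(self._tmp.name) / "db")

    def search(self, queries: dict, evalue_max: float = 1e-5) -> pd.DataFrame:
        """Run blastx; returns qid/sid/pident/length/evalue/bitscore rows
        sorted by (qid, bitscore desc), already thresholded on E-value."""
        if not queries:
            return pd.DataFrame(
                columns=["qid", "sid", "pident", "length", "evalue", "bitscore"])
        with tempfile.NamedTemporaryFile("w", suffix=".fna", delete=False) as fh:
            qpath = fh.name
        write_fasta(qpath, queries)
        proc = subprocess.run(
            ["blastx", "-query", qpath, "-db", self._db,
             "-evalue", str(evalue_max), "-num_threads", "1",
             "-outfmt", "6 qseqid sseqid pident length evalue bitscore"],
            check=True, capture_output=True, text=True)
        Path(qpath).unlink(missing_ok=True)
        rows = [line.split("\t") for line in proc.stdout.splitlines()]
        df = pd.DataFrame(
            rows, columns=["qid", "sid", "pident", "length", "evalue", "bitscore"])
        for col, typ in (("pident", float), ("length", int),
                         ("evalue", float), ("bitscore", float)):
            df[col] = df[col].astype(typ)
        df = df.sort_values(["qid", "bitscore"], ascending=[True, False])
        return df.reset_index(drop=True)


class BlastNucleotideIndex:
    """A nucleotide database used to nominate alignment candidates."""

    def __init__(self, sequences: dict):
        if not sequences:
            raise ValueError("sequence set must be non-empty")
        _require("makeblastdb")
        _require("blastn")
        self._tmp = tempfile.TemporaryDirectory(prefix="allomap_blastn_")
        fasta = Path(self._tmp.name) / "db.fna"
        write_fasta(fasta, sequences)
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "nucl",
             "-out", str(Path(self._tmp.name) / "db")],
            check=True, capture_output=True)
        self._db = str(Path(self._tmp.name) / "db")

    def search(self, queries: dict, evalue_max: float = 1e-10,
               max_targets: int = 12) -> pd.DataFrame:
        if not queries:
            return pd.DataFrame(
                columns=["qid", "sid", "pident", "length", "evalue", "bitscore"])
        with tempfile.NamedTemporaryFile("w", suffix=".fna", delete=False) as fh:
            qpath = fh.name
        write_fasta(qpath, queries)
        proc = subprocess.run(
            ["blastn", "-task", "blastn", "-query", qpath, "-db", self._db,
             "-evalue", str(evalue_max), "-num_threads", "1",
             "-max_target_seqs", str(max_targets),
             "-outfmt", "6 qseqid sseqid pident length evalue bitscore"],
            check=True, capture_output=True, text=True)
        Path(qpath).unlink(missing_ok=True)
        rows = [line.split("\t") for line in proc.stdout.splitlines()]
        df = pd.DataFrame(
            rows, columns=["qid", "sid", "pident", "length", "evalue", "bitscore"])
        for col, typ in (("pident", float), ("length", int),
                         ("evalue", float), ("bitscore", float)):
            df[col] = df[col].astype(typ)
        df = df.sort_values(["qid", "bitscore"], ascending=[True, False])
        return df.reset_index(drop=True)


def translated_best_hits(contig_seq: str, proteins, evalue_max: float = 1e-5) -> list:
    """Ranked translated-search hits of one contig against a protein set.

    ``proteins`` is either an id -> sequence dict or a prebuilt
    :class:`BlastProteinIndex`.  Returns (protein_id, bitscore, evalue)
    tuples sorted by score; contigs shorter than one codon yield no hits.
    """
    if not contig_seq:
        raise ValueError("empty contig")
    if len(contig_seq) < 3:
        return []
    index = proteins if isinstance(proteins, BlastProteinIndex) \
        else BlastProteinIndex(proteins)
    df = index.search({"query": contig_seq}, evalue_max=evalue_max)
    return [(r.sid, r.bitscore, r.evalue) for r in df.itertuples()]
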