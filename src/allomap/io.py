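"""File round-tripping for the pipeline's plain-text interchange formats.

FASTA goes through Biopython; the tabular sidecars (per-contig depth,
genotype matrix, truth tables, block tables) are TSV via pandas.  Exon
structures are written as GFF3 in transcript coordinates (1-based closed
intervals, seqid = gene id).
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_HEADER = "##gff-version 3"


def write_fasta(path, records: dict) -> None:
    """Write an id -> sequence mapping as FASTA (sorted by id)."""
    recs = [SeqRecord(Seq(records[k]), id=k, description="") for k in sorted(records)]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_depth_tsv(path, depths: dict) -> None:
    df = pd.DataFrame(sorted(depths.items()), columns=["contig_id", "mean_depth"])
    df.to_csv(path, sep="\t", index=False)


def read_depth_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["contig_id"], df["mean_depth"].astype(float)))


def write_genotypes_tsv(path, matrix: pd.DataFrame) -> None:
    """Genotype matrix: rows = markers, columns = individuals, values a/b/-."""
    matrix.to_csv(path, sep="\t", index_label="marker_id")


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="marker_id", dtype=str)
    bad = set(df.values.ravel()) - {"a", "b", "-"}
    if bad:
        raise ValueError(f"genotype matrix contains invalid calls: {sorted(bad)}")
    return df


def write_exons_gff3(path, genes) -> None:
    """Write exon structures of ReferenceGene records as transcript-space GFF3."""
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for gene in sorted(genes, key=lambda g: g.id):
            end = len(gene.sequence)
            fh.write(f"{gene.id}\tallomap\tgene\t1\t{end}\t.\t+\t.\tID={gene.id}\n")
            pos = 0
            for k, length in enumerate(gene.exon_lengths, start=1):
                fh.write(f"{gene.id}\tallomap\texon\t{pos + 1}\t{pos + length}\t.\t+\t.\t"
                         f"ID={gene.id}.exon{k};Parent={gene.id}\n")
                pos += length


def read_exons_gff3(path) -> dict:
    """Read a transcript-space GFF3 back into gene id -> exon length list."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols)
    exons = df[df["type"] == "exon"].sort_values(["seqid", "start"])
    out: dict = {}
    for row in exons.itertuples():
        out.setdefault(row.seqid, []).append(int(row.end) - int(row.start) + 1)
    return out


def junctions_from_exon_lengths(exon_lengths) -> list:
    """Transcript-coordinate junction positions (last base of each exon but one)."""
    out, pos = [], 0
    for length in exon_lengths[:-1]:
        pos += length
        out.append(pos)
    return out


def write_block_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_block_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"block_id", "subgenome_class", "reference_lg", "at_start", "at_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    return df


def write_truth_tables(outdir, truth) -> None:
    """Write the machine-checkable truth sidecars of a synthetic run."""
    from pathlib import Path

    outdir = Path(outdir)
    pd.DataFrame(sorted(truth.truth_assignment.items()),
                 columns=["contig_id", "genome"]).to_csv(
        outdir / "truth_assignment.tsv", sep="\t", index=False)
    pd.DataFrame([vars(v) for v in truth.truth_variants]).to_csv(
        outdir / "truth_variants.tsv", sep="\t", index=False)
    rows = [(lg, m, p) for lg, loci in sorted(truth.true_map.items()) for m, p in loci]
    pd.DataFrame(rows, columns=["lg_id", "locus_id", "position_cM"]).to_csv(
        outdir / "truth_map.tsv", sep="\t", index=False)
    import json

    (outdir / "truth_layout.json").write_text(json.dumps(
        {"layout_A": truth.layout_A, "layout_B": truth.layout_B,
         "events_A": truth.events_A, "events_B": truth.events_B},
        indent=1, sort_keys=True))
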