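"""End-to-end orchestration: simulate -> assign -> snps -> map -> blocks.

Stages communicate through plain-text files so each one is runnable
standalone on the outputs of the previous stage.  The run report keeps
in/out counts at every filter so the marker-development funnel can be
reconstructed (and re-counted) from the written tables alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .assign import (AssignConfig, Contig, assignments_to_frame,
                     coverage_report, group_gene_models, run_assignment)
from .blocks import (association_motifs, block_table_to_definitions,
                     call_blocks, fragmentation_compare, infer_homoeology)
from .linkage import build_map, map_to_frame
from .simulate import SimConfig, simulate_truth_set, synthetic_block_table
from .snp import (FilterConfig, HomoeologueProjection, MARKER_PREFIX,
                  align_alleles, call_snps, classify_copy_category,
                  classify_variant, design_marker_sequence, funnel_report,
                  kaspar_filter)


@dataclass
class PipelineConfig:
    workdir: str = "pipeline_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: [
        "simulate", "assign", "snps", "map", "blocks", "report"])
    sim: SimConfig = None
    assign: AssignConfig = field(default_factory=AssignConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    lod_threshold: float = 4.0
    alpha: float = 0.05
    min_shared: int = 2
    min_markers: dict = field(default_factory=lambda: {"A": 1, "B": 2})

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "assign" in d and isinstance(d["assign"], dict):
            d["assign"] = AssignConfig(**d["assign"])
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterConfig(**d["filter"])
        return cls(**d)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth_set(config.sim)
    aio.write_fasta(outdir / "contigs.fasta",
                    {c.id: c.sequence for c in truth.contigs})
    aio.write_depth_tsv(outdir / "contig_depth.tsv",
                        {c.id: c.mean_depth for c in truth.contigs})
    aio.write_fasta(outdir / "refA_cds.fasta",
                    {g.id: g.sequence for g in truth.reference_A})
    from Bio.Seq import Seq
    aio.write_fasta(outdir / "refA_proteins.fasta",
                    {g.id: str(Seq(g.sequence).translate()).replace("*", "X")
                     for g in truth.reference_A})
    aio.write_exons_gff3(outdir / "refA_exons.gff3", truth.reference_A)
    aio.write_fasta(outdir / "refB_transcripts.fasta",
                    {g.id: g.sequence for g in truth.reference_B})
    meta = pd.DataFrame(
        [{"gene_id": g.id, "genome": g.genome, "family_id": g.family_id,
          "block_id": g.block_id, "subgenome_class": g.subgenome_class,
          "at_id": g.at_id, "length": len(g.sequence)}
         for g in truth.reference_A + truth.reference_B])
    meta.to_csv(outdir / "reference_genes.tsv", sep="\t", index=False)
    aio.write_block_table(outdir / "block_table.tsv", synthetic_block_table(truth))
    aio.write_genotypes_tsv(outdir / "genotypes.tsv", truth.dh_genotypes)
    aio.write_truth_tables(outdir, truth)
    (outdir / "sim_config.json").write_text(config.sim.to_json())
    return {"n_contigs": len(truth.contigs),
            "n_reference_A": len(truth.reference_A),
            "n_reference_B": len(truth.reference_B),
            "n_truth_variants": len(truth.truth_variants)}


def stage_assign(config: PipelineConfig, outdir: Path) -> dict:
    seqs = aio.read_fasta(outdir / "contigs.fasta")
    depths = aio.read_depth_tsv(outdir / "contig_depth.tsv")
    contigs = [Contig(cid, cid.split("|", 1)[0], seq, depths.get(cid, 0.0))
               for cid, seq in sorted(seqs.items())]
    proteins = aio.read_fasta(outdir / "refA_proteins.fasta")
    cds = aio.read_fasta(outdir / "refA_cds.fasta")
    transcripts = aio.read_fasta(outdir / "refB_transcripts.fasta")
    assignments = run_assignment(contigs, proteins, cds, transcripts,
                                 config.assign)
    frame = assignments_to_frame(assignments)
    frame.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    groups = group_gene_models(assignments)
    rows = [{"genome": genome, "gene_model_id": gid,
             "contigs": ";".join(sorted(a.contig_id for a in assigns))}
            for genome in ("A", "B")
            for gid, assigns in sorted(groups[genome].items())]
    pd.DataFrame(rows).to_csv(outdir / "gene_model_groups.tsv",
                              sep="\t", index=False)
    ref_lengths = {k: len(v) for k, v in {**cds, **transcripts}.items()}
    cov, hist = coverage_report(groups, ref_lengths)
    cov.to_csv(outdir / "gene_model_coverage.tsv", sep="\t", index=False)
    hist.to_csv(outdir / "coverage_histogram.tsv", sep="\t", index=False)
    counts = frame["verdict"].value_counts().to_dict()
    return {"n_contigs": len(contigs),
            "verdicts": {k: int(counts.get(k, 0)) for k in
                         ("A", "B", "B_specific", "ambiguous", "removed")},
            "n_gene_models_A": len(groups["A"]),
            "n_gene_models_B": len(groups["B"])}


def _representatives(group_frame: pd.DataFrame, contig_seqs: dict,
                     depths: dict) -> dict:
    """Per gene model and accession: the longest assigned contig."""
    reps = {}
    for row in group_frame.itertuples():
        for cid in row.contigs.split(";"):
            acc = cid.split("|", 1)[0]
            key = (row.genome, row.gene_model_id, acc)
            if key not in reps or len(contig_seqs[cid]) > len(contig_seqs[reps[key]]):
                reps[key] = cid
    return reps


def stage_snps(config: PipelineConfig, outdir: Path) -> dict:
    groups = pd.read_csv(outdir / "gene_model_groups.tsv", sep="\t")
    contig_seqs = aio.read_fasta(outdir / "contigs.fasta")
    depths = aio.read_depth_tsv(outdir / "contig_depth.tsv")
    cds = aio.read_fasta(outdir / "refA_cds.fasta")
    transcripts = aio.read_fasta(outdir / "refB_transcripts.fasta")
    refs = {**cds, **transcripts}
    meta = pd.read_csv(outdir / "reference_genes.tsv", sep="\t").set_index("gene_id")
    exons = aio.read_exons_gff3(outdir / "refA_exons.gff3")
    assignments = pd.read_csv(outdir / "assignments.tsv", sep="\t")
    ref_start = {r.contig_id: int(r.ref_start)
                 for r in assignments.itertuples()
                 if r.verdict in ("A", "B") and str(r.ref_start) not in ("", "nan")}

    accessions = sorted({cid.split("|", 1)[0] for cid in contig_seqs})
    if len(accessions) < 2:
        raise RuntimeError("need contigs from two accessions to call SNPs")
    acc1, acc2 = accessions[:2]
    reps = _representatives(groups, contig_seqs, depths)

    fam_members = meta.groupby(["family_id", "genome"]).groups
    copy_counts = {fam: {"A": 0, "B": 0} for fam, _ in fam_members}
    members = {}
    for (fam, genome), idx in fam_members.items():
        copy_counts[fam][genome] = len(idx)
        members[(fam, genome)] = list(idx)
    cls_of = meta["subgenome_class"].to_dict()

    models_with_overlap = {"A": 0, "B": 0}
    models_with_snps = {"A": 0, "B": 0}
    variant_rows, marker_rows = [], []
    registry = set()
    n_pass = 0
    marker_no = 0
    for row in groups.itertuples():
        genome, gid = row.genome, row.gene_model_id
        r1 = reps.get((genome, gid, acc1))
        r2 = reps.get((genome, gid, acc2))
        if not r1 or not r2:
            continue
        seq1, seq2 = contig_seqs[r1], contig_seqs[r2]
        aln = align_alleles(seq1, seq2, gene_model_id=gid,
                            accessions=(acc1, acc2),
                            depths=(depths.get(r1, 0.0), depths.get(r2, 0.0)),
                            window_len=config.filter.window_len)
        if not aln:
            continue
        models_with_overlap[genome] += 1
        variants = call_snps(aln)
        if not variants:
            continue
        models_with_snps[genome] += 1

        info = meta.loc[gid]
        fam = info["family_id"]
        k = copy_counts.get(fam, {"A": 0, "B": 0})
        category = classify_copy_category(k["A"], k["B"]) \
            if (k["A"] or k["B"]) else "A_only"

        # homoeologue / paralogue reference sequences for classification
        other = "B" if genome == "A" else "A"
        homoeo_ids = [g for g in members.get((fam, other), [])
                      if cls_of[g] == info["subgenome_class"]]
        para_ids = [g for g in members.get((fam, genome), []) if g != gid]
        homoeo = HomoeologueProjection(seq1, refs[homoeo_ids[0]]) \
            if homoeo_ids else None
        paras = [HomoeologueProjection(seq1, refs[p]) for p in para_ids]

        # HSV/PSV sites within the model for window lower-casing
        variable_sites = {}
        aln_cols = {c.pos1: c for c in aln.columns if c.pos1 > 0}
        projections = ([("HSV", homoeo)] if homoeo else []) + \
            [("PSV", p) for p in paras]
        for _, proj in projections:
            for pos, base_other in proj.map.items():
                col = aln_cols.get(pos)
                if col is None or not col.is_match:
                    continue
                if base_other not in ("-", None) and base_other != col.base1:
                    variable_sites[pos] = (col.base1, base_other)

        offset = ref_start.get(r1, 1) - 1
        # exon structure comes from the A-genome annotation; B gene models
        # borrow their homoeologue's structure (exon boundaries are
        # conserved between the subgenomes), else the screen is unevaluable
        junctions_model = None
        struct_gene = gid if genome == "A" else (homoeo_ids[0] if homoeo_ids else None)
        if struct_gene is not None and struct_gene in exons:
            junc = aio.junctions_from_exon_lengths(exons[struct_gene])
            junctions_model = [j - offset for j in junc]

        gene_has_marker = False
        for v in variants:
            v.genome = genome
            classify_variant(v, homoeo, paralogue_bases=[
                p.base_at(v.position) for p in paras])
            ok, reasons = kaspar_filter(v, aln, junctions_model, config.filter)
            variant_rows.append({
                "gene_model_id": gid, "genome": genome, "family_id": fam,
                "position": v.position, "allele_1": v.allele_1,
                "allele_2": v.allele_2, "depth_1": v.depth_1,
                "depth_2": v.depth_2, "var_class": v.var_class,
                "category": category, "filter_pass": ok,
                "filter_reasons": ";".join(reasons),
                "ref_position": v.position + offset})
            if ok and v.var_class == "allelic_SNP" and not gene_has_marker \
                    and category in ("i_B_unique", "ii_single_copy_both",
                                     "iii_multi_copy"):
                n_pass += 1
                marker_no += 1
                rec = design_marker_sequence(
                    v, seq1, variable_sites,
                    marker_id=f"{MARKER_PREFIX}{marker_no:04d}",
                    category=category, registry=registry,
                    flank_len=config.filter.flank_len,
                    gene_A=gid if genome == "A" else "",
                    gene_B=gid if genome == "B" else "",
                    at_ortholog=info["at_id"], block_id=info["block_id"])
                marker_rows.append({
                    "marker_id": rec.marker_id, "at_ortholog": rec.at_ortholog,
                    "block_id": rec.block_id,
                    "subgenome_class": info["subgenome_class"],
                    "gene_model_id": gid, "family_id": fam, "genome": genome,
                    "category": category, "position": v.position,
                    "marker_sequence": rec.marker_sequence})
                gene_has_marker = True

    pd.DataFrame(variant_rows).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(marker_rows).to_csv(outdir / "markers.tsv", sep="\t", index=False)
    vdf = pd.DataFrame(variant_rows)
    n_allelic = int((vdf["var_class"] == "allelic_SNP").sum()) if len(vdf) else 0
    by_genome = vdf[vdf["var_class"] == "allelic_SNP"].groupby("genome").size() \
        if len(vdf) else pd.Series(dtype=int)
    return {"models_with_overlap": models_with_overlap,
            "models_with_snps": models_with_snps,
            "n_variants": len(variant_rows),
            "n_allelic_snps": n_allelic,
            "allelic_snps_by_genome": {g: int(by_genome.get(g, 0))
                                       for g in ("A", "B")},
            "n_markers": len(marker_rows)}


def stage_map(config: PipelineConfig, outdir: Path) -> dict:
    markers = pd.read_csv(outdir / "markers.tsv", sep="\t")
    if markers.empty:
        raise RuntimeError("no markers available; run the snps stage first")
    genotypes = aio.read_genotypes_tsv(outdir / "genotypes.tsv")
    loci = [g for g in markers["gene_model_id"] if g in genotypes.index]
    matrix = genotypes.loc[sorted(set(loci))]
    result = build_map(matrix, lod_threshold=config.lod_threshold,
                       alpha=config.alpha)
    frame = map_to_frame(result["maps"])
    frame = frame.rename(columns={"marker_id": "gene_model_id"})
    by_gene = markers.drop_duplicates("gene_model_id").set_index("gene_model_id")
    frame["marker_id"] = [by_gene.loc[g, "marker_id"] for g in frame["gene_model_id"]]
    frame["genome"] = [by_gene.loc[g, "genome"] for g in frame["gene_model_id"]]
    frame["at_id"] = [by_gene.loc[g, "at_ortholog"] for g in frame["gene_model_id"]]
    frame["subgenome_class"] = [by_gene.loc[g, "subgenome_class"]
                                for g in frame["gene_model_id"]]
    frame.to_csv(outdir / "linkage_map.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(result["excluded"].items()),
                 columns=["marker", "reason"]).to_csv(
        outdir / "map_excluded.tsv", sep="\t", index=False)
    return {"n_markers_genotyped": len(matrix),
            "n_excluded": len(result["excluded"]),
            "n_markers_mapped": int(len(frame)),
            "n_linkage_groups": len(result["maps"]),
            "map_length_cM": round(sum(m.length_cm for m in result["maps"]), 1)}


def stage_blocks(config: PipelineConfig, outdir: Path) -> dict:
    lmap = pd.read_csv(outdir / "linkage_map.tsv", sep="\t")
    markers = pd.read_csv(outdir / "markers.tsv", sep="\t")
    table = aio.read_block_table(outdir / "block_table.tsv")
    definitions = block_table_to_definitions(table)

    lg_genome = lmap.groupby("lg_id")["genome"].agg(
        lambda s: s.value_counts().idxmax())
    calls = {"A": [], "B": []}
    painted = lmap.rename(columns={"position_cM": "position_cM"})
    for genome in ("A", "B"):
        lgs = [lg for lg, g in lg_genome.items() if g == genome]
        sub = painted[painted["lg_id"].isin(lgs)]
        calls[genome] = call_blocks(sub, genome, definitions,
                                    min_markers=config.min_markers)

    fams = markers.drop_duplicates("marker_id").set_index("marker_id")
    marker_families = dict(zip(lmap["marker_id"],
                               [fams.loc[m, "family_id"] for m in lmap["marker_id"]]))
    cat_ii = {fams.loc[m, "family_id"] for m in lmap["marker_id"]
              if fams.loc[m, "category"] == "ii_single_copy_both"}
    links = infer_homoeology(calls["A"], calls["B"], marker_families, cat_ii,
                             min_shared=config.min_shared)

    keys = sorted({c.key for c in calls["A"]} | {c.key for c in calls["B"]})
    frags = [fragmentation_compare(b, cls, calls["A"], calls["B"])
             for b, cls in keys]
    motifs = association_motifs(calls["A"], calls["B"])

    def call_rows(cs):
        return [{"lg_id": c.lg_id, "genome": c.genome, "block_id": c.block_id,
                 "subgenome_class": c.subgenome_class,
                 "n_markers": len(c.supporting_markers),
                 "markers": ";".join(c.supporting_markers),
                 "cm_start": c.cm_start, "cm_end": c.cm_end,
                 "at_start": str(c.at_span[0]), "at_end": str(c.at_span[1]),
                 "orientation": c.orientation}
                for c in cs]
    pd.DataFrame(call_rows(calls["A"]) + call_rows(calls["B"])).to_csv(
        outdir / "block_calls.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "block_id": l.block_call_A.block_id,
        "subgenome_class": l.block_call_A.subgenome_class,
        "lg_A": l.block_call_A.lg_id, "lg_B": l.block_call_B.lg_id,
        "shared_markers": ";".join(l.shared_single_copy_markers)}
        for l in links]).to_csv(outdir / "homoeology_links.tsv",
                                sep="\t", index=False)
    pd.DataFrame([{
        "block_id": f.block_id, "subgenome_class": f.subgenome_class,
        "n_segments_A": len(f.segments_A), "n_segments_B": len(f.segments_B),
        "segments_A": ";".join(f"{lg}:{s[0]}-{s[1]}" for lg, s in f.segments_A),
        "segments_B": ";".join(f"{lg}:{s[0]}-{s[1]}" for lg, s in f.segments_B),
        "classification": f.classification}
        for f in frags]).to_csv(outdir / "fragmentation.tsv",
                                sep="\t", index=False)
    pd.DataFrame([{"motif": "-".join(m), "lg_pairs": ";".join(
        f"{a}/{b}" for a, b in pairs)}
        for m, pairs in sorted(motifs["shared"].items())]).to_csv(
        outdir / "shared_motifs.tsv", sep="\t", index=False)
    frag_counts = pd.Series([f.classification for f in frags]).value_counts()
    return {"n_block_calls_A": len(calls["A"]),
            "n_block_calls_B": len(calls["B"]),
            "n_homoeology_links": len(links),
            "fragmentation": {k: int(v) for k, v in frag_counts.items()},
            "n_shared_motifs": len(motifs["shared"])}


# ---------------------------------------------------------------------------
# report


REPORT_SCHEMA = {
    "required": ["seed", "stages", "counts", "funnel"],
    "counts_required": [],
}


def validate_report(report: dict) -> None:
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key: {key}")
    funnel = report["funnel"]
    counts = [row["count"] for row in funnel]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("funnel counts must be non-increasing")


def build_funnel(counts: dict) -> list:
    """Fig-2-style funnel over the pipeline's own stage counts."""
    stages = []
    if "assign" in counts:
        v = counts["assign"]["verdicts"]
        stages.append(("contigs_in", counts["assign"]["n_contigs"]))
        stages.append(("contigs_assigned_A_or_B", v["A"] + v["B"]))
    if "snps" in counts:
        s = counts["snps"]
        stages.append(("gene_models_with_allelic_overlap",
                       s["models_with_overlap"]["A"] + s["models_with_overlap"]["B"]))
        stages.append(("gene_models_with_snps",
                       s["models_with_snps"]["A"] + s["models_with_snps"]["B"]))
        stages.append(("gene_models_with_markers", s["n_markers"]))
    if "map" in counts:
        stages.append(("markers_mapped", counts["map"]["n_markers_mapped"]))
    df = funnel_report(stages) if stages else None
    return [] if df is None else df.to_dict("records")


def write_report(counts: dict, outdir: Path, seed: int) -> dict:
    report = {"seed": seed,
              "stages": sorted(counts),
              "counts": counts,
              "funnel": build_funnel(counts)}
    validate_report(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    pd.DataFrame(report["funnel"]).to_csv(outdir / "funnel.tsv",
                                          sep="\t", index=False)
    return report


def recount_from_outputs(outdir: Path) -> dict:
    """Independent recount of headline totals from the written tables."""
    out = {}
    f = outdir / "assignments.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        out["contigs_in"] = len(df)
        out["contigs_assigned_A_or_B"] = int(df["verdict"].isin(["A", "B"]).sum())
    f = outdir / "variants.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        out["n_allelic_snps"] = int((df["var_class"] == "allelic_SNP").sum())
    f = outdir / "markers.tsv"
    if f.exists():
        out["gene_models_with_markers"] = len(pd.read_csv(f, sep="\t"))
    f = outdir / "linkage_map.tsv"
    if f.exists():
        out["markers_mapped"] = len(pd.read_csv(f, sep="\t"))
    return out


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "assign": stage_assign,
    "snps": stage_snps,
    "map": stage_map,
    "blocks": stage_blocks,
}

STAGE_ORDER = ["simulate", "assign", "snps", "map", "blocks", "report"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the report."""
    outdir = Path(config.workdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        if stage == "report":
            report = write_report(counts, outdir, config.seed)
            recount = recount_from_outputs(outdir)
            for row in report["funnel"]:
                name = row["stage"]
                if name in recount and recount[name] != row["count"]:
                    raise RuntimeError(
                        f"funnel/recount mismatch at {name}: "
                        f"{row['count']} vs {recount[name]}")
            continue
        counts[stage] = STAGE_FUNCS[stage](config, outdir)
    if "report" not in config.stages:
        report = {"seed": config.seed, "stages": sorted(counts),
                  "counts": counts, "funnel": build_funnel(counts)}
    return report
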