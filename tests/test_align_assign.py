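"""Contig classification: identity computation, translated search,
verdict rules, orphan screening, gene-model grouping and coverage."""

import numpy as np
import pytest
from Bio.Seq import Seq

from allomap.align import (BlastNucleotideIndex, BlastProteinIndex,
                           IdentityResult, nucleotide_identity,
                           reverse_complement, translated_best_hits)
from allomap.assign import (AssignConfig, Assignment, Contig, assign_contig,
                            classify_orphans, coverage_fraction,
                            coverage_report, group_gene_models)
from allomap.simulate import _rand_cds


def _hit(ref, ident, length):
    return IdentityResult(ref, ident, length, "+", 1, length)


class TestNucleotideIdentity:
    def test_identical_sequences(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        res = nucleotide_identity(seq, seq)
        assert res.identity_pct == 100.0
        assert res.aligned_length == 200

    def test_ten_mismatches_gives_95pct(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        other = list(seq)
        for i in range(0, 100, 10):   # 10 substitutions
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
        res = nucleotide_identity("".join(other), seq)
        assert res.identity_pct == pytest.approx(95.0)
        assert res.aligned_length == 200

    def test_reverse_complement_same_identity_minus_strand(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = nucleotide_identity(seq[50:250], seq)
        rev = nucleotide_identity(reverse_complement(seq[50:250]), seq)
        assert rev.identity_pct == pytest.approx(fwd.identity_pct)
        assert rev.strand == "-"
        assert (rev.ref_start, rev.ref_end) == (fwd.ref_start, fwd.ref_end) == (51, 250)


@pytest.fixture(scope="module")
def protein_db():
    rng = np.random.default_rng(99)
    cds = {f"P{i}": _rand_cds(rng, 360) for i in range(6)}
    proteins = {k: str(Seq(v).translate()).replace("*", "X") for k, v in cds.items()}
    return cds, proteins, BlastProteinIndex(proteins)


class TestTranslatedBestHits:
    def test_exact_fragment_is_top_hit(self, protein_db):
        cds, proteins, index = protein_db
        fragment = cds["P3"][60:300]   # an exact 80-aa coding fragment
        hits = translated_best_hits(fragment, index)
        assert hits and hits[0][0] == "P3"
        assert hits[0][2] < 1e-20

    def test_empty_contig_rejected(self, protein_db):
        with pytest.raises(ValueError):
            translated_best_hits("", protein_db[2])

    def test_dinucleotide_shuffled_contigs_find_no_hits(self, protein_db):
        cds, proteins, index = protein_db
        fragment = cds["P3"][0:240]
        rng = np.random.default_rng(5)
        queries = {}
        for k in range(100):
            pairs = [fragment[i:i + 2] for i in range(0, len(fragment), 2)]
            rng.shuffle(pairs)
            queries[f"shuf{k:03d}"] = "".join(pairs)
        hits = index.search(queries, evalue_max=1e-5)
        n_hit = len(set(hits["qid"]))
        assert n_hit <= 5   # >= 95% of shuffles have no significant hit


class TestAssignContig:
    CONTIG = Contig("c1", "acc", "ACGT" * 50, 10)

    def test_maximum_identity_wins(self):
        res = assign_contig(self.CONTIG, [_hit("gA", 95.0, 300)],
                            [_hit("gB", 88.0, 300)])
        assert res.verdict == "A" and res.gene_model_id == "gA"

    def test_below_keep_rule_removed(self):
        res = assign_contig(self.CONTIG, [_hit("gA", 78.0, 250)], [])
        assert res.verdict == "removed"
        assert res.reason == "below_identity_threshold"

    def test_boundary_values_are_exclusive(self):
        # exactly 80% or exactly 100 bp does NOT satisfy the keep rule
        assert assign_contig(self.CONTIG, [_hit("gA", 80.0, 300)], []).verdict == "removed"
        assert assign_contig(self.CONTIG, [_hit("gA", 95.0, 100)], []).verdict == "removed"
        assert assign_contig(self.CONTIG, [_hit("gA", 80.1, 101)], []).verdict == "A"

    def test_tie_is_ambiguous(self):
        res = assign_contig(self.CONTIG, [_hit("gA", 92.0, 300)],
                            [_hit("gB", 92.0, 280)])
        assert res.verdict == "ambiguous"

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_exhaustive_rescan(self, seed):
        """Oracle: brute-force re-scan over all hit pairs (<=10 hits)."""
        rng = np.random.default_rng(seed)
        config = AssignConfig()
        hits_A = [_hit(f"a{i}", float(rng.uniform(60, 100)), int(rng.integers(50, 400)))
                  for i in range(rng.integers(0, 6))]
        hits_B = [_hit(f"b{i}", float(rng.uniform(60, 100)), int(rng.integers(50, 400)))
                  for i in range(rng.integers(0, 6))]
        res = assign_contig(self.CONTIG, hits_A, hits_B, config)

        passing = [(h, g) for g, hs in (("A", hits_A), ("B", hits_B))
                   for h in hs if h.identity_pct > 80 and h.aligned_length > 100]
        if not passing:
            assert res.verdict == "removed"
            return
        best = max(h.identity_pct for h, _ in passing)
        genomes = {g for h, g in passing if h.identity_pct == best}
        assert res.verdict == ("ambiguous" if len(genomes) > 1 else genomes.pop())

    def test_monotonicity_of_removal_in_identity_threshold(self):
        rng = np.random.default_rng(11)
        cases = []
        for _ in range(200):
            cases.append(([_hit("a", float(rng.uniform(60, 100)),
                                int(rng.integers(50, 400)))],
                          [_hit("b", float(rng.uniform(60, 100)),
                                int(rng.integers(50, 400)))]))
        removed = []
        for thr in (70.0, 80.0, 90.0, 95.0):
            cfg = AssignConfig(min_identity_pct=thr)
            removed.append(sum(
                assign_contig(self.CONTIG, ha, hb, cfg).verdict == "removed"
                for ha, hb in cases))
        assert removed == sorted(removed)


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(42)
    cds_A = {f"gA{i}": _rand_cds(rng, 600) for i in range(4)}
    tx_B = {f"gB{i}": _rand_cds(rng, 600) for i in range(4)}
    return cds_A, tx_B


class TestClassifyOrphans:
    def test_three_orphan_fates(self, refs):
        cds_A, tx_B = refs
        rng = np.random.default_rng(1)
        orphans = [
            Contig("o_genome", "acc", cds_A["gA0"][50:400], 5),
            Contig("o_bspec", "acc", tx_B["gB1"][100:500], 5),
            Contig("o_random", "acc", "".join(rng.choice(list("ACGT"), 300)), 5),
        ]
        out = {a.contig_id: a for a in classify_orphans(orphans, cds_A, tx_B)}
        assert out["o_genome"].verdict == "removed"
        assert out["o_genome"].reason == "matches_genome_reference"
        assert out["o_bspec"].verdict == "B_specific"
        assert out["o_bspec"].gene_model_id == "gB1"
        assert out["o_random"].verdict == "removed"
        assert out["o_random"].reason == "unclassified"


class TestGroupingAndCoverage:
    def _assign(self, cid, verdict, gene, start=1, end=200):
        return Assignment(cid, verdict, gene_model_id=gene,
                          best_identity=IdentityResult(gene, 95.0, end - start + 1,
                                                       "+", start, end))

    def test_three_contigs_one_group(self):
        assigns = [self._assign(f"c{i}", "A", "G") for i in range(3)]
        groups = group_gene_models(assigns)
        assert len(groups["A"]["G"]) == 3 and not groups["B"]

    def test_group_count_equals_distinct_gene_models(self):
        assigns = [self._assign(f"c{i}", "A", f"G{i % 4}") for i in range(10)]
        groups = group_gene_models(assigns)
        assert len(groups["A"]) == 4

    def test_coverage_union_semantics(self):
        a1 = self._assign("c1", "A", "G", 1, 300)
        a2 = self._assign("c2", "A", "G", 200, 500)
        assert coverage_fraction([a1, a2], 500) == pytest.approx(1.0)
        assert coverage_fraction([self._assign("c", "A", "G", 1, 450)], 500) \
            == pytest.approx(0.90)

    def test_histogram_sums_to_model_count(self):
        groups = {"A": {"G1": [self._assign("c1", "A", "G1", 1, 450)],
                        "G2": [self._assign("c2", "A", "G2", 1, 100)]},
                  "B": {}}
        df, hist = coverage_report(groups, {"G1": 500, "G2": 500})
        assert hist["n_gene_models"].sum() == 2

    def test_zero_length_reference_rejected(self):
        groups = {"A": {"G1": [self._assign("c1", "A", "G1")]}, "B": {}}
        with pytest.raises(ValueError):
            coverage_report(groups, {"G1": 0})


class TestPipelineAssignment:
    def test_every_contig_gets_exactly_one_verdict(self, pipeline_small):
        import pandas as pd
        df = pd.read_csv(pipeline_small["workdir"] / "assignments.tsv", sep="\t")
        n_in = pipeline_small["report"]["counts"]["assign"]["n_contigs"]
        assert len(df) == n_in
        assert df["contig_id"].is_unique
        assert df["verdict"].value_counts().sum() == n_in

    def test_truth_recovery_at_least_95pct(self, pipeline_small):
        import pandas as pd
        wd = pipeline_small["workdir"]
        truth = pd.read_csv(wd / "truth_assignment.tsv", sep="\t") \
            .set_index("contig_id")["genome"]
        df = pd.read_csv(wd / "assignments.tsv", sep="\t")
        kept = df[df["verdict"] != "removed"]
        verdict_genome = kept["verdict"].replace({"B_specific": "B"})
        correct = (verdict_genome.values == truth.loc[kept["contig_id"]].values)
        assert correct.mean() >= 0.95

    def test_majority_of_gene_models_well_covered(self, pipeline_small):
        """At the default simulated coverage, >70% of gene models exceed
        0.6 coverage of their reference."""
        import pandas as pd
        cov = pd.read_csv(pipeline_small["workdir"] / "gene_model_coverage.tsv",
                          sep="\t")
        assert (cov["coverage"] > 0.6).mean() > 0.70
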