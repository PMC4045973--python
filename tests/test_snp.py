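"""Variant calling and marker design: allelic alignment, SNP calls vs a
brute-force haplotype scan, HSV/PSV classification, the co-dominant
assay filters and the marker sequence conventions."""

import numpy as np
import pandas as pd
import pytest

from allomap.snp import (AllelicAlignment, FilterConfig, HomoeologueProjection,
                         Variant, align_alleles, call_snps,
                         classify_copy_category, classify_site,
                         classify_variant, design_marker_sequence,
                         funnel_report, kaspar_filter, validate_marker_record)


def _mutate(seq, pos, base):
    return seq[:pos - 1] + base + seq[pos:]


@pytest.fixture()
def base_seq(rng):
    return "".join(rng.choice(list("ACGT"), 300))


class TestAlignAlleles:
    def test_identical_sequences_no_mismatch(self, base_seq):
        aln = align_alleles(base_seq, base_seq)
        assert aln and all(c.is_match for c in aln.columns)

    def test_single_substitution_at_120(self, base_seq):
        other = _mutate(base_seq, 120, "A" if base_seq[119] != "A" else "C")
        aln = align_alleles(base_seq, other)
        mismatches = [c for c in aln.columns if not c.is_match]
        assert len(mismatches) == 1 and mismatches[0].pos1 == 120

    def test_short_overlap_is_empty(self, base_seq):
        # staggered substrings sharing only 80 bases < the 101-bp window
        s1, s2 = base_seq[0:160], base_seq[80:300]
        aln = align_alleles(s1, s2, window_len=101)
        assert not aln

    def test_staggered_overlap_covers_full_intersection(self, base_seq):
        s1, s2 = base_seq[0:220], base_seq[60:300]
        aln = align_alleles(s1, s2, window_len=101)
        pos1 = [c.pos1 for c in aln.columns]
        assert min(pos1) == 61 and max(pos1) == 220


class TestCallSnps:
    def test_three_substitutions_and_one_gap(self, base_seq):
        other = base_seq
        for p in (50, 120, 200):
            other = _mutate(other, p, {"A": "G", "G": "A", "C": "T", "T": "C"}[other[p - 1]])
        other = other[:259] + other[260:]       # one deletion
        aln = align_alleles(base_seq, other)
        variants = call_snps(aln)
        assert sorted(v.position for v in variants) == [50, 120, 200]

    def test_all_match_gives_no_variants(self, base_seq):
        assert call_snps(align_alleles(base_seq, base_seq)) == []

    def test_matches_bruteforce_haplotype_scan(self, truth_small):
        """Oracle: direct column scan of the true haplotypes over the
        overlap of the two accessions' longest contigs (10 genes)."""
        t = truth_small
        by_gene = {}
        for c in t.contigs:
            by_gene.setdefault((c.true_gene, c.accession), []).append(c)
        genes = [g.id for g in t.reference_A[:10]]
        checked = 0
        for gid in genes:
            reps = {}
            for acc in ("line_1", "line_2"):
                cs = by_gene.get((gid, acc))
                if cs:
                    reps[acc] = max(cs, key=lambda c: len(c.sequence))
            if len(reps) < 2:
                continue
            r1, r2 = reps["line_1"], reps["line_2"]
            aln = align_alleles(r1.sequence, r2.sequence, gene_model_id=gid)
            called = sorted(v.position for v in call_snps(aln))
            h1 = t.haplotypes[("A", gid, "line_1")]
            h2 = t.haplotypes[("A", gid, "line_2")]
            lo = max(r1.true_start, r2.true_start)
            hi = min(r1.true_end, r2.true_end)
            if hi - lo + 1 < 101:
                assert called == []
                continue
            expected = sorted(p - r1.true_start + 1 for p in range(lo, hi + 1)
                              if h1[p - 1] != h2[p - 1])
            assert called == expected
            checked += 1
        assert checked >= 5


class TestClassification:
    def test_allelic_snp_definition(self):
        assert classify_site("G", "A", "A") == "allelic_SNP"

    def test_hsv_definition(self):
        assert classify_site("G", "G", "A") == "HSV"

    def test_psv_definition(self):
        assert classify_site("G", "G", "G", paralogue_bases=["T"]) == "PSV"

    def test_variant_level_with_projection(self, base_seq):
        homoeo_seq = _mutate(base_seq, 150, {"A": "C", "C": "A",
                                             "G": "T", "T": "G"}[base_seq[149]])
        proj = HomoeologueProjection(base_seq, homoeo_seq)
        v_same = Variant("g", 150, base_seq[149], base_seq[149])
        assert classify_variant(v_same, proj) == "HSV"
        v_diff = Variant("g", 150, "A", "G")
        assert classify_variant(v_diff, proj) == "allelic_SNP"

    def test_unprojectable_site_flagged(self, base_seq):
        homoeo_del = base_seq[:149] + base_seq[150:]
        proj = HomoeologueProjection(base_seq, homoeo_del)
        v = Variant("g", 150, base_seq[149], base_seq[149])
        assert classify_variant(v, proj) == "undetermined"


class TestKasparFilter:
    def _setup(self, base_seq, pos=150, depths=(10.0, 10.0)):
        other = _mutate(base_seq, pos, {"A": "G", "G": "A",
                                        "C": "T", "T": "C"}[base_seq[pos - 1]])
        aln = align_alleles(base_seq, other, depths=depths)
        variant = [v for v in call_snps(aln) if v.position == pos][0]
        return variant, aln

    def test_clean_variant_passes(self, base_seq):
        v, aln = self._setup(base_seq)
        ok, reasons = kaspar_filter(v, aln, junctions=[])
        assert ok and reasons == []

    def test_low_depth_fails(self, base_seq):
        v, aln = self._setup(base_seq, depths=(6.0, 10.0))
        ok, reasons = kaspar_filter(v, aln, junctions=[])
        assert not ok and reasons == ["depth"]

    def test_short_left_flank_fails(self, base_seq):
        v, aln = self._setup(base_seq, pos=40)
        ok, reasons = kaspar_filter(v, aln, junctions=[])
        assert not ok and "flank" in reasons

    def test_nearby_snp_breaks_flank_conservation(self, base_seq):
        other = base_seq
        for p in (150, 170):
            other = _mutate(other, p, {"A": "G", "G": "A",
                                       "C": "T", "T": "C"}[other[p - 1]])
        aln = align_alleles(base_seq, other, depths=(10, 10))
        v150 = [v for v in call_snps(aln) if v.position == 150][0]
        ok, reasons = kaspar_filter(v150, aln, junctions=[])
        assert not ok and "flank" in reasons

    def test_junction_in_window_fails(self, base_seq):
        v, aln = self._setup(base_seq)
        ok, reasons = kaspar_filter(v, aln, junctions=[170])
        assert not ok and reasons == ["junction"]

    def test_missing_exon_structure_is_conservative(self, base_seq):
        v, aln = self._setup(base_seq)
        ok, reasons = kaspar_filter(v, aln, junctions=None)
        assert not ok and reasons == ["junction_unevaluable"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_window_rescan(self, seed):
        """Oracle: explicit window scan over raw sequences (200 variants)."""
        rng = np.random.default_rng(seed)
        flank = 50
        n_checked = 0
        for _ in range(200):
            L = int(rng.integers(150, 400))
            seq1 = "".join(rng.choice(list("ACGT"), L))
            pos = int(rng.integers(1, L + 1))
            seq2 = _mutate(seq1, pos, {"A": "G", "G": "A", "C": "T",
                                       "T": "C"}[seq1[pos - 1]])
            # sprinkle extra substitutions
            for _ in range(rng.integers(0, 3)):
                q = int(rng.integers(1, L + 1))
                if q != pos:
                    seq2 = _mutate(seq2, q, {"A": "C", "C": "A", "G": "T",
                                             "T": "G"}[seq2[q - 1]])
            d1, d2 = float(rng.integers(3, 15)), float(rng.integers(3, 15))
            junctions = sorted(rng.choice(np.arange(1, L + 1),
                                          size=rng.integers(0, 3), replace=False))
            aln = align_alleles(seq1, seq2, depths=(d1, d2), window_len=1)
            vs = [v for v in call_snps(aln) if v.position == pos]
            if not vs:
                continue
            got, _ = kaspar_filter(vs[0], aln, junctions=list(junctions))

            # independent re-check on the raw strings
            depth_ok = d1 >= 7 and d2 >= 7
            flank_ok = (pos - flank >= 1 and pos + flank <= L and
                        seq1[pos - flank - 1:pos - 1] == seq2[pos - flank - 1:pos - 1] and
                        seq1[pos:pos + flank] == seq2[pos:pos + flank])
            junction_ok = not any(pos - flank <= j <= pos + flank for j in junctions)
            assert got == (depth_ok and flank_ok and junction_ok)
            n_checked += 1
        assert n_checked >= 150


class TestCopyCategories:
    @pytest.mark.parametrize("ka,kb,expect", [
        (0, 1, "i_B_unique"),
        (0, 2, "i_B_unique"),
        (1, 1, "ii_single_copy_both"),
        (2, 1, "iii_multi_copy"),
        (1, 0, "A_only"),
    ])
    def test_three_way_rule(self, ka, kb, expect):
        assert classify_copy_category(ka, kb) == expect

    def test_absent_everywhere_rejected(self):
        with pytest.raises(ValueError):
            classify_copy_category(0, 0)


class TestMarkerDesign:
    def test_clean_window_layout(self, base_seq):
        v = Variant("g", 150, "A", "G", 10, 10, genome="A")
        rec = design_marker_sequence(v, base_seq, {}, "BJ_VH_0001")
        seq = rec.marker_sequence
        assert seq[50:55] == "[A/G]"
        assert seq[:50] == base_seq[99:149].upper()
        assert seq[55:] == base_seq[150:200].upper()
        validate_marker_record(rec, known_sites=set())

    def test_hsv_lowercase_iupac(self, base_seq):
        # an HSV (t in one genome, c in the other) 10 bases left of the target
        v = Variant("g", 150, "A", "G", 10, 10)
        sites = {140: ("T", "C")}
        rec = design_marker_sequence(v, base_seq, sites, "BJ_VH_0002")
        assert rec.marker_sequence[40] == "y"
        validate_marker_record(rec, known_sites={140})

    def test_duplicate_marker_rejected(self, base_seq):
        v = Variant("g", 150, "A", "G")
        registry = set()
        design_marker_sequence(v, base_seq, {}, "m1", registry=registry)
        with pytest.raises(ValueError):
            design_marker_sequence(v, base_seq, {}, "m2", registry=registry)

    def test_window_past_end_rejected(self, base_seq):
        v = Variant("g", 20, "A", "G")
        with pytest.raises(ValueError):
            design_marker_sequence(v, base_seq, {}, "m1")


class TestFunnel:
    def test_valid_funnel(self):
        df = funnel_report([("in", 100), ("step1", 60), ("step2", 45)])
        assert list(df["removed"]) == [0, 40, 15]

    def test_increasing_counts_rejected(self):
        with pytest.raises(ValueError):
            funnel_report([("in", 100), ("more", 120)])


class TestPipelineVariants:
    def test_a_genome_has_more_allelic_snps(self, pipeline_small):
        counts = pipeline_small["report"]["counts"]["snps"]["allelic_snps_by_genome"]
        assert counts["A"] > counts["B"]

    def test_variant_classes_partition(self, pipeline_small):
        df = pd.read_csv(pipeline_small["workdir"] / "variants.tsv", sep="\t")
        assert set(df["var_class"]) <= {"allelic_SNP", "HSV", "PSV", "undetermined"}
        assert df["var_class"].notna().all()

    def test_allelic_call_precision(self, pipeline_small):
        """Called allelic SNPs coincide with true accession differences
        at reference coordinates (>= 0.95 precision; recall over covered
        regions is asserted exactly in the brute-force oracle test)."""
        wd = pipeline_small["workdir"]
        calls = pd.read_csv(wd / "variants.tsv", sep="\t")
        calls = calls[calls["var_class"] == "allelic_SNP"]
        truth = pd.read_csv(wd / "truth_variants.tsv", sep="\t")
        truth_keys = set(zip(truth["gene_id"], truth["position"]))
        call_keys = set(zip(calls["gene_model_id"], calls["ref_position"]))
        tp = len(call_keys & truth_keys)
        assert len(call_keys) > 50
        assert tp / len(call_keys) >= 0.95
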