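import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capmeth.genome_model import (
    AnnotationError,
    GeneModel,
    GenomicInterval,
    classify_cgi_location,
    classify_promoter_cpg_density,
    compute_cgi_shores,
    derive_gene_regions,
    load_gene_annotation,
    load_refflat,
    select_representative,
    write_refflat,
)


class TestGenomicInterval:
    def test_length(self):
        assert GenomicInterval("chr1", 10, 25).length() == 15

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (8, 2)])
    def test_invalid_coordinates(self, start, end):
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", start, end)


class TestReaders:
    def test_refflat_basic(self, tmp_path):
        path = tmp_path / "a.refFlat"
        path.write_text(
            "G1\tNM_1\tchr1\t+\t1000\t5000\t1200\t4800\t2\t1000,3000,\t2000,5000,\n"
        )
        (gene,) = load_refflat(str(path))
        assert gene.start == 1000 and gene.end == 5000
        assert gene.exons == [(1000, 2000), (3000, 5000)]
        regions = derive_gene_regions(gene)
        assert len(regions.introns) == 1
        assert regions.introns[0].start == 2000 and regions.introns[0].end == 3000

    def test_refflat_malformed_line_names_lineno(self, tmp_path):
        path = tmp_path / "bad.refFlat"
        path.write_text("G1\tNM_1\tchr1\t+\t1000\n")
        with pytest.raises(AnnotationError, match="bad.refFlat:1"):
            load_refflat(str(path))

    def test_refflat_exon_outside_tx(self, tmp_path):
        path = tmp_path / "bad.refFlat"
        path.write_text(
            "G1\tNM_1\tchr1\t+\t1000\t5000\t1000\t5000\t1\t500,\t2000,\n"
        )
        with pytest.raises(AnnotationError, match="exon outside"):
            load_refflat(str(path))

    def test_gtf_coordinate_conversion(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        (gene,) = load_gene_annotation(str(path), "GTF")
        assert gene.exons == [(1000, 1500)]

    def test_toy_annotation_round_trips(self, tmp_path, small_toy):
        path = tmp_path / "roundtrip.refFlat"
        write_refflat(small_toy.genes, str(path))
        back = load_refflat(str(path))
        assert len(back) == len(small_toy.genes)
        for a, b in zip(small_toy.genes, back):
            assert (a.gene_id, a.chrom, a.strand, a.start, a.end,
                    a.cds_start, a.cds_end, a.exons) == (
                b.gene_id, b.chrom, b.strand, b.start, b.end,
                b.cds_start, b.cds_end, b.exons)

    def test_representative_longest_then_smallest_start(self):
        mk = lambda s, e: GeneModel(
            gene_id="G", chrom="chr1", strand="+", start=s, end=e,
            cds_start=s, cds_end=s, exons=[(s, e)],
        )
        assert select_representative([mk(0, 100), mk(10, 200)])[0].start == 10
        assert select_representative([mk(50, 150), mk(0, 100)])[0].start == 0


class TestGeneRegions:
    def test_plus_strand_promoter_and_tts(self, plus_gene):
        r = derive_gene_regions(plus_gene)
        assert (r.promoter.start, r.promoter.end) == (9_000, 11_000)
        assert (r.tts_flank.start, r.tts_flank.end) == (20_000, 21_000)

    def test_minus_strand_mirrored(self, minus_gene):
        r = derive_gene_regions(minus_gene)
        assert (r.promoter.start, r.promoter.end) == (19_000, 21_000)
        assert (r.tts_flank.start, r.tts_flank.end) == (9_000, 10_000)

    def test_single_exon_coding_gene(self):
        g = GeneModel(
            gene_id="g", chrom="chr1", strand="+", start=5_000, end=8_000,
            cds_start=5_500, cds_end=7_500, exons=[(5_000, 8_000)],
        )
        r = derive_gene_regions(g)
        assert r.introns == []
        assert [(u.start, u.end) for u in r.utr5] == [(5_000, 5_500)]
        assert [(u.start, u.end) for u in r.utr3] == [(7_500, 8_000)]

    def test_exon_intron_tile_tx(self, plus_gene):
        r = derive_gene_regions(plus_gene)
        pieces = sorted(
            [(iv.start, iv.end) for iv in r.exons + r.introns]
        )
        assert pieces[0][0] == plus_gene.start
        assert pieces[-1][1] == plus_gene.end
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2  # contiguous, no overlap
        total = sum(e - s for s, e in pieces)
        assert total == plus_gene.end - plus_gene.start

    def test_utr_cds_partition_exons(self, minus_gene):
        r = derive_gene_regions(minus_gene)
        utr_cds = sum(iv.length() for iv in r.utr5 + r.utr3 + r.coding_exons)
        assert utr_cds == sum(iv.length() for iv in r.exons)


class TestShores:
    sizes = {"chr1": 1_000_000}

    def test_isolated_island(self):
        ss = compute_cgi_shores([GenomicInterval("chr1", 10_000, 10_500)],
                                self.sizes)
        coords = sorted((s.interval.start, s.interval.end) for s in ss.shores)
        assert coords == [(8_000, 10_000), (10_500, 12_500)]

    def test_truncated_at_neighbor(self):
        ss = compute_cgi_shores(
            [GenomicInterval("chr1", 10_000, 10_500),
             GenomicInterval("chr1", 11_000, 11_400)],
            self.sizes,
        )
        down = [s for s in ss.shores if s.island_index == 0
                and s.side == "downstream"][0]
        assert (down.interval.start, down.interval.end) == (10_500, 11_000)

    def test_chromosome_edge_clip(self):
        ss = compute_cgi_shores([GenomicInterval("chr1", 500, 900)], self.sizes)
        up = [s for s in ss.shores if s.side == "upstream"][0]
        assert (up.interval.start, up.interval.end) == (0, 500)

    def test_overlapping_islands_rejected(self):
        with pytest.raises(AnnotationError, match="overlap"):
            compute_cgi_shores(
                [GenomicInterval("chr1", 100, 500),
                 GenomicInterval("chr1", 400, 800)],
                self.sizes,
            )

    def test_shores_disjoint_from_islands_and_bounded(self, small_toy,
                                                      small_config):
        ss = compute_cgi_shores(small_toy.cgis, small_config.chrom_sizes)
        assert len(ss.shores) <= 2 * len(ss.islands)
        assert sum(s.interval.length() for s in ss.shores) <= 4000 * len(ss.islands)
        for sh in ss.shores:
            assert sh.interval.length() <= 2000
            for isl in ss.islands:
                assert not sh.interval.overlaps(isl)


class TestCgiLocation:
    def test_location_classes(self, plus_gene):
        genes = [plus_gene]
        assert classify_cgi_location(
            GenomicInterval("chr1", 9_500, 10_200), genes) == "promoter"
        assert classify_cgi_location(
            GenomicInterval("chr1", 14_000, 14_500), genes) == "gene_body"
        assert classify_cgi_location(
            GenomicInterval("chr1", 70_000, 71_000), genes) == "intergenic"

    def test_partition(self, small_toy):
        classes = [classify_cgi_location(c, small_toy.genes)
                   for c in small_toy.cgis]
        assert set(classes) <= {"promoter", "gene_body", "intergenic"}
        assert len(classes) == len(small_toy.cgis)


def brute_force_cpg_class(seq, window=500, step=5):
    """Independent oracle: enumerate windows with plain Python."""
    seq = seq.upper()
    if len(seq) < window:
        starts, window = [0], len(seq)
    else:
        starts = range(0, len(seq) - window + 1, step)
    any_hcp, any_icp = False, False
    for s in starts:
        w = seq[s:s + window]
        eff = sum(1 for b in w if b in "ACGT")
        nc, ng = w.count("C"), w.count("G")
        ncg = sum(1 for i in range(len(w) - 1) if w[i:i + 2] == "CG")
        gc = (nc + ng) / eff if eff else 0.0
        oe = ncg * eff / (nc * ng) if nc and ng else 0.0
        if gc >= 0.55 and oe >= 0.75:
            any_hcp = True
        if oe >= 0.48:
            any_icp = True
    return "HCP" if any_hcp else ("ICP" if any_icp else "LCP")


class TestPromoterCpGClass:
    def test_cg_repeat_is_hcp(self):
        seq = "CG" * 250  # GC=1.0, O/E = (250*500)/(250*250) = 2.0
        res = classify_promoter_cpg_density(seq)
        assert res.cpg_class == "HCP"
        assert math.isclose(res.best_window_oe, 2.0)
        assert math.isclose(res.best_window_gc, 1.0)

    def test_poly_a_is_lcp(self):
        assert classify_promoter_cpg_density("A" * 900).cpg_class == "LCP"

    def test_constructed_icp_matches_bruteforce(self):
        from capmeth.synthetic_data import ICP_UNIT

        seq = (ICP_UNIT * 9)[:900]
        res = classify_promoter_cpg_density(seq)
        assert res.cpg_class == "ICP"
        assert brute_force_cpg_class(seq) == "ICP"
        assert 0.48 <= res.best_window_oe < 0.75
        assert res.best_window_gc < 0.55

    def test_short_sequence_single_window_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            res = classify_promoter_cpg_density("CG" * 100)
        assert res.cpg_class == "HCP"

    def test_ambiguous_bases_excluded(self):
        # Ns excluded from counts and window length
        seq = ("CG" * 200 + "N" * 100)
        res = classify_promoter_cpg_density(seq)
        assert res.cpg_class == "HCP"

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=500, max_size=700))
    def test_matches_bruteforce_oracle(self, seq):
        assert classify_promoter_cpg_density(seq).cpg_class == \
            brute_force_cpg_class(seq)

    @settings(max_examples=20, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=500, max_size=600))
    def test_reverse_complement_invariant(self, seq):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        assert classify_promoter_cpg_density(seq).cpg_class == \
            classify_promoter_cpg_density(rc).cpg_class
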