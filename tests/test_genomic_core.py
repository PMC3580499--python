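"""Coordinate conventions, interval algebra, and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telinc import genomic_core as gc
from .conftest import bitmask_merge, bitmask_overlap, random_pairs

GTF_FIXTURE = "\n".join([
    'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
    'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
    'chr1\tsrc\texon\t501\t700\t.\t-\t.\tgene_id "g2"; transcript_id "t2";',
    'chr2\tsrc\texon\t11\t50\t.\t+\t.\tgene_id "g3"; transcript_id "t3";',
    'chr2\tsrc\texon\t81\t130\t.\t+\t.\tgene_id "g3"; transcript_id "t3";',
]) + "\n"

RM_OUT = """\
   SW   perc perc perc  query    position in query    matching repeat
score   div. del. ins.  sequence begin end (left)     repeat class/family begin end (left) ID

 1306   14.2  0.3  0.0  chr1     1001  1500 (8500) C  L1PA7    LINE/L1     (100) 5500 5000   1
  500    5.0  0.0  0.0  chr1     2001  2100 (7900) +  AluY     SINE/Alu       1   100  (200) 2
  200   10.0  0.0  0.0  chr1     3001  3050 (6950) +  (TA)n    Simple_repeat  1    50    (0) 3
  300    8.0  0.0  0.0  chr2      501   950 (9050) +  LTR7     LTR/ERV1       1   450    (0) 4
"""


class TestGTF:
    def test_coordinates_converted_to_half_open(self):
        cat = gc.parse_gtf(GTF_FIXTURE)
        t1 = cat["t1"]
        assert (t1.exons[0].start, t1.exons[0].end) == (100, 200)

    def test_exons_grouped_and_mature_length(self):
        cat = gc.parse_gtf(GTF_FIXTURE)
        t1 = cat["t1"]
        assert t1.n_exons == 2
        assert t1.mature_length == 200
        assert t1.gene_id == "g1"

    def test_minus_strand_tss_is_max_coordinate(self):
        t2 = gc.parse_gtf(GTF_FIXTURE)["t2"]
        assert t2.tss == 700
        assert t2.tss_base == 699

    def test_round_trip_is_canonical_identity(self):
        canon = gc.write_gtf(gc.parse_gtf(GTF_FIXTURE))
        assert gc.write_gtf(gc.parse_gtf(canon)) == canon
        cat = gc.parse_gtf(canon)
        assert sorted(t.transcript_id for t in cat) == ["t1", "t2", "t3"]

    def test_malformed_attributes_name_the_line(self):
        bad = GTF_FIXTURE + "chr1\tsrc\texon\t1\t50\t.\t+\t.\tno_attrs_here\n"
        with pytest.raises(ValueError, match="line 6"):
            gc.parse_gtf(bad)

    def test_mixed_strand_transcript_rejected(self):
        bad = "\n".join([
            'chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";',
            'chr1\tsrc\texon\t61\t90\t.\t-\t.\tgene_id "g"; transcript_id "t";',
        ])
        with pytest.raises(ValueError, match="mixed"):
            gc.parse_gtf(bad)


class TestRepeatMasker:
    def test_out_field_mapping(self):
        tes = gc.parse_repeatmasker(RM_OUT, mode="out")
        l1 = next(t for t in tes if t.family == "L1")
        assert l1.interval.strand == "-"          # 'C' column
        assert l1.interval.start == 1000          # 1-based converted
        assert l1.perc_div == 14.2
        assert l1.te_class == "LINE"
        assert l1.element_name == "L1PA7"

    def test_simple_repeat_dropped_and_counted(self):
        tes, dropped = gc.parse_repeatmasker_with_report(RM_OUT, mode="out")
        assert all(t.element_name != "(TA)n" for t in tes)
        assert sum(dropped.values()) == 1

    def test_bed_mode_family_element_split(self):
        tes = gc.parse_repeatmasker("chr1\t0\t300\tERV1/LTR7\t0\t+\n",
                                    mode="bed")
        assert tes[0].family == "ERV1"
        assert tes[0].element_name == "LTR7"
        assert tes[0].te_class == "LTR"

    def test_te_bed_round_trip(self):
        tes = gc.parse_repeatmasker(RM_OUT, mode="out")
        text = gc.write_te_bed(tes)
        back = gc.parse_repeatmasker(text, mode="bed")
        assert len(back) == len(tes)
        assert {t.element_name for t in back} == {t.element_name for t in tes}
        assert {(t.interval.chrom, t.interval.start, t.interval.end)
                for t in back} == {(t.interval.chrom, t.interval.start,
                                    t.interval.end) for t in tes}


class TestIntervalAlgebra:
    def test_merge_overlapping_and_abutting(self):
        ivs = [gc.Interval("c", 0, 10), gc.Interval("c", 5, 15)]
        assert [(i.start, i.end) for i in gc.merge_intervals(ivs)] == [(0, 15)]
        ivs = [gc.Interval("c", 0, 5), gc.Interval("c", 5, 10)]
        assert [(i.start, i.end) for i in gc.merge_intervals(ivs)] == [(0, 10)]

    def test_merge_rejects_mixed_chromosomes(self):
        with pytest.raises(ValueError, match="mixed"):
            gc.merge_intervals([gc.Interval("a", 0, 1), gc.Interval("b", 0, 1)])

    def test_overlap_examples(self):
        a = [gc.Interval("c", 0, 10)]
        assert gc.overlap_bp(a, [gc.Interval("c", 5, 15)]) == 5
        assert gc.overlap_bp(a, [gc.Interval("c", 20, 30)]) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_merge_and_overlap_match_bitmask_oracle(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(50, 10_000))
        a = random_pairs(rng, size, int(rng.integers(1, 60)))
        b = random_pairs(rng, size, int(rng.integers(1, 60)))
        merged = gc.merge_pairs(a)
        assert merged == bitmask_merge(a, size)
        assert gc.overlap_bp_pairs(gc.merge_pairs(a), gc.merge_pairs(b)) == \
            bitmask_overlap(a, b, size)
        # symmetry and the upper bound
        ov = gc.overlap_bp_pairs(gc.merge_pairs(b), gc.merge_pairs(a))
        assert ov == bitmask_overlap(a, b, size)
        assert ov <= min(sum(e - s for s, e in merged),
                         sum(e - s for s, e in gc.merge_pairs(b)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_intervalset_queries_match_bitmask(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(50, 5_000))
        pairs = random_pairs(rng, size, int(rng.integers(1, 40)))
        idx = gc.IntervalSet(pairs)
        mask = np.zeros(size, dtype=bool)
        for s, e in pairs:
            mask[s:e] = True
        pos = rng.integers(0, size, 50)
        assert (idx.covers(pos) == mask[pos]).all()
        s, e = sorted(rng.integers(0, size, 2))
        assert idx.overlap_bp(s, e) == mask[s:e].sum()


class TestGenomeLayout:
    def test_alignable_size_identity(self):
        g = gc.GenomeLayout(["c1", "c2"], {"c1": 100, "c2": 200},
                            {"c1": [(10, 20), (15, 30)]})
        assert g.alignable_size + g.excluded_bp == g.total_size
        assert g.excluded_bp == 20  # merged, not 25

    def test_excluded_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            gc.GenomeLayout(["c1"], {"c1": 100}, {"c1": [(90, 120)]})

    def test_from_files(self):
        g = gc.genome_from_files("c1\t100\nc2\t50\n", "c1\t0\t10\n")
        assert g.alignable_size == 140


class TestTables:
    def test_expression_round_trip(self):
        text = "gene_id\ts1\ts2\ng1\t1.5\t0\ng2\t3\t4\n"
        m = gc.read_expression_table(text)
        assert m.fpkm.loc["g1", "s1"] == 1.5
        again = gc.read_expression_table(m.to_tsv())
        assert again.fpkm.equals(m.fpkm)

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gc.read_expression_table("gene_id\ts1\ng1\t1\ng1\t2\n")

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gc.read_expression_table("gene_id\ts1\ng1\t-1\n")

    def test_bedgraph_round_trip(self):
        track = {"chr1": (np.array([5, 6, 7, 20]),
                          np.array([0.5, 0.5, 0.25, 1.0]))}
        text = gc.write_bedgraph(track)
        back = gc.read_bedgraph(text)
        assert (back["chr1"][0] == track["chr1"][0]).all()
        assert np.allclose(back["chr1"][1], track["chr1"][1])
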