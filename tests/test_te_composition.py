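"""Coverage fractions, junction overlap, conservation partition, identity."""

import itertools

import numpy as np
import pytest

from telinc import te_composition as tc
from telinc.genomic_core import Catalog, GenomeLayout, Interval
from .conftest import bitmask_overlap, make_te, make_transcript


class TestCompositionSummary:
    def test_te_fraction_of_single_exon(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 100)])])
        tes = [make_te("chr1", 0, 42)]
        s = tc.composition_summary(cat, tes)
        assert s.per_transcript.loc["t", "te_fraction"] == pytest.approx(0.42)
        assert s.fraction_sequence_te == pytest.approx(0.42)

    def test_intronic_te_counts_only_in_locus_space(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 100), (200, 300)])])
        tes = [make_te("chr1", 120, 180)]
        exonic = tc.composition_summary(cat, tes, space="exonic")
        locus = tc.composition_summary(cat, tes, space="locus")
        assert exonic.per_transcript.loc["t", "te_fraction"] == 0.0
        assert locus.per_transcript.loc["t", "te_fraction"] > 0.0

    def test_same_family_overlap_not_double_counted(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 100)])])
        tes = [make_te("chr1", 0, 10), make_te("chr1", 5, 15)]
        s = tc.composition_summary(cat, tes)
        assert s.per_transcript.loc["t", "te_bp"] == 15

    def test_splitting_a_te_leaves_fractions_unchanged(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 500)])])
        whole = [make_te("chr1", 100, 300)]
        split = [make_te("chr1", 100, 170), make_te("chr1", 170, 300)]
        assert tc.composition_summary(cat, whole).fraction_sequence_te == \
            tc.composition_summary(cat, split).fraction_sequence_te

    def test_te_dte_partition_covers_catalog(self, sim):
        s = tc.composition_summary(sim.catalog, sim.tes)
        te, dte = set(s.te_transcripts), set(s.dte_transcripts)
        assert not te & dte
        assert te | dte == {t.transcript_id for t in sim.catalog}

    def test_locus_space_dominates_exonic(self, sim):
        ex = tc.composition_summary(sim.catalog, sim.tes, "exonic")
        lo = tc.composition_summary(sim.catalog, sim.tes, "locus")
        assert (lo.per_transcript.te_bp >= ex.per_transcript.te_bp - 1e-9).all()

    def test_random_fixture_matches_bitmask_oracle(self):
        rng = np.random.default_rng(12)
        size = 2000
        for _ in range(10):
            exon_pairs = sorted(
                {tuple(sorted(rng.integers(0, size, 2))) for _ in range(4)})
            exon_pairs = [(s, e) for s, e in exon_pairs if e > s]
            merged = []
            pos = 0
            for s, e in exon_pairs:  # make them disjoint by shifting
                s, e = max(s, pos + 1), max(e, max(s, pos + 1) + 1)
                if e <= size:
                    merged.append((s, e))
                    pos = e
            if not merged:
                continue
            cat = Catalog([make_transcript("t", "chr1", merged)])
            te_pairs = [tuple(sorted(rng.integers(0, size, 2)))
                        for _ in range(6)]
            te_pairs = [(s, e) for s, e in te_pairs if e > s]
            tes = [make_te("chr1", s, e) for s, e in te_pairs]
            if not tes:
                continue
            s = tc.composition_summary(cat, tes)
            assert s.per_transcript.loc["t", "te_bp"] == \
                bitmask_overlap(merged, te_pairs, size)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            tc.composition_summary(Catalog([]), [])


class TestGenomeFraction:
    def test_merged_bp_over_genome(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        tes = [make_te("c", 0, 300), make_te("c", 200, 499)]
        assert tc.genome_te_fraction(tes, genome) == pytest.approx(0.499)
        assert tc.genome_te_fraction([], genome) == 0.0


class TestJunctions:
    def test_donor_site_is_first_intronic_base(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 10), (20, 30)], "+")])
        donor, acceptor = tc.junction_te_overlap(cat, [make_te("chr1", 10, 12)])
        assert (donor, acceptor) == (1.0, 0.0)

    def test_minus_strand_swaps_roles(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 10), (20, 30)], "-")])
        donor, acceptor = tc.junction_te_overlap(cat, [make_te("chr1", 10, 12)])
        assert (donor, acceptor) == (0.0, 1.0)

    def test_no_multi_exon_transcripts_rejected(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 10)])])
        with pytest.raises(ValueError):
            tc.junction_te_overlap(cat, [])

    def test_random_fixture_matches_per_junction_check(self, sim):
        donor, acceptor = tc.junction_te_overlap(sim.catalog, sim.tes)
        from telinc.genomic_core import build_index
        index = build_index(t.interval for t in sim.tes)

        def in_te(chrom, pos):
            idx = index.get(chrom)
            return bool(idx.covers(np.array([pos]))[0]) if idx else False

        d_hit = a_hit = total = 0
        for t in sim.catalog:
            for intron in t.introns():
                total += 1
                first, last = intron.start, intron.end - 1
                d, a = (first, last) if t.strand == "+" else (last, first)
                d_hit += in_te(t.chrom, d)
                a_hit += in_te(t.chrom, a)
        assert donor == pytest.approx(d_hit / total)
        assert acceptor == pytest.approx(a_hit / total)


class TestConservation:
    def test_exact_partition_means(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 10)])])
        tes = [make_te("chr1", 0, 5)]
        track = {"chr1": (np.arange(10),
                          np.array([0.1] * 5 + [0.9] * 5))}
        out = tc.conservation_partition(cat, tes, track)
        assert out["te"]["mean"] == pytest.approx(0.1)
        assert out["non_te"]["mean"] == pytest.approx(0.9)
        assert out["te"]["n_bases"] == 5

    def test_empty_track_treat_as_zero(self):
        cat = Catalog([make_transcript("t", "chr1", [(0, 10)])])
        out = tc.conservation_partition(cat, [make_te("chr1", 0, 5)], {})
        assert out["te"]["mean"] == 0.0
        assert out["non_te"]["mean"] == 0.0

    def test_sparse_track_matches_per_base_loop(self):
        rng = np.random.default_rng(7)
        cat = Catalog([
            make_transcript("a", "chr1", [(0, 40), (60, 100)]),
            make_transcript("b", "chr1", [(150, 260)]),
        ])
        tes = [make_te("chr1", 20, 80), make_te("chr1", 200, 220)]
        pos = np.sort(rng.choice(300, 120, replace=False))
        track = {"chr1": (pos, rng.random(120))}
        out = tc.conservation_partition(cat, tes, track)

        lookup = dict(zip(track["chr1"][0].tolist(),
                          track["chr1"][1].tolist()))
        te_mask = np.zeros(300, bool)
        for te in tes:
            te_mask[te.interval.start:te.interval.end] = True
        sums = {"dte": [0.0, 0], "te": [0.0, 0], "non_te": [0.0, 0]}
        for t in cat:
            bases = [p for e in t.exons for p in range(e.start, e.end)]
            if not any(te_mask[p] for p in bases):
                for p in bases:
                    sums["dte"][0] += lookup.get(p, 0.0)
                    sums["dte"][1] += 1
            else:
                for p in bases:
                    key = "te" if te_mask[p] else "non_te"
                    sums[key][0] += lookup.get(p, 0.0)
                    sums[key][1] += 1
        for key, (tot, n) in sums.items():
            assert out[key]["n_bases"] == n
            if n:
                assert out[key]["mean"] == pytest.approx(tot / n)

    def test_planted_partition_ordering(self, sim):
        out = tc.conservation_partition(sim.catalog, sim.tes, sim.track)
        assert out["dte"]["mean"] > out["non_te"]["mean"] > out["te"]["mean"]


class TestConsensusIdentity:
    def test_identity_complements_divergence(self):
        te = make_te("chr1", 0, 10, perc_div=10.0)
        assert te.identity == 90.0

    def test_separated_groups_match_permutation_oracle(self):
        tes = [make_te("chr1", i * 10, i * 10 + 5, perc_div=d)
               for i, d in enumerate([10, 9, 8, 20, 19, 18])]
        mean_in, mean_out, p = tc.consensus_identity_compare(
            tes, [0, 1, 2], [3, 4, 5])
        assert mean_in == pytest.approx(91.0)
        assert mean_out == pytest.approx(81.0)
        assert p == pytest.approx(0.1)  # U=9 of 9; 2/20 orderings as extreme

    def test_identical_groups_not_rejected(self):
        tes = [make_te("chr1", i * 10, i * 10 + 5, perc_div=10.0)
               for i in range(6)]
        *_, p = tc.consensus_identity_compare(tes, [0, 1, 2], [3, 4, 5])
        assert p == 1.0

    def test_empty_group_rejected(self):
        tes = [make_te("chr1", 0, 5)]
        with pytest.raises(ValueError):
            tc.consensus_identity_compare(tes, [0], [])
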