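"""Binomial read enrichment, peak overlap, and TSS coverage profiles."""

import numpy as np
import pytest
from scipy.stats import binom

from telinc import chipseq_enrichment as ce
from telinc.genomic_core import Catalog, GenomeLayout, Interval
from .conftest import make_te, make_transcript


def make_reads(midpoints, chrom="c", length=2, label="treatment"):
    half = length // 2
    return ce.ReadSet([Interval(chrom, max(0, m - half), m + half)
                       for m in midpoints], label)


class TestReadEnrichment:
    def test_worked_binomial_example(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        tes = [make_te("c", 0, 100, family="f")]
        reads = make_reads([10, 20, 30, 40, 50, 500, 600, 700, 800, 900])
        r = ce.read_te_enrichment(reads, tes, "f", genome)
        assert (r.k, r.n) == (5, 10)
        assert r.p0 == pytest.approx(0.1)
        assert r.fold == pytest.approx(5.0)
        assert r.p_enrich == pytest.approx(1 - binom.cdf(4, 10, 0.1))
        assert r.p_enrich == pytest.approx(0.001635, abs=2e-6)

    def test_uniform_reads_give_unit_fold(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        tes = [make_te("c", 0, 100, family="f")]
        reads = make_reads(list(range(5, 1000, 10)))  # 100 reads, 10 inside
        r = ce.read_te_enrichment(reads, tes, "f", genome)
        assert r.fold == pytest.approx(1.0)

    def test_zero_hits_depletion_closed_form(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        tes = [make_te("c", 0, 100, family="f")]
        reads = make_reads([500, 600, 700])
        r = ce.read_te_enrichment(reads, tes, "f", genome)
        assert r.k == 0
        assert r.p_deplete == pytest.approx((1 - 0.1) ** 3)

    def test_matches_per_read_membership_loop(self):
        rng = np.random.default_rng(21)
        genome = GenomeLayout(["c1", "c2"], {"c1": 5000, "c2": 5000})
        tes = [make_te(rng.choice(["c1", "c2"]), s, s + 200, family="f")
               for s in rng.integers(0, 4800, 6)]
        reads = ce.ReadSet([
            Interval(rng.choice(["c1", "c2"]),
                     *sorted([int(x), int(x) + 50]))
            for x in rng.integers(0, 4900, 200)])
        r = ce.read_te_enrichment(reads, tes, "f", genome)
        from telinc.genomic_core import merge_pairs
        merged = {}
        for te in tes:
            merged.setdefault(te.interval.chrom, []).append(
                (te.interval.start, te.interval.end))
        merged = {c: merge_pairs(p) for c, p in merged.items()}
        k = sum(1 for rd in reads.reads
                if any(s <= (rd.start + rd.end) // 2 < e
                       for s, e in merged.get(rd.chrom, [])))
        assert r.k == k

    def test_tails_overlap_at_point_mass(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            pe = float(binom.sf(k - 1, n, p0))
            pd = float(binom.cdf(k, n, p0))
            assert pe + pd >= 1.0 - 1e-12

    def test_degenerate_family_sizes_rejected(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        reads = make_reads([10])
        with pytest.raises(ValueError):
            ce.read_te_enrichment(reads, [make_te("c", 0, 5, family="g")],
                                  "f", genome)

    def test_planted_chip_fold_recovered(self, sim):
        r = ce.read_te_enrichment(sim.treatment, sim.tes,
                                  sim.truth.chip_family, sim.genome)
        assert r.fold == pytest.approx(sim.truth.chip_fold, rel=0.30)
        assert r.p_enrich < 1e-6
        ctrl = ce.read_te_enrichment(sim.control, sim.tes,
                                     sim.truth.chip_family, sim.genome)
        assert ctrl.fold == pytest.approx(1.0, abs=0.5)


class TestPeakOverlap:
    def test_saturating_and_empty_peak_sets(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        els = [make_te("c", 100, 200, family="f"), make_te("c", 500, 600, family="f")]
        rng = np.random.default_rng(0)
        frac, _ = ce.peak_overlap_fraction(els, [Interval("c", 0, 1000)],
                                           genome, n_shuffles=10, rng=rng)
        assert frac == 1.0
        frac, _ = ce.peak_overlap_fraction(els, [], genome, n_shuffles=10,
                                           rng=np.random.default_rng(1))
        assert frac == 0.0

    def test_empty_elements_rejected(self):
        genome = GenomeLayout(["c"], {"c": 1000})
        with pytest.raises(ValueError):
            ce.peak_overlap_fraction([], [], genome)

    def test_planted_colocation_recovered(self, sim):
        planted = set(map(tuple, sim.truth.planted_elements))
        els = [t for t in sim.tes
               if (t.interval.chrom, t.interval.start, t.interval.end,
                   t.interval.strand) in planted]
        frac, p = ce.peak_overlap_fraction(
            els, sim.peaks, sim.genome, rng=np.random.default_rng(5))
        assert frac == pytest.approx(sim.truth.peak_cover_fraction, abs=0.10)
        assert p < 0.01


class TestTSSProfile:
    def test_treatment_equals_control_is_flat_zero(self):
        cat = Catalog([make_transcript("t", "c", [(1000, 1400)], "+")])
        reads = make_reads([900, 1100, 1300], length=50)
        prof = ce.tss_chip_profile(cat, reads, reads, flank=500)
        assert np.allclose(prof.values, 0.0)

    def test_single_read_coordinate_footprint(self):
        cat = Catalog([make_transcript("t", "c", [(1000, 1400)], "+")])
        reads = ce.ReadSet([Interval("c", 990, 1010)])
        prof = ce.tss_chip_profile(cat, reads, None, flank=100)
        nonzero = prof.offsets[prof.values > 0]
        assert nonzero.min() == -10 and nonzero.max() == 9
        assert prof.values.max() == pytest.approx(1e6 / 1)

    def test_duplicating_reads_leaves_profile_unchanged(self):
        cat = Catalog([make_transcript("t", "c", [(1000, 1400)], "+")])
        reads = ce.ReadSet([Interval("c", 990, 1010), Interval("c", 1200, 1260)])
        doubled = ce.ReadSet(reads.reads * 2)
        p1 = ce.tss_chip_profile(cat, reads, None, flank=300)
        p2 = ce.tss_chip_profile(cat, doubled, None, flank=300)
        assert np.allclose(p1.values, p2.values)

    def test_family_restriction_requires_promoter_element(self):
        cat = Catalog([
            make_transcript("with", "c", [(5000, 5400)], "+"),
            make_transcript("without", "c", [(20000, 20400)], "+"),
        ])
        tes = [make_te("c", 4800, 5100, family="f")]
        reads = make_reads([5100], length=50)
        prof = ce.tss_chip_profile(cat, reads, None, flank=200,
                                   restrict_family="f", tes=tes)
        assert prof.n_transcripts == 1

    def test_no_qualifying_transcripts_rejected(self):
        cat = Catalog([make_transcript("t", "c", [(1000, 1400)], "+")])
        tes = [make_te("c", 90_000, 90_100, family="f")]
        with pytest.raises(ValueError):
            ce.tss_chip_profile(cat, make_reads([10]), None,
                                restrict_family="f", tes=tes)

    def test_shifted_planted_signal_peaks_downstream(self):
        """Reads placed downstream of planted TSS elements produce a
        coverage maximum at a positive offset."""
        from telinc import synthetic_data as sd

        cfg = sd.SimConfig(seed=3)
        cfg.chip.read_shift = 450  # planted elements are 500 bp
        sim = sd.simulate(cfg)
        prof = ce.tss_chip_profile(
            sim.catalog, sim.treatment, sim.control, flank=1500,
            restrict_family=sim.truth.chip_family, tes=sim.tes)
        assert int(prof.offsets[np.argmax(prof.values)]) > 0
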