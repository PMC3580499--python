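"""ChIP-Seq read and peak enrichment at TE elements.

Each aligned read is modeled as a Bernoulli draw whose success probability
is the TE family's merged bp over the alignable genome; enrichment and
depletion are the exact binomial tails.  Peak/element co-location is tested
by shuffling the elements (peaks frozen) with the same machinery as the
transcript shuffle.  TSS coverage profiles subtract control coverage after
per-million scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_core import (
    Catalog,
    GenomeLayout,
    Interval,
    IntervalSet,
    build_index,
    build_family_index,
)
from .position_orientation import MetaProfile

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2000
#: Strand-oriented promoter window (upstream, downstream of the TSS) used to
#: select transcripts for TE-restricted coverage profiles.
DEFAULT_PROMOTER = (-2000, 200)


@dataclass
class ReadSet:
    """Single-best-alignment reads as intervals."""

    reads: list
    label: str = "treatment"

    @property
    def total(self) -> int:
        return len(self.reads)

    def midpoints_by_chrom(self) -> dict:
        out: dict = {}
        for r in self.reads:
            out.setdefault(r.chrom, []).append((r.start + r.end) // 2)
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class ChipEnrichment:
    family: str
    k: int
    n: int
    p0: float
    fold: float
    p_enrich: float
    p_deplete: float
    q: float = float("nan")


def read_te_enrichment(reads: ReadSet, tes, family: str,
                       genome: GenomeLayout, key: str = "family") -> ChipEnrichment:
    """Binomial enrichment of reads in one TE family.

    A read belongs to the family if its midpoint base falls inside a merged
    family element; the null success probability p0 is family bp over the
    alignable genome.  Both exact tails are reported: p_enrich = P(X >= k),
    p_deplete = P(X <= k).
    """
    fam_index = build_family_index(tes, key=key)
    if family not in fam_index:
        raise ValueError(f"family {family!r} absent from TE annotations")
    by_chrom = fam_index[family]
    family_bp = sum(idx.total_bp for idx in by_chrom.values())
    alignable = genome.alignable_size
    if family_bp == 0 or family_bp >= alignable:
        raise ValueError(
            f"family bp {family_bp} must be in (0, alignable={alignable})")
    p0 = family_bp / alignable
    k = 0
    for chrom, mids in reads.midpoints_by_chrom().items():
        idx = by_chrom.get(chrom)
        if idx is not None:
            k += int(idx.covers(mids).sum())
    n = reads.total
    fold = (k / n) / p0 if n else float("nan")
    p_enrich = float(stats.binom.sf(k - 1, n, p0))
    p_deplete = float(stats.binom.cdf(k, n, p0))
    return ChipEnrichment(family, k, n, p0, fold, p_enrich, p_deplete)


def _place_interval(iv: Interval, genome: GenomeLayout,
                    rng: np.random.Generator, retry_cap: int = 1000) -> Interval:
    from .enrichment_shuffle import _admissible

    length = genome.chrom_lengths[iv.chrom]
    span = len(iv)
    excluded = genome.excluded_pairs(iv.chrom)
    for _ in range(retry_cap):
        start = int(rng.integers(0, length - span + 1))
        if _admissible(start, span, excluded):
            return Interval(iv.chrom, start, start + span, iv.strand)
    raise ValueError(f"no admissible placement for element on {iv.chrom}")


def peak_overlap_fraction(te_elements, peaks, genome: GenomeLayout,
                          n_shuffles: int = 100,
                          rng: np.random.Generator | None = None) -> tuple:
    """Fraction of elements overlapping >= 1 peak bp, with a shuffle-null p.

    Elements are relocated uniformly on their own chromosome (peaks frozen)
    ``n_shuffles`` times; a normal fit to the null fractions gives a
    two-sided p, as in the transcript-shuffle enrichment test.
    """
    elements = [te.interval if hasattr(te, "interval") else te
                for te in te_elements]
    if not elements:
        raise ValueError("empty element set")
    if rng is None:
        rng = np.random.default_rng()
    peak_index = build_index(peaks)

    def fraction(ivs):
        hit = 0
        for iv in ivs:
            idx = peak_index.get(iv.chrom)
            if idx is not None and idx.any_overlap(iv.start, iv.end):
                hit += 1
        return hit / len(ivs)

    observed = fraction(elements)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = fraction([_place_interval(iv, genome, rng)
                            for iv in elements])
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if observed == mu else np.finfo(float).tiny
    else:
        z = (observed - mu) / sd
        p = 2.0 * min(stats.norm.cdf(z), stats.norm.sf(z))
    return observed, float(min(p, 1.0))


def _coverage_at(positions: np.ndarray, starts: np.ndarray,
                 ends: np.ndarray) -> np.ndarray:
    """Number of reads overlapping each base position (sorted start/end)."""
    return (np.searchsorted(starts, positions, side="right")
            - np.searchsorted(ends, positions, side="right"))


def _read_arrays(reads: ReadSet) -> dict:
    out: dict = {}
    for r in reads.reads:
        s, e = out.setdefault(r.chrom, ([], []))
        s.append(r.start)
        e.append(r.end)
    return {c: (np.sort(np.asarray(s, dtype=np.int64)),
                np.sort(np.asarray(e, dtype=np.int64)))
            for c, (s, e) in out.items()}


def tss_chip_profile(catalog: Catalog, treatment: ReadSet,
                     control: ReadSet | None = None,
                     flank: int = DEFAULT_FLANK,
                     promoter: tuple = DEFAULT_PROMOTER,
                     restrict_family: str | None = None,
                     tes=None, key: str = "family") -> MetaProfile:
    """Control-subtracted ChIP coverage around TSSs, strand-oriented.

    Per-offset value = mean over transcripts of (treatment coverage -
    control coverage), each scaled to reads-per-million, so the profile is
    invariant to sequencing depth and may be negative.  With
    ``restrict_family``, only transcripts carrying an element of that
    family inside the strand-oriented promoter window (upstream, downstream
    relative to the TSS) are profiled.
    """
    transcripts = list(catalog)
    if restrict_family is not None:
        if tes is None:
            raise ValueError("restrict_family requires TE annotations")
        fam_index = build_family_index(tes, key=key)
        if restrict_family not in fam_index:
            raise ValueError(f"family {restrict_family!r} absent from TEs")
        by_chrom = fam_index[restrict_family]
        lo, hi = promoter

        def qualifies(t):
            idx = by_chrom.get(t.chrom)
            if idx is None:
                return False
            if t.strand == "+":
                s, e = t.tss + lo, t.tss + hi
            else:
                s, e = t.tss - hi, t.tss - lo
            return s < e and idx.any_overlap(max(s, 0), max(e, 1))

        transcripts = [t for t in transcripts if qualifies(t)]
    if not transcripts:
        raise ValueError("no qualifying transcripts for TSS profile")

    treat_arr = _read_arrays(treatment)
    ctrl_arr = _read_arrays(control) if control is not None else {}
    scale_t = 1e6 / treatment.total if treatment.total else 0.0
    scale_c = (1e6 / control.total if control is not None and control.total
               else 0.0)

    offsets = np.arange(-flank, flank)
    acc = np.zeros(2 * flank)
    for t in transcripts:
        pos = t.offset_to_genomic(offsets, "tss")
        valid = pos >= 0
        safe = np.where(valid, pos, 0)
        cov = np.zeros(2 * flank)
        if t.chrom in treat_arr:
            s, e = treat_arr[t.chrom]
            cov += scale_t * _coverage_at(safe, s, e)
        if t.chrom in ctrl_arr:
            s, e = ctrl_arr[t.chrom]
            cov -= scale_c * _coverage_at(safe, s, e)
        acc += np.where(valid, cov, 0.0)
    values = acc / len(transcripts)
    return MetaProfile(restrict_family or "all", "tss", offsets, values,
                       len(transcripts))


def read_bed_reads(text: str, label: str = "treatment") -> ReadSet:
    from .genomic_core import read_bed_intervals

    return ReadSet(read_bed_intervals(text), label)
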