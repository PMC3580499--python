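"""TE positional meta-profiles around transcript ends and orientation tests.

Strand-aware coverage profiles anchored at the TSS or 3' end, 100-bin
interior profiles over the locus span, and exact binomial tests of
sense/antisense orientation bias against a 50/50 null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .genomic_core import Catalog, IntervalSet, build_family_index

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2000
DEFAULT_N_BINS = 100
#: Strand-oriented window downstream of the 3' end used for 3'-end
#: orientation counting (captures the Alu peak ~250 nt downstream).
END3_WINDOW = 500
#: A consensus_span covering at least this fraction of the family consensus
#: qualifies an element as full length.
FULL_LENGTH_FRACTION = 0.9


@dataclass
class MetaProfile:
    """Mean 0/1 TE coverage at strand-oriented offsets around an anchor."""

    family: str
    anchor: str  # tss | tes3
    offsets: np.ndarray
    values: np.ndarray
    n_transcripts: int


@dataclass
class InteriorProfile:
    """Mean fractional TE coverage over n_bins tiling each locus 5'->3'."""

    family: str
    n_bins: int
    values: np.ndarray
    n_transcripts: int


@dataclass
class OrientationResult:
    family: str
    region: str  # tss | end3 | transcript
    n_sense: int
    n_antisense: int
    n_unstranded: int
    p: float
    q: float = float("nan")


def _family_chrom_index(tes, family: str, key: str = "family") -> dict:
    index = build_family_index(tes, key=key)
    if family not in index:
        raise ValueError(f"family {family!r} absent from TE annotations")
    return index[family]


def endpoint_profile(catalog: Catalog, tes, family: str, anchor: str = "tss",
                     flank: int = DEFAULT_FLANK, key: str = "family",
                     genome=None) -> MetaProfile:
    """Mean TE coverage indicator around transcript 5' or 3' ends.

    Offsets run -flank..flank-1 in transcription direction (negative =
    upstream of the anchor); minus-strand transcripts are genomically
    mirrored.  Each transcript contributes a 0/1 indicator per offset
    (inside any element of the family or not); transcripts whose window
    runs off the chromosome contribute only in-bounds offsets, so each
    offset keeps its own denominator.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if anchor not in ("tss", "tes3"):
        raise ValueError(f"unknown anchor {anchor!r}")
    by_chrom = _family_chrom_index(tes, family, key)
    offsets = np.arange(-flank, flank)
    hits = np.zeros(2 * flank)
    denom = np.zeros(2 * flank)
    for t in catalog:
        pos = t.offset_to_genomic(offsets, "tss" if anchor == "tss" else "end3")
        in_bounds = pos >= 0
        if genome is not None:
            in_bounds &= pos < genome.chrom_lengths[t.chrom]
        denom += in_bounds
        idx = by_chrom.get(t.chrom)
        if idx is None:
            continue
        covered = idx.covers(np.where(in_bounds, pos, 0)) & in_bounds
        hits += covered
    with np.errstate(invalid="ignore"):
        values = np.where(denom > 0, hits / np.maximum(denom, 1), 0.0)
    return MetaProfile(family, anchor, offsets, values, len(catalog))


def interior_profile(catalog: Catalog, tes, family: str,
                     n_bins: int = DEFAULT_N_BINS, key: str = "family") -> InteriorProfile:
    """Mean fractional TE coverage of n_bins tiling each locus span.

    Bins run 5'->3' in transcription direction (minus-strand loci are
    mirrored); bin value is covered bp over bin width.  Transcripts with
    span < n_bins are skipped (logged).
    """
    by_chrom = _family_chrom_index(tes, family, key)
    total = np.zeros(n_bins)
    n_used = n_skipped = 0
    for t in catalog:
        if t.span < n_bins:
            n_skipped += 1
            continue
        idx = by_chrom.get(t.chrom)
        if idx is None:
            fractions = np.zeros(n_bins)
        else:
            bounds = t.start + t.span * np.arange(n_bins + 1) / n_bins
            cov = idx.coverage_to(bounds)
            widths = np.diff(bounds)
            fractions = np.diff(cov) / widths
        if t.strand == "-":
            fractions = fractions[::-1]
        total += fractions
        n_used += 1
    if n_skipped:
        logger.info("interior_profile: skipped %d transcripts with span < %d",
                    n_skipped, n_bins)
    if n_used == 0:
        raise ValueError("no transcripts long enough for interior profile")
    return InteriorProfile(family, n_bins, total / n_used, n_used)


def is_full_length(te, consensus_length: float | None = None,
                   min_element_bp: int = 0) -> bool:
    """Element qualifies as full length if its consensus span covers >= 90%
    of the family consensus; falls back to a length threshold when
    consensus coordinates are absent."""
    if te.consensus_span is not None:
        begin, end, left = te.consensus_span
        total = consensus_length if consensus_length else max(end, end + left)
        if total > 0:
            return (end - begin + 1) / total >= FULL_LENGTH_FRACTION
    return len(te.interval) >= min_element_bp


def orientation_counts(catalog: Catalog, tes, family: str,
                       region: str = "tss", min_element_bp: int = 0,
                       key: str = "family") -> tuple:
    """Count sense/antisense (element, transcript) pairs for a TE family.

    Regions: ``tss`` - element span contains the TSS base; ``end3`` -
    element overlaps the strand-oriented window [3' end, 3' end + 500);
    ``transcript`` - element overlaps any exon.  Sense means element strand
    equals transcript strand; unstranded ('.') elements are excluded from
    the counts and tallied separately.

    Returns (n_sense, n_antisense, n_unstranded).
    """
    if region not in ("tss", "end3", "transcript"):
        raise ValueError(f"unknown region {region!r}")
    elements = [te for te in tes
                if (te.family if key == "family" else te.element_name) == family
                and len(te.interval) >= min_element_bp]
    by_chrom: dict = {}
    for te in elements:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    n_sense = n_anti = n_unstranded = 0
    for t in catalog:
        for te in by_chrom.get(t.chrom, ()):
            iv = te.interval
            if region == "tss":
                hit = iv.start <= t.tss_base < iv.end
            elif region == "end3":
                if t.strand == "+":
                    lo, hi = t.end, t.end + END3_WINDOW
                else:
                    lo, hi = t.start - END3_WINDOW, t.start
                hit = iv.start < hi and lo < iv.end
            else:
                hit = any(iv.start < e.end and e.start < iv.end
                          for e in t.exons)
            if not hit:
                continue
            if iv.strand == ".":
                n_unstranded += 1
            elif iv.strand == t.strand:
                n_sense += 1
            else:
                n_anti += 1
    return n_sense, n_anti, n_unstranded


def orientation_test(n_sense: int, n_antisense: int) -> float:
    """Exact two-sided binomial test of sense/antisense counts vs 50/50.

    Two-sided p sums the point masses no larger than the observed one.
    """
    if n_sense < 0 or n_antisense < 0:
        raise ValueError("negative counts")
    n = n_sense + n_antisense
    if n == 0:
        raise ValueError("no stranded elements to test")
    return float(binomtest(n_sense, n, 0.5).pvalue)


def orientation_table(catalog: Catalog, tes, families, region: str = "tss",
                      min_element_bp: int = 0, key: str = "family") -> list:
    """orientation_counts + orientation_test per family, BH across the set."""
    from .enrichment_shuffle import bh_correct

    results = []
    for family in families:
        s, a, u = orientation_counts(catalog, tes, family, region,
                                     min_element_bp, key)
        p = orientation_test(s, a) if (s + a) else 1.0
        results.append(OrientationResult(family, region, s, a, u, p))
    for r, q in zip(results, bh_correct([r.p for r in results])):
        r.q = float(q)
    return results
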