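"""Descriptive TE-composition statistics for a transcript catalog.

Coverage fractions per transcript and catalog-wide, the TE/dTE transcript
partition, distinct families per transcript, splice-junction TE overlap,
per-base conservation partitioning, and consensus-identity comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_core import (
    Catalog,
    GenomeLayout,
    IntervalSet,
    build_family_index,
    build_index,
    merge_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class CompositionSummary:
    """TE content of a catalog, per transcript and aggregated.

    ``per_transcript`` columns: te_bp, mature_bp, te_fraction, n_families,
    families (frozenset).  The dTE set is the transcripts with te_bp = 0.
    """

    per_transcript: pd.DataFrame
    per_family: pd.DataFrame  # columns: bp, n_transcripts
    space: str
    fraction_transcripts_with_te: float = field(init=False)
    fraction_sequence_te: float = field(init=False)
    median_te_fraction: float = field(init=False)
    mean_families_per_transcript: float = field(init=False)

    def __post_init__(self):
        df = self.per_transcript
        self.fraction_transcripts_with_te = float((df.te_bp > 0).mean())
        self.fraction_sequence_te = float(df.te_bp.sum() / df.mature_bp.sum())
        self.median_te_fraction = float(df.te_fraction.median())
        self.mean_families_per_transcript = float(df.n_families.mean())

    @property
    def te_transcripts(self) -> list:
        return list(self.per_transcript.index[self.per_transcript.te_bp > 0])

    @property
    def dte_transcripts(self) -> list:
        return list(self.per_transcript.index[self.per_transcript.te_bp == 0])


def _transcript_pairs(t, space: str):
    if space == "exonic":
        return [(e.start, e.end) for e in t.exons]
    if space == "locus":
        return [(t.start, t.end)]
    raise ValueError(f"unknown space {space!r}")


def composition_summary(catalog: Catalog, tes, space: str = "exonic") -> CompositionSummary:
    """TE composition of a catalog against a TE annotation set.

    ``space='exonic'`` (default) counts TE bp against merged exons (the
    mature transcript); ``'locus'`` counts against the full locus span.
    Overlapping TEs of different families each contribute family membership,
    but te_bp is the merged union over all TEs (no double counting).
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    all_te = build_index(te.interval for te in tes)
    fam_index = build_family_index(tes)

    rows = []
    fam_bp: dict = {f: 0.0 for f in fam_index}
    fam_tx: dict = {f: 0 for f in fam_index}
    for t in catalog:
        pairs = _transcript_pairs(t, space)
        size = sum(e - s for s, e in pairs)
        idx = all_te.get(t.chrom)
        te_bp = idx.overlap_pairs_bp(pairs) if idx is not None else 0.0
        families = set()
        for f, by_chrom in fam_index.items():
            fidx = by_chrom.get(t.chrom)
            if fidx is None:
                continue
            bp = fidx.overlap_pairs_bp(pairs)
            if bp > 0:
                families.add(f)
                fam_bp[f] += bp
                fam_tx[f] += 1
        rows.append((t.transcript_id, te_bp, size, te_bp / size,
                     frozenset(families), len(families)))
    per_transcript = pd.DataFrame(
        rows, columns=["transcript_id", "te_bp", "mature_bp", "te_fraction",
                       "families", "n_families"]
    ).set_index("transcript_id")
    per_family = pd.DataFrame(
        {"bp": pd.Series(fam_bp), "n_transcripts": pd.Series(fam_tx)}
    )
    return CompositionSummary(per_transcript, per_family, space)


def genome_te_fraction(tes, genome: GenomeLayout) -> float:
    """Fraction of the genome covered by merged TE annotations."""
    index = build_index(te.interval for te in tes)
    covered = sum(idx.total_bp for idx in index.values())
    return covered / genome.total_size


def junction_te_overlap(catalog: Catalog, tes) -> tuple:
    """Fraction of splice donor / acceptor sites falling inside a TE.

    The donor site is the first intronic base past an exon in transcription
    direction; the acceptor site is the last intronic base before the next
    exon.  On the minus strand the genomic roles are mirrored.
    """
    index = build_index(te.interval for te in tes)
    donors: dict = {}
    acceptors: dict = {}
    n_junctions = 0
    for t in catalog:
        if t.n_exons < 2:
            continue
        for intron in t.introns():
            n_junctions += 1
            first, last = intron.start, intron.end - 1
            d, a = (first, last) if t.strand == "+" else (last, first)
            donors.setdefault(t.chrom, []).append(d)
            acceptors.setdefault(t.chrom, []).append(a)
    if n_junctions == 0:
        raise ValueError("no multi-exon transcripts in catalog")

    def frac(sites_by_chrom):
        hit = total = 0
        for chrom, sites in sites_by_chrom.items():
            idx = index.get(chrom)
            total += len(sites)
            if idx is not None:
                hit += int(idx.covers(np.asarray(sites)).sum())
        return hit / total

    return frac(donors), frac(acceptors)


def conservation_partition(catalog: Catalog, tes, track: dict,
                           missing: str = "treat-as-0",
                           per_transcript: bool = False) -> dict:
    """Mean conservation over three disjoint base sets.

    Partitions exonic bases into: dTE-transcript bases, TE bases of
    TE-transcripts, and non-TE bases of TE-transcripts.  ``track`` is a
    sparse per-base map (chrom -> (positions, scores)); bases absent from
    the track score 0 under ``missing='treat-as-0'`` and are dropped under
    ``'skip'``.  With ``per_transcript=True`` means of per-transcript means
    are returned instead of pooled per-base means.

    Returns dict of group -> {'mean': float, 'n_bases': int}.
    """
    if missing not in ("treat-as-0", "skip"):
        raise ValueError(f"unknown missing policy {missing!r}")
    te_index = build_index(te.interval for te in tes)

    def lookup(chrom, positions):
        entry = track.get(chrom)
        if entry is None:
            scores = np.zeros(len(positions))
            found = np.zeros(len(positions), dtype=bool)
            return scores, found
        pos, val = entry
        i = np.searchsorted(pos, positions)
        i = np.clip(i, 0, len(pos) - 1)
        found = pos[i] == positions
        scores = np.where(found, val[i], 0.0)
        return scores, found

    groups = {"dte": [], "te": [], "non_te": []}
    for t in catalog:
        idx = te_index.get(t.chrom)
        bases = np.concatenate([np.arange(e.start, e.end) for e in t.exons])
        in_te = idx.covers(bases) if idx is not None else np.zeros(len(bases), bool)
        scores, found = lookup(t.chrom, bases)
        if missing == "skip":
            bases, in_te, scores = bases[found], in_te[found], scores[found]
        if not in_te.any():
            groups["dte"].append((scores, np.ones(len(scores), bool)))
        else:
            groups["te"].append((scores, in_te))
            groups["non_te"].append((scores, ~in_te))

    out = {}
    for name, chunks in groups.items():
        if per_transcript:
            means = [float(s[m].mean()) for s, m in chunks if m.any()]
            n = sum(int(m.sum()) for s, m in chunks)
            mean = float(np.mean(means)) if means else 0.0
        else:
            tot = sum(float(s[m].sum()) for s, m in chunks)
            n = sum(int(m.sum()) for s, m in chunks)
            mean = tot / n if n else 0.0
        out[name] = {"mean": mean, "n_bases": n}
    return out


def consensus_identity_compare(tes, inside_ids, outside_ids) -> tuple:
    """Mean consensus identity (100 - %div) of elements inside vs outside a
    catalog, with a two-sided rank-sum p.

    ``inside_ids``/``outside_ids`` index ``tes`` by position.
    """
    from .expression_analysis import rank_sum_test

    inside = [tes[i].identity for i in inside_ids]
    outside = [tes[i].identity for i in outside_ids]
    if not inside or not outside:
        raise ValueError("both element groups must be non-empty")
    _, p = rank_sum_test(inside, outside)
    return float(np.mean(inside)), float(np.mean(outside)), p
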