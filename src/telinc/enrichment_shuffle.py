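"""Shuffling statistical test for TE family enrichment.

Transcript models are relocated uniformly at random on their own chromosome
(exon structure, strand, and mature length frozen; TE annotations fixed in
place), the statistic of interest is recomputed for each of ``n_shuffles``
null catalogs, a normal distribution is fit to the null sample, and
two-sided p-values are read from its CDF.  q-values are Benjamini-Hochberg
across the families tested in one invocation.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_core import Catalog, GenomeLayout, Interval, Transcript, build_family_index

logger = logging.getLogger(__name__)

DEFAULT_N_SHUFFLES = 100
PLACEMENT_RETRY_CAP = 1000


@dataclass
class EnrichmentResult:
    """Observed statistic vs the shuffle null for one TE family."""

    family: str
    observed: float
    null_mean: float
    null_sd: float
    fold: float
    z: float
    p: float
    q: float
    n_shuffles: int
    direction: str  # enriched | depleted


def _admissible(start: int, span: int, excluded_pairs) -> bool:
    for s, e in excluded_pairs:
        if start < e and s < start + span:
            return False
    return True


def place_transcript(transcript: Transcript, genome: GenomeLayout,
                     rng: np.random.Generator,
                     retry_cap: int = PLACEMENT_RETRY_CAP) -> Transcript:
    """Relocate one transcript uniformly on its chromosome.

    The full locus span must fit on the chromosome and avoid excluded
    regions; placement is rejection-sampled with a retry cap, and exon
    offsets within the locus (hence intron lengths) are preserved.
    """
    chrom = transcript.chrom
    length = genome.chrom_lengths[chrom]
    span = transcript.span
    if span > length:
        raise ValueError(
            f"{transcript.transcript_id}: span {span} exceeds {chrom} length"
        )
    excluded = genome.excluded_pairs(chrom)
    for _ in range(retry_cap):
        start = int(rng.integers(0, length - span + 1))
        if _admissible(start, span, excluded):
            shift = start - transcript.start
            exons = [Interval(chrom, e.start + shift, e.end + shift, e.strand)
                     for e in transcript.exons]
            return Transcript(transcript.transcript_id, transcript.gene_id,
                              exons, dict(transcript.scores))
    raise ValueError(
        f"{transcript.transcript_id}: no admissible placement on {chrom} "
        f"after {retry_cap} tries"
    )


def shuffle_catalog(catalog: Catalog, genome: GenomeLayout,
                    rng: np.random.Generator,
                    retry_cap: int = PLACEMENT_RETRY_CAP) -> Catalog:
    """Relocate every transcript independently (TEs stay frozen)."""
    return Catalog([place_transcript(t, genome, rng, retry_cap)
                    for t in catalog])


def _family_statistic(catalog: Catalog, family_index: dict,
                      statistic: str) -> dict:
    """Per-family observed statistic on one catalog.

    ``bp``: exonic TE-family bp summed over transcripts (merged within the
    family, so overlapping same-family elements never double count).
    ``transcripts``: number of transcripts with >= 1 bp exonic overlap.
    """
    out = {}
    for family, by_chrom in family_index.items():
        total = 0.0
        for t in catalog:
            idx = by_chrom.get(t.chrom)
            if idx is None:
                continue
            bp = idx.overlap_pairs_bp([(e.start, e.end) for e in t.exons])
            if statistic == "bp":
                total += bp
            else:
                total += 1.0 if bp > 0 else 0.0
        out[family] = total
    return out


class _ShufflePlan:
    """Per-chromosome vectorized layout of a catalog for fast shuffling.

    Stores transcript spans and within-locus exon offsets so a whole null
    catalog reduces to one uniform start draw per transcript (rejection
    against excluded regions, identical in distribution to
    ``place_transcript``) followed by prefix-sum coverage queries.
    """

    def __init__(self, catalog: Catalog, genome: GenomeLayout):
        self.chroms = []
        by_chrom: dict = {}
        for t in catalog:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, txs in sorted(by_chrom.items()):
            length = genome.chrom_lengths[chrom]
            spans = np.array([t.span for t in txs], dtype=np.int64)
            if (spans > length).any():
                bad = txs[int(np.argmax(spans > length))]
                raise ValueError(
                    f"{bad.transcript_id}: span exceeds {chrom} length")
            off_s, off_e, ex_tx = [], [], []
            for i, t in enumerate(txs):
                for e in t.exons:
                    off_s.append(e.start - t.start)
                    off_e.append(e.end - t.start)
                    ex_tx.append(i)
            self.chroms.append({
                "chrom": chrom,
                "ids": [t.transcript_id for t in txs],
                "n": len(txs),
                "high": length - spans + 1,
                "spans": spans,
                "orig_starts": np.array([t.start for t in txs], dtype=np.int64),
                "off_s": np.array(off_s, dtype=np.int64),
                "off_e": np.array(off_e, dtype=np.int64),
                "ex_tx": np.array(ex_tx, dtype=np.int64),
                "excluded": genome.excluded_pairs(chrom),
            })

    def draw_starts(self, group: dict, rng,
                    retry_cap: int = PLACEMENT_RETRY_CAP) -> np.ndarray:
        starts = rng.integers(0, group["high"])
        excluded = group["excluded"]
        if not excluded:
            return starts
        spans = group["spans"]
        for _ in range(retry_cap):
            bad = np.zeros(group["n"], dtype=bool)
            for s, e in excluded:
                bad |= (starts < e) & (s < starts + spans)
            if not bad.any():
                return starts
            starts[bad] = rng.integers(0, group["high"][bad])
        stuck = group["ids"][int(np.argmax(bad))]
        raise ValueError(
            f"{stuck}: no admissible placement on {group['chrom']} "
            f"after {retry_cap} tries")

    def statistics(self, starts_by_group: list, family_index: dict,
                   statistic: str) -> dict:
        totals = dict.fromkeys(family_index, 0.0)
        for group, starts in zip(self.chroms, starts_by_group):
            b_start = starts[group["ex_tx"]] + group["off_s"]
            b_end = starts[group["ex_tx"]] + group["off_e"]
            for family, by_chrom in family_index.items():
                idx = by_chrom.get(group["chrom"])
                if idx is None:
                    continue
                bp = idx.coverage_to(b_end) - idx.coverage_to(b_start)
                if statistic == "bp":
                    totals[family] += float(bp.sum())
                else:
                    per_tx = np.bincount(group["ex_tx"], weights=bp,
                                         minlength=group["n"])
                    totals[family] += float((per_tx > 0).sum())
        return totals


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def family_enrichment(catalog: Catalog, tes, genome: GenomeLayout,
                      families=None, statistic: str = "bp",
                      n_shuffles: int = DEFAULT_N_SHUFFLES,
                      rng: np.random.Generator | None = None,
                      two_sided: bool = True) -> list:
    """Shuffle-null enrichment/depletion of TE families in a catalog.

    Parameters
    ----------
    families : optional list of family names to test (default: all families
        present in ``tes``); unknown names raise.
    statistic : 'bp' (exonic family bp, default) or 'transcripts'
        (transcripts with any exonic overlap).
    n_shuffles : size of the null sample the normal is fit to (>= 2).

    Returns one EnrichmentResult per family, BH-corrected across the set.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if statistic not in ("bp", "transcripts"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if rng is None:
        rng = np.random.default_rng()
    index = build_family_index(tes)
    if families is None:
        families = sorted(index)
    else:
        unknown = [f for f in families if f not in index]
        if unknown:
            raise ValueError(f"unknown TE families: {unknown}")
        index = {f: index[f] for f in families}

    plan = _ShufflePlan(catalog, genome)
    observed = plan.statistics(
        [g["orig_starts"] for g in plan.chroms], index, statistic)
    null = {f: np.empty(n_shuffles) for f in families}
    for i in range(n_shuffles):
        starts = [plan.draw_starts(g, rng) for g in plan.chroms]
        stat = plan.statistics(starts, index, statistic)
        for f in families:
            null[f][i] = stat[f]

    results = []
    p_values = []
    for f in families:
        obs = observed[f]
        mu = float(np.mean(null[f]))
        sd = float(np.std(null[f], ddof=1))
        if sd == 0.0:
            logger.warning("family %s: degenerate null (sd = 0)", f)
            z = 0.0
            p = 1.0 if obs == mu else sys.float_info.min
        else:
            z = (obs - mu) / sd
            if two_sided:
                p = 2.0 * min(stats.norm.cdf(z), stats.norm.sf(z))
            else:
                p = float(stats.norm.sf(z))
        fold = obs / mu if mu > 0 else float("inf") if obs > 0 else 1.0
        results.append(EnrichmentResult(
            family=f, observed=obs, null_mean=mu, null_sd=sd, fold=fold,
            z=z, p=min(p, 1.0), q=float("nan"), n_shuffles=n_shuffles,
            direction="enriched" if fold >= 1.0 else "depleted",
        ))
        p_values.append(results[-1].p)
    for r, q in zip(results, bh_correct(p_values)):
        r.q = float(q)
    return results
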