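"""The lincRNA catalog filter cascade and primary-isoform selection.

Stages, applied in order to an already-assembled catalog:

1. structure        - >= 2 exons and mature length > 200 bp
2. expression       - > 1 FPKM in at least one sample
3. coding potential - sense overlap with protein exons, or PhyloCSF > 100
4. annotation overlap - exonic overlap with tRNA/rRNA/small-RNA annotations
5. antisense/pseudogene - exonic overlap with a protein exon on the
   opposite strand, or with a pseudogene

A whitelist of externally validated transcript ids bypasses the expression
and coding-potential stages (they were added back from curated annotation
sets) but not the antisense/pseudogene removals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genomic_core import Catalog, Transcript, build_index
from .expression_analysis import ExpressionMatrix, DEFAULT_PSEUDOCOUNT

logger = logging.getLogger(__name__)

KNOWN_ANNOTATION_SETS = ("protein_exons", "smallrna", "pseudogenes")

STAGES = ("structure", "expression", "coding_potential",
          "annotation_overlap", "antisense_pseudogene")


@dataclass
class FilterParams:
    min_exons: int = 2
    min_length: int = 200          # mature (summed-exon) bp, strict >
    min_fpkm_any: float = 1.0      # strict >, in at least one sample
    phylocsf_max: float = 100.0    # scores above this are called coding
    phylocsf_score_name: str = "phylocsf"
    length_space: str = "mature"   # mature | locus
    antisense_protein_exclusion: bool = True
    whitelist: frozenset = frozenset()

    def __post_init__(self):
        if min(self.min_exons, self.min_length, self.min_fpkm_any) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterStage:
    stage: str
    n_input: int
    n_removed: int
    survivor_ids: list


@dataclass
class FilterReport:
    stages: list = field(default_factory=list)

    def add(self, stage: str, n_input: int, survivors: list):
        self.stages.append(FilterStage(stage, n_input,
                                       n_input - len(survivors), survivors))

    def validate_telescoping(self):
        for a, b in zip(self.stages, self.stages[1:]):
            assert len(a.survivor_ids) == b.n_input, "report does not telescope"

    def to_rows(self) -> list:
        return [(s.stage, s.n_input, s.n_removed) for s in self.stages]


def _tx_length(t: Transcript, space: str) -> int:
    return t.mature_length if space == "mature" else t.span


def _exonic_overlap(t: Transcript, index: dict, strand: str | None = None) -> bool:
    """Any exonic bp overlap with an annotation index; ``strand`` restricts
    to annotations on the same ('sense') or opposite ('antisense') strand."""
    sets = index.get(t.chrom)
    if sets is None:
        return False
    if strand is None:
        idx = sets.get("any")
        return idx is not None and any(
            idx.any_overlap(e.start, e.end) for e in t.exons)
    want = t.strand if strand == "sense" else ("-" if t.strand == "+" else "+")
    idx = sets.get(want)
    return idx is not None and any(
        idx.any_overlap(e.start, e.end) for e in t.exons)


def _build_stranded_index(intervals) -> dict:
    """chrom -> {'any': IntervalSet, '+': ..., '-': ...}."""
    out: dict = {}
    by: dict = {}
    for iv in intervals:
        entry = by.setdefault(iv.chrom, {"any": [], "+": [], "-": []})
        entry["any"].append((iv.start, iv.end))
        if iv.strand in ("+", "-"):
            entry[iv.strand].append((iv.start, iv.end))
    from .genomic_core import IntervalSet
    for chrom, groups in by.items():
        out[chrom] = {k: IntervalSet(v) for k, v in groups.items() if v}
    return out


def filter_catalog(catalog: Catalog, expr: ExpressionMatrix | None,
                   params: FilterParams, annotation_sets: dict) -> tuple:
    """Apply the filter cascade; returns (filtered Catalog, FilterReport).

    ``annotation_sets`` maps names from KNOWN_ANNOTATION_SETS to Interval
    lists; unknown names raise.  Transcripts absent from ``expr`` are
    treated as 0 FPKM (logged).
    """
    unknown = set(annotation_sets) - set(KNOWN_ANNOTATION_SETS)
    if unknown:
        raise ValueError(f"unknown annotation set names: {sorted(unknown)}")
    protein = _build_stranded_index(annotation_sets.get("protein_exons", []))
    smallrna = _build_stranded_index(annotation_sets.get("smallrna", []))
    pseudo = _build_stranded_index(annotation_sets.get("pseudogenes", []))

    report = FilterReport()
    survivors = list(catalog)

    def run_stage(name, keep_fn):
        nonlocal survivors
        n_in = len(survivors)
        survivors = [t for t in survivors if keep_fn(t)]
        report.add(name, n_in, [t.transcript_id for t in survivors])

    wl = params.whitelist

    run_stage("structure", lambda t:
              t.n_exons >= params.min_exons
              and _tx_length(t, params.length_space) > params.min_length)

    missing = [t.transcript_id for t in survivors
               if expr is not None and t.transcript_id not in expr.fpkm.index]
    if missing:
        logger.warning("%d transcripts missing from expression table; "
                       "treated as 0 FPKM", len(missing))

    def max_fpkm(t):
        if t.transcript_id not in expr.fpkm.index:
            return 0.0
        return float(expr.fpkm.loc[t.transcript_id].max())

    if expr is None:
        logger.warning("no expression table supplied; expression stage "
                       "passes all transcripts")
    run_stage("expression", lambda t:
              expr is None or t.transcript_id in wl
              or max_fpkm(t) > params.min_fpkm_any)

    def noncoding(t):
        if t.transcript_id in wl:
            return True
        score = t.scores.get(params.phylocsf_score_name, -math.inf)
        if score > params.phylocsf_max:
            return False
        return not _exonic_overlap(t, protein, strand="sense")

    run_stage("coding_potential", noncoding)
    run_stage("annotation_overlap", lambda t: not _exonic_overlap(t, smallrna))

    def keep_final(t):
        if params.antisense_protein_exclusion and \
                _exonic_overlap(t, protein, strand="antisense"):
            return False
        return not _exonic_overlap(t, pseudo)

    run_stage("antisense_pseudogene", keep_final)
    report.validate_telescoping()
    return Catalog(survivors), report


def select_primary_isoform(gene_transcripts, expr: ExpressionMatrix,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT) -> str:
    """The isoform with the greatest FPKM geometric mean across samples.

    The geometric mean is pseudocounted (exp(mean(log(v + c))) - c); exact
    ties break to the lexicographically smaller transcript_id (logged).
    """
    from .expression_analysis import geometric_mean_expr

    ids = sorted(t.transcript_id if isinstance(t, Transcript) else t
                 for t in gene_transcripts)
    if not ids:
        raise ValueError("gene has no isoforms")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    best_id, best_g = None, -math.inf
    tied = False
    for tid in ids:
        v = (expr.fpkm.loc[tid].to_numpy(dtype=float)
             if tid in expr.fpkm.index else np.zeros(len(expr.samples)))
        g = geometric_mean_expr(v, pseudocount)
        if math.isclose(g, best_g, rel_tol=0, abs_tol=1e-12):
            tied = True
        elif g > best_g:
            best_id, best_g, tied = tid, g, False
    if tied:
        logger.info("primary-isoform tie at gene of %s: lexicographic break",
                    best_id)
    return best_id


def collapse_to_primary(catalog: Catalog, expr: ExpressionMatrix,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> Catalog:
    """One primary isoform per gene locus."""
    keep = [select_primary_isoform(tids, expr, pseudocount)
            for tids in catalog.grouping.values()]
    return catalog.subset(keep)
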