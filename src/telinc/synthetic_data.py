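"""Synthetic genomes, TE annotations, catalogs, expression and ChIP data
with known planted parameters.

The generator emulates the statistical structure the pipeline is built to
measure: multi-chromosome genomes carrying TE elements of several named
families at configurable densities; multi-exon transcripts, a subset with
an LTR-like element planted across the TSS with a sense-strand bias; an
exonically enriched TE family at a target enrichment fold; a log-normal
FPKM matrix with one cell-type-specific planted class; a conservation
track scoring TE bases low and TE-devoid transcripts high; and ChIP reads
concentrated on the planted elements in the treatment condition only.
Every planted quantity is recorded in SimTruth from the realized
simulation, so each pipeline stage has a recovery test with ground truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import (
    Catalog,
    GenomeLayout,
    Interval,
    IntervalSet,
    TEAnnotation,
    Transcript,
    build_family_index,
    build_index,
    merge_pairs,
    write_bed_intervals,
    write_bedgraph,
    write_chrom_sizes,
    write_gtf,
    write_te_bed,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TEFamilySim:
    """One simulated TE family.

    ``density`` is the target genome fraction covered by uniformly placed
    background elements.  ``tss_window``/``n_tss_genes``/``sense_bias``
    plant one element per selected gene spanning the stated strand-oriented
    window around its TSS, on the sense strand with probability
    ``sense_bias``.  ``enrich_fold`` plants additional exonic copies sized
    so the expected shuffle-test enrichment equals the fold.
    """

    name: str
    te_class: str = "Other"
    density: float = 0.01
    mean_length: int = 300
    length_sigma: float = 0.3
    sense_bias: float = 0.5
    tss_window: tuple | None = None   # (upstream, downstream) e.g. (-400, 100)
    n_tss_genes: int = 0
    enrich_fold: float | None = None


@dataclass
class ExpressionSim:
    """Log-normal FPKM baseline with one planted cell-type-specific class.

    Per-gene level = exp(N(log_mean, gene_sigma)); per-sample noise
    multiplies by exp(N(0, sample_sigma)).  The planted class (by default
    the genes carrying the planted TSS element) is multiplied by
    ``planted_fold`` in ``planted_sample`` only.
    """

    samples: tuple = ("ESC", "iPSC", "brain", "liver", "testis", "fibroblast")
    log_mean: float = math.log(3.0)
    gene_sigma: float = 0.5
    sample_sigma: float = 0.3
    planted_fold: float = 4.0
    planted_sample: str = "ESC"
    planted_fraction: float | None = None  # None -> use the TSS-planted genes


@dataclass
class ChipSim:
    """Treatment reads enriched at planted elements; control uniform.

    ``fold`` is the target binomial-test enrichment of treatment reads in
    the ``target_family`` elements.  ``read_shift`` moves targeted read
    midpoints downstream (transcription direction) of the element span,
    emulating signal over the element body/interior.
    """

    n_treatment: int = 20000
    n_control: int = 20000
    read_length: int = 100
    target_family: str = "LTR7"
    fold: float = 5.0
    read_shift: int = 0
    peak_cover_fraction: float = 0.8
    peak_pad: int = 100
    n_background_peaks: int = 50
    background_peak_length: int = 400


@dataclass
class ConservationSim:
    """Beta parameters for per-base scores of the three base classes."""

    dte: tuple = (8.0, 2.0)      # TE-devoid transcripts: high conservation
    te: tuple = (1.0, 9.0)       # TE-derived bases: near zero
    non_te: tuple = (2.0, 8.0)   # remaining bases of TE-transcripts


def default_families() -> list:
    return [
        TEFamilySim("L1", "LINE", density=0.06, mean_length=900),
        TEFamilySim("Alu", "SINE", density=0.05, mean_length=300),
        TEFamilySim("MIR", "SINE", density=0.02, mean_length=180),
        TEFamilySim("ERVL", "LTR", density=0.01, mean_length=500),
        TEFamilySim("ERV1", "LTR", density=0.006, mean_length=450,
                    enrich_fold=3.0),
        TEFamilySim("LTR7", "LTR", density=0.002, mean_length=450,
                    sense_bias=0.9, tss_window=(-400, 100), n_tss_genes=50),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 250_000
    gap_length: int = 5_000
    n_genes: int = 500
    exon_mean_length: int = 140
    exon_length_sigma: float = 0.35
    intron_mean_length: int = 250
    intron_length_sigma: float = 0.5
    extra_exons_lambda: float = 1.2  # exons per gene = 2 + Poisson(lambda)
    min_intergenic: int = 500        # gene loci never closer than this
    families: list = field(default_factory=default_families)
    expression: ExpressionSim = field(default_factory=ExpressionSim)
    chip: ChipSim = field(default_factory=ChipSim)
    conservation: ConservationSim = field(default_factory=ConservationSim)

    def validate(self):
        total_density = sum(f.density for f in self.families)
        if total_density > 0.9:
            raise ValueError(
                f"infeasible TE density {total_density:.2f} > 0.9")
        if any(f.enrich_fold is not None and f.enrich_fold <= 0
               for f in self.families):
            raise ValueError("enrichment folds must be > 0")
        if self.chip.fold <= 0 or self.expression.planted_fold <= 0:
            raise ValueError("planted folds must be > 0")


@dataclass
class SimTruth:
    """Ground truth recorded from the realized simulation."""

    family_density: dict = field(default_factory=dict)
    family_sense_fraction: dict = field(default_factory=dict)
    tss_gene_ids: list = field(default_factory=list)
    tss_family: str | None = None
    tss_window: tuple | None = None
    planted_elements: list = field(default_factory=list)  # (chrom, start, end, strand)
    enrich_family: str | None = None
    enrich_fold: float | None = None
    expr_planted_ids: list = field(default_factory=list)
    expr_planted_sample: str | None = None
    expr_planted_fold: float | None = None
    chip_family: str | None = None
    chip_fold: float | None = None
    peak_cover_fraction: float | None = None


@dataclass
class SimData:
    config: SimConfig
    genome: GenomeLayout
    tes: list
    catalog: Catalog
    expression: "object"   # ExpressionMatrix
    track: dict
    treatment: "object"    # ReadSet
    control: "object"
    peaks: list
    truth: SimTruth


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _uniform_placement(rng, length, span, excluded, retry_cap=1000):
    for _ in range(retry_cap):
        start = int(rng.integers(0, length - span + 1))
        if all(start >= e or start + span <= s for s, e in excluded):
            return start
    raise ValueError("no admissible placement found")


def _gene_structure(cfg: SimConfig, rng):
    """(exon_lengths, intron_lengths) for one gene."""
    n_exons = 2 + int(rng.poisson(cfg.extra_exons_lambda))
    exon_lens = np.maximum(
        30, rng.lognormal(math.log(cfg.exon_mean_length),
                          cfg.exon_length_sigma, n_exons).astype(int))
    intron_lens = np.maximum(
        60, rng.lognormal(math.log(cfg.intron_mean_length),
                          cfg.intron_length_sigma, n_exons - 1).astype(int))
    return exon_lens, intron_lens


def _make_genes_and_genome(cfg: SimConfig, rng):
    """Lay out non-overlapping gene loci along each chromosome.

    Gene loci (and one assembly gap per chromosome, which becomes the
    excluded region) are separated by at least ``min_intergenic`` bp, with
    the remaining free space split randomly among the interstices.
    Transcripts are intergenic by construction, so planted TSS-proximal
    elements belong to exactly one host gene.
    """
    names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    lengths = {c: cfg.chrom_length for c in names}
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    transcripts, excluded = [], {}
    gene_counter = 0
    for chrom, n in zip(names, per_chrom):
        structures = None
        for _ in range(100):
            cand = [_gene_structure(cfg, rng) for _ in range(n)]
            total_span = sum(int(e.sum() + i.sum()) for e, i in cand)
            n_items = n + (1 if cfg.gap_length > 0 else 0)
            budget = (cfg.chrom_length - total_span - cfg.gap_length
                      - (n_items + 1) * cfg.min_intergenic)
            if budget >= 0:
                structures = cand
                break
        if structures is None:
            raise ValueError(
                f"cannot fit {n} gene loci on a {cfg.chrom_length} bp "
                f"chromosome with min_intergenic={cfg.min_intergenic}")
        extra = rng.multinomial(budget, np.full(n_items + 1, 1.0 / (n_items + 1)))
        gap_slot = int(rng.integers(n_items)) if cfg.gap_length > 0 else -1
        items = list(range(n))
        if gap_slot >= 0:
            items.insert(gap_slot, "gap")
        pos = 0
        for slot, item in enumerate(items):
            pos += cfg.min_intergenic + int(extra[slot])
            if item == "gap":
                excluded[chrom] = [(pos, pos + cfg.gap_length)]
                pos += cfg.gap_length
                continue
            exon_lens, intron_lens = structures[item]
            strand = "+" if rng.random() < 0.5 else "-"
            exons, p = [], pos
            for j, el in enumerate(exon_lens):
                exons.append(Interval(chrom, p, p + int(el), strand))
                p += int(el)
                if j < len(intron_lens):
                    p += int(intron_lens[j])
            gid = f"g{gene_counter:04d}"
            transcripts.append(Transcript(f"{gid}.t1", gid, exons))
            gene_counter += 1
            pos = p
    genome = GenomeLayout(names, lengths, excluded)
    return Catalog(transcripts), genome


def _element_length(fam: TEFamilySim, rng) -> int:
    return max(20, int(rng.lognormal(math.log(fam.mean_length),
                                     fam.length_sigma)))


def _place_background(fam: TEFamilySim, genome: GenomeLayout, rng) -> list:
    target_bp = fam.density * genome.total_size
    elements, placed = [], 0
    counter = 0
    lengths = np.array([genome.chrom_lengths[c] for c in genome.chrom_names],
                       dtype=float)
    cumw = np.cumsum(lengths / lengths.sum())
    while placed < target_bp:
        chrom = genome.chrom_names[int(np.searchsorted(cumw, rng.random()))]
        span = _element_length(fam, rng)
        span = min(span, genome.chrom_lengths[chrom] - 1)
        start = _uniform_placement(rng, genome.chrom_lengths[chrom], span,
                                   genome.excluded_pairs(chrom))
        strand = "+" if rng.random() < 0.5 else "-"
        elements.append(TEAnnotation(
            Interval(chrom, start, start + span, strand), fam.name,
            f"{fam.name}_elt", fam.te_class,
            perc_div=float(np.clip(rng.normal(15, 5), 0.5, 40)),
        ))
        placed += span
        counter += 1
        if counter > 10_000_000:  # pragma: no cover - safety valve
            raise RuntimeError("TE placement did not converge")
    return elements


def _plant_tss_elements(fam: TEFamilySim, catalog: Catalog, genome, rng):
    """One element per selected gene spanning fam.tss_window around the TSS."""
    up, down = fam.tss_window
    order = rng.permutation(len(catalog.transcripts))
    chosen = [catalog.transcripts[i] for i in order[:fam.n_tss_genes]]
    elements, hosts, n_sense = [], [], 0
    for t in chosen:
        if t.strand == "+":
            s, e = t.tss + up, t.tss + down
        else:
            s, e = t.tss - down, t.tss - up
        s = max(0, s)
        e = min(genome.chrom_lengths[t.chrom], e)
        sense = rng.random() < fam.sense_bias
        strand = t.strand if sense else ("-" if t.strand == "+" else "+")
        n_sense += sense
        elements.append(TEAnnotation(
            Interval(t.chrom, s, e, strand), fam.name, f"{fam.name}_elt",
            fam.te_class, perc_div=float(np.clip(rng.normal(12, 4), 0.5, 40)),
        ))
        hosts.append(t.gene_id)
    sense_fraction = n_sense / len(chosen) if chosen else float("nan")
    return elements, hosts, sense_fraction


def _plant_enrichment(fam: TEFamilySim, catalog: Catalog,
                      genome: GenomeLayout, baseline_bp: float, rng) -> list:
    """Plant exonic copies so the expected shuffle-null fold equals
    fam.enrich_fold.

    With exonic genome fraction rho = E/G, baseline family bp B placed
    uniformly, and planted exonic bp P, the expected observed exonic
    overlap is B*rho + P while the shuffle null expects (B + P)*rho, so
    P = B*rho*(f - 1) / (1 - f*rho).  f*rho must stay < 1.
    """
    exon_pairs: dict = {}
    for t in catalog:
        exon_pairs.setdefault(t.chrom, []).extend(
            (e.start, e.end) for e in t.exons)
    exonic_bp = sum(sum(e - s for s, e in merge_pairs(p))
                    for p in exon_pairs.values())
    rho = exonic_bp / genome.total_size
    f = fam.enrich_fold
    if f * rho >= 1.0:
        raise ValueError(
            f"cannot plant fold {f} with exonic genome fraction {rho:.2f}")
    target_bp = baseline_bp * rho * (f - 1.0) / (1.0 - f * rho)
    transcripts = list(catalog)
    weights = np.array([t.mature_length for t in transcripts], dtype=float)
    weights /= weights.sum()
    elements, placed = [], 0.0
    while placed < target_bp:
        t = transcripts[int(rng.choice(len(transcripts), p=weights))]
        exon = t.exons[int(rng.integers(t.n_exons))]
        span = min(_element_length(fam, rng), len(exon))
        start = exon.start + int(rng.integers(0, len(exon) - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        elements.append(TEAnnotation(
            Interval(t.chrom, start, start + span, strand), fam.name,
            f"{fam.name}_elt", fam.te_class,
            perc_div=float(np.clip(rng.normal(15, 5), 0.5, 40)),
        ))
        placed += span
    return elements


def _make_expression(cfg: SimConfig, catalog: Catalog, planted_ids, rng):
    from .expression_analysis import ExpressionMatrix

    ex = cfg.expression
    genes = sorted({t.gene_id for t in catalog})
    base = rng.lognormal(ex.log_mean, ex.gene_sigma, len(genes))
    fpkm = base[:, None] * rng.lognormal(
        0.0, ex.sample_sigma, (len(genes), len(ex.samples)))
    df = pd.DataFrame(fpkm, index=genes, columns=list(ex.samples))
    planted = set(planted_ids)
    if planted:
        mask = df.index.isin(planted)
        df.loc[mask, ex.planted_sample] *= ex.planted_fold
    return ExpressionMatrix(df.round(6))


def _make_track(cfg: SimConfig, catalog: Catalog, tes, rng) -> dict:
    """Per-base conservation scores over exonic bases (sparse bedGraph-style)."""
    cons = cfg.conservation
    te_index = build_index(te.interval for te in tes)
    by_chrom: dict = {}
    for t in catalog:
        bases = np.concatenate([np.arange(e.start, e.end) for e in t.exons])
        idx = te_index.get(t.chrom)
        in_te = idx.covers(bases) if idx is not None else np.zeros(len(bases), bool)
        if in_te.any():
            a_te, b_te = cons.te
            a_nt, b_nt = cons.non_te
            scores = np.where(in_te,
                              rng.beta(a_te, b_te, len(bases)),
                              rng.beta(a_nt, b_nt, len(bases)))
        else:
            a, b = cons.dte
            scores = rng.beta(a, b, len(bases))
        pos, val = by_chrom.setdefault(t.chrom, ([], []))
        pos.append(bases)
        val.append(scores)
    track = {}
    for chrom, (pos, val) in by_chrom.items():
        pos = np.concatenate(pos)
        val = np.concatenate(val)
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        keep = np.concatenate([[True], np.diff(pos) > 0])  # first wins on overlap
        track[chrom] = (pos[keep], np.round(val[keep], 4))
    return track


def _make_chip(cfg: SimConfig, genome: GenomeLayout, tes, planted, rng):
    """Treatment reads enriched at the target family; control uniform.

    The targeting probability q is solved so the expected binomial-test
    fold equals cfg.chip.fold: k/n = q*h + (1-q)*p0 with h the chance a
    targeted read midpoint lands inside a family element (1 when
    read_shift = 0), hence q = p0*(f - h0...)/..., here solved for h = 1
    case and computed exactly for shifted reads by geometry sampling.
    """
    from .chipseq_enrichment import ReadSet

    chip = cfg.chip
    fam_index = build_family_index(tes).get(chip.target_family, {})
    family_bp = sum(idx.total_bp for idx in fam_index.values())
    p0 = family_bp / genome.alignable_size
    if not planted or family_bp == 0:
        q, expected_fold = 0.0, None
    else:
        if chip.read_shift == 0:
            h = 1.0
        else:
            # fraction of the shifted span still inside the element, averaged
            h = float(np.mean([
                max(0.0, (len(el.interval) - abs(chip.read_shift)))
                / len(el.interval) for el, _ in planted]))
        if h <= p0:
            raise ValueError("read_shift leaves no excess mass on elements")
        q = float(np.clip(p0 * (chip.fold - 1.0) / (h - p0), 0.0, 1.0))
        expected_fold = (q * h + (1 - q) * p0) / p0

    chrom_names = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in chrom_names],
                       dtype=float)
    cumw = np.cumsum(lengths / lengths.sum())
    excluded = {c: genome.excluded_pairs(c) for c in chrom_names}

    def uniform_midpoints(n):
        """n (chrom_idx, midpoint) pairs uniform on the alignable genome."""
        ci = np.searchsorted(cumw, rng.random(n))
        mid = (rng.random(n) * lengths[ci]).astype(np.int64)
        for _ in range(100):
            bad = np.zeros(n, dtype=bool)
            for k, c in enumerate(chrom_names):
                for s, e in excluded[c]:
                    bad |= (ci == k) & (mid >= s) & (mid < e)
            if not bad.any():
                return ci, mid
            nb = int(bad.sum())
            ci[bad] = np.searchsorted(cumw, rng.random(nb))
            mid[bad] = (rng.random(nb) * lengths[ci[bad]]).astype(np.int64)
        raise RuntimeError("midpoint rejection did not converge")

    half = chip.read_length // 2

    def make_read(chrom, mid):
        s = max(0, mid - half)
        e = min(genome.chrom_lengths[chrom], mid + half)
        return Interval(chrom, s, max(e, s + 1), ".")

    n = chip.n_treatment
    targeted = rng.random(n) < q
    n_t = int(targeted.sum())
    el_idx = (rng.integers(0, len(planted), n_t) if planted
              else np.zeros(0, dtype=np.int64))
    el_start = np.array([planted[i][0].interval.start for i in range(len(planted))])
    el_end = np.array([planted[i][0].interval.end for i in range(len(planted))])
    el_chrom = [planted[i][0].interval.chrom for i in range(len(planted))]
    el_dir = np.array([1 if planted[i][1].strand == "+" else -1
                       for i in range(len(planted))])
    t_mid = el_start[el_idx] + (
        rng.random(n_t) * (el_end[el_idx] - el_start[el_idx])).astype(np.int64)
    if chip.read_shift:
        t_mid = t_mid + el_dir[el_idx] * chip.read_shift
    u_ci, u_mid = uniform_midpoints(n - n_t)

    treatment, ti, ui = [], 0, 0
    for flag in targeted:
        if flag:
            chrom = el_chrom[el_idx[ti]]
            m = int(np.clip(t_mid[ti], 0, genome.chrom_lengths[chrom] - 1))
            treatment.append(make_read(chrom, m))
            ti += 1
        else:
            treatment.append(make_read(chrom_names[u_ci[ui]], int(u_mid[ui])))
            ui += 1
    c_ci, c_mid = uniform_midpoints(chip.n_control)
    control = [make_read(chrom_names[ci_], int(m_))
               for ci_, m_ in zip(c_ci, c_mid)]

    peaks, covered = [], 0
    for el, _host in planted:
        if rng.random() < chip.peak_cover_fraction:
            iv = el.interval
            peaks.append(Interval(
                iv.chrom, max(0, iv.start - chip.peak_pad),
                min(genome.chrom_lengths[iv.chrom], iv.end + chip.peak_pad)))
            covered += 1
    p_ci, p_mid = uniform_midpoints(chip.n_background_peaks)
    for ci_, m_ in zip(p_ci, p_mid):
        chrom, m = chrom_names[ci_], int(m_)
        bh = chip.background_peak_length // 2
        peaks.append(Interval(chrom, max(0, m - bh),
                              min(genome.chrom_lengths[chrom], m + bh)))
    realized_cover = covered / len(planted) if planted else None
    return (ReadSet(treatment, "treatment"), ReadSet(control, "control"),
            peaks, expected_fold, realized_cover)


def simulate(config: SimConfig | None = None,
             seed: int | None = None) -> SimData:
    """Generate a full synthetic dataset; deterministic given the seed."""
    cfg = config if config is not None else SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = SimTruth()

    catalog, genome = _make_genes_and_genome(cfg, rng)

    tes: list = []
    planted_pairs: list = []   # (TEAnnotation, host Transcript)
    for fam in cfg.families:
        background = _place_background(fam, genome, rng) if fam.density > 0 else []
        tes.extend(background)
        if fam.tss_window is not None and fam.n_tss_genes > 0:
            elements, hosts, sense_frac = _plant_tss_elements(
                fam, catalog, genome, rng)
            tes.extend(elements)
            host_tx = {t.gene_id: t for t in catalog}
            planted_pairs.extend(
                (el, host_tx[g]) for el, g in zip(elements, hosts))
            truth.tss_gene_ids = sorted(hosts)
            truth.tss_family = fam.name
            truth.tss_window = fam.tss_window
            truth.family_sense_fraction[fam.name] = sense_frac
            truth.planted_elements = [
                (el.interval.chrom, el.interval.start, el.interval.end,
                 el.interval.strand) for el in elements]
        if fam.enrich_fold is not None:
            baseline_bp = float(sum(len(te.interval) for te in background))
            tes.extend(_plant_enrichment(fam, catalog, genome, baseline_bp, rng))
            truth.enrich_family = fam.name
            truth.enrich_fold = fam.enrich_fold

    fam_index = build_family_index(tes)
    for name, by_chrom in fam_index.items():
        bp = sum(idx.total_bp for idx in by_chrom.values())
        truth.family_density[name] = bp / genome.total_size

    ex = cfg.expression
    if ex.planted_fraction is not None:
        genes = sorted({t.gene_id for t in catalog})
        n = int(round(ex.planted_fraction * len(genes)))
        idx = rng.permutation(len(genes))[:n]
        planted_expr = sorted(genes[i] for i in idx)
    else:
        planted_expr = list(truth.tss_gene_ids)
    expression = _make_expression(cfg, catalog, planted_expr, rng)
    truth.expr_planted_ids = planted_expr
    truth.expr_planted_sample = ex.planted_sample
    truth.expr_planted_fold = ex.planted_fold

    track = _make_track(cfg, catalog, tes, rng)

    treatment, control, peaks, chip_fold, peak_cover = _make_chip(
        cfg, genome, tes, planted_pairs, rng)
    truth.chip_family = cfg.chip.target_family
    truth.chip_fold = chip_fold
    truth.peak_cover_fraction = peak_cover

    return SimData(cfg, genome, tes, catalog, expression, track,
                   treatment, control, peaks, truth)


# ---------------------------------------------------------------------------
# File output & helpers
# ---------------------------------------------------------------------------

def write_dataset(sim: SimData, outdir) -> dict:
    """Write the dataset as the plain-text formats the readers consume.

    Returns {name: path}.  Conservation is emitted as bedGraph, TEs as
    BED6+1 (family/element name), reads and peaks as BED.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit(name, text):
        p = outdir / name
        p.write_text(text)
        paths[name] = p

    emit("genome.chrom.sizes", write_chrom_sizes(sim.genome.chrom_lengths))
    gaps = [Interval(c, s, e) for c, ivs in sim.genome.excluded.items()
            for s, e in ivs]
    emit("gaps.bed", write_bed_intervals(gaps))
    emit("tes.bed", write_te_bed(sim.tes))
    emit("catalog.gtf", write_gtf(sim.catalog))
    emit("expression.tsv", sim.expression.to_tsv())
    emit("conservation.bedGraph", write_bedgraph(sim.track))
    emit("chip_treatment.bed", write_bed_intervals(sim.treatment.reads))
    emit("chip_control.bed", write_bed_intervals(sim.control.reads))
    emit("peaks.bed", write_bed_intervals(sim.peaks))
    emit("truth.json", json.dumps(asdict(sim.truth), indent=1, default=str))
    rows = ["key\tvalue"]
    flat = asdict(sim.truth)
    for k, v in flat.items():
        rows.append(f"{k}\t{json.dumps(v, default=str)}")
    emit("truth.tsv", "\n".join(rows) + "\n")
    return paths


def length_matched_subsample(class_a, class_b, lengths: dict,
                             rng: np.random.Generator | None = None,
                             min_p: float = 0.1) -> tuple:
    """Greedy nearest-length pairing of two gene classes without replacement.

    Returns (subset_a, subset_b) whose length distributions are
    indistinguishable by rank-sum test (p > ``min_p``); raises when the
    classes are too disjoint in length to match.
    """
    from .expression_analysis import rank_sum_test

    class_a, class_b = list(class_a), list(class_b)
    if not class_a or not class_b:
        raise ValueError("both classes must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    la = np.array([lengths[g] for g in class_a], dtype=float)
    lb = np.array([lengths[g] for g in class_b], dtype=float)
    order_b = np.argsort(lb)
    sorted_lb = lb[order_b]
    used = np.zeros(len(class_b), dtype=bool)
    pairs = []
    for i in np.argsort(la):
        j = int(np.searchsorted(sorted_lb, la[i]))
        left, right = j - 1, j
        while left >= 0 and used[left]:
            left -= 1
        while right < len(sorted_lb) and used[right]:
            right += 1
        cand = [k for k in (left, right) if 0 <= k < len(sorted_lb)]
        if not cand:
            continue
        best = min(cand, key=lambda k: abs(sorted_lb[k] - la[i]))
        used[best] = True
        pairs.append((i, order_b[best]))
    if not pairs:
        raise ValueError("no length-matched pairs found")
    sub_a = [class_a[i] for i, _ in pairs]
    sub_b = [class_b[j] for _, j in pairs]
    _, p = rank_sum_test([lengths[g] for g in sub_a],
                         [lengths[g] for g in sub_b])
    if p <= min_p:
        raise ValueError(
            f"classes too disjoint in length to match (rank-sum p = {p:.3g})")
    return sub_a, sub_b
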