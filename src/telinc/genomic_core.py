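"""Coordinate conventions, interval algebra, and file I/O for the pipeline.

All internal coordinates are 0-based half-open on the forward genome strand.
GTF (1-based inclusive) and RepeatMasker ``.out`` (1-based inclusive) are
converted at the parsing boundary; writers convert back.  The transcription
start site (TSS) of a minus-strand transcript is its maximal genomic
coordinate, and all upstream/downstream logic elsewhere in the package is
strand-flipped accordingly.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: RepeatMasker repeat classes that are not transposable elements and are
#: removed when building the TE catalog (non-coding RNA, satellite, low
#: complexity and simple repeats).
NON_TE_CLASSES = frozenset(
    {"Satellite", "Low_complexity", "Simple_repeat", "RNA", "rRNA", "tRNA",
     "snRNA", "scRNA", "srpRNA", "ncRNA", "Unknown?"}
)

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Other")

#: Family name -> TE class, for inputs (BED) that carry only the family.
FAMILY_TO_CLASS = {
    "L1": "LINE", "L2": "LINE", "CR1": "LINE", "RTE": "LINE", "L1PA": "LINE",
    "Alu": "SINE", "MIR": "SINE", "B2": "SINE", "B4": "SINE", "ID": "SINE",
    "ERV1": "LTR", "ERVK": "LTR", "ERVL": "LTR", "ERVL-MaLR": "LTR",
    "Gypsy": "LTR", "LTR7": "LTR", "HERVH": "LTR",
    "hAT-Charlie": "DNA", "TcMar-Tigger": "DNA", "hAT-Blackjack": "DNA",
    "hAT-Tip100": "DNA", "TcMar-Mariner": "DNA", "MuDR": "DNA",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker element.

    ``family`` is the repeat family (e.g. ``L1``, ``Alu``, ``ERV1``),
    ``element_name`` the subfamily/element (e.g. ``LTR7``, ``AluY``),
    ``te_class`` one of LINE/SINE/LTR/DNA/Other.  ``perc_div`` is percent
    divergence from the RepBase consensus, so nucleotide identity is
    ``100 - perc_div``.  ``consensus_span`` optionally carries
    (begin, end, left) in consensus coordinates for full-length filtering.
    """

    interval: Interval
    family: str
    element_name: str
    te_class: str = "Other"
    perc_div: float = 0.0
    consensus_span: tuple | None = None

    def __post_init__(self):
        if not self.family:
            raise ValueError("TE family must be non-empty")
        if not (0.0 <= self.perc_div <= 100.0):
            raise ValueError(f"perc_div {self.perc_div} outside [0, 100]")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")

    @property
    def identity(self) -> float:
        """Percent nucleotide identity to the family consensus."""
        return 100.0 - self.perc_div


@dataclass
class Transcript:
    """A stranded multi-exon gene model on one chromosome.

    Exons are stored sorted and disjoint.  ``scores`` holds optional
    per-transcript annotations such as a precomputed PhyloCSF score.
    """

    transcript_id: str
    gene_id: str
    exons: list
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        if len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> int:
        """Genomic locus length, introns included."""
        return self.end - self.start

    @property
    def mature_length(self) -> int:
        """Summed exon length (spliced transcript length)."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """TSS coordinate: locus start on '+', locus end on '-'."""
        return self.start if self.strand == "+" else self.end

    @property
    def tss_base(self) -> int:
        """Genomic position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def end3_base(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list:
        return [
            Interval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def offset_to_genomic(self, offsets: np.ndarray, anchor: str = "tss") -> np.ndarray:
        """Map strand-oriented offsets (negative = upstream in transcription
        direction) around ``anchor`` ('tss' or 'end3') to genomic positions."""
        offsets = np.asarray(offsets)
        base = self.tss_base if anchor == "tss" else self.end3_base
        if self.strand == "-":
            return base - offsets
        return base + offsets


@dataclass
class Catalog:
    """A set of transcripts grouped into gene loci."""

    transcripts: list

    def __post_init__(self):
        ids = [t.transcript_id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate transcript ids: {dup[:5]}")
        self._by_id = {t.transcript_id: t for t in self.transcripts}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._by_id[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    @property
    def grouping(self) -> dict:
        """gene_id -> sorted list of transcript_ids."""
        groups: dict = {}
        for t in self.transcripts:
            groups.setdefault(t.gene_id, []).append(t.transcript_id)
        return {g: sorted(ts) for g, ts in groups.items()}

    def subset(self, transcript_ids) -> "Catalog":
        keep = set(transcript_ids)
        return Catalog([t for t in self.transcripts if t.transcript_id in keep])


@dataclass
class GenomeLayout:
    """Chromosome names/lengths and excluded (unalignable) regions.

    ``alignable_size`` is the total genome size minus merged excluded bp,
    the denominator of the ChIP-Seq binomial model and the placement space
    of the shuffling null.
    """

    chrom_names: list
    chrom_lengths: dict
    excluded: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, ivs in self.excluded.items():
            length = self.chrom_lengths[name]
            for s, e in ivs:
                if not (0 <= s < e <= length):
                    raise ValueError(
                        f"excluded interval [{s}, {e}) outside {name}:[0, {length})"
                    )
        if not self.excluded:
            logger.info("no excluded regions supplied; alignable size = genome size")

    @property
    def total_size(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    @property
    def excluded_bp(self) -> int:
        total = 0
        for ivs in self.excluded.values():
            total += sum(e - s for s, e in merge_pairs(ivs))
        return total

    @property
    def alignable_size(self) -> int:
        return self.total_size - self.excluded_bp

    def excluded_pairs(self, chrom: str) -> list:
        return merge_pairs(self.excluded.get(chrom, []))


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_pairs(pairs) -> list:
    """Merge (start, end) pairs into a minimal sorted disjoint cover.

    Abutting intervals are joined (half-open adjacency).
    """
    pairs = sorted(pairs)
    out: list = []
    for s, e in pairs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def merge_intervals(intervals) -> list:
    """Merge a same-chromosome Interval list into a strand-agnostic cover."""
    intervals = list(intervals)
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"merge_intervals: mixed chromosomes {sorted(chroms)}")
    chrom = intervals[0].chrom
    return [Interval(chrom, s, e) for s, e in
            merge_pairs((iv.start, iv.end) for iv in intervals)]


def overlap_bp_pairs(a_pairs, b_pairs) -> int:
    """Overlap bp between two merged (start, end) pair lists (one chrom)."""
    total = 0
    i = j = 0
    a_pairs, b_pairs = list(a_pairs), list(b_pairs)
    while i < len(a_pairs) and j < len(b_pairs):
        lo = max(a_pairs[i][0], b_pairs[j][0])
        hi = min(a_pairs[i][1], b_pairs[j][1])
        if lo < hi:
            total += hi - lo
        if a_pairs[i][1] < b_pairs[j][1]:
            i += 1
        else:
            j += 1
    return total


def overlap_bp(a_intervals, b_intervals) -> int:
    """Total overlap bp between two interval lists (grouped by chromosome).

    Inputs need not be pre-merged; they are merged per chromosome first, so
    the result never double-counts bases.
    """
    by_chrom_a: dict = {}
    by_chrom_b: dict = {}
    for iv in a_intervals:
        by_chrom_a.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for iv in b_intervals:
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for chrom in by_chrom_a.keys() & by_chrom_b.keys():
        total += overlap_bp_pairs(
            merge_pairs(by_chrom_a[chrom]), merge_pairs(by_chrom_b[chrom])
        )
    return total


class IntervalSet:
    """Merged interval index on one chromosome with O(log n) coverage queries.

    Backs every inner loop in the package: exonic TE overlap, meta-profile
    base membership, fractional-bin coverage, and read-midpoint assignment.
    """

    __slots__ = ("starts", "ends", "cum")

    def __init__(self, pairs):
        merged = merge_pairs(pairs)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)
        lengths = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lengths)])

    @classmethod
    def from_intervals(cls, intervals) -> "IntervalSet":
        return cls([(iv.start, iv.end) for iv in intervals])

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_bp(self) -> int:
        return int(self.cum[-1])

    def coverage_to(self, x) -> np.ndarray:
        """Covered bases in (-inf, x); x may be a float array (fractional)."""
        x = np.asarray(x, dtype=np.float64)
        i = np.searchsorted(self.starts, x, side="right")
        full = self.cum[i]
        # subtract the part of interval i-1 at or beyond x
        prev_end = np.where(i > 0, self.ends[np.maximum(i - 1, 0)], 0)
        over = np.clip(prev_end - x, 0, None)
        return np.where(i > 0, full - over, 0.0)

    def overlap_bp(self, start, end) -> float:
        lo, hi = self.coverage_to([start, end])
        return float(hi - lo)

    def overlap_pairs_bp(self, pairs) -> float:
        """Total overlap of this set with a disjoint (start, end) pair list."""
        if not len(self.starts):
            return 0.0
        pairs = np.asarray(list(pairs), dtype=np.float64)
        if pairs.size == 0:
            return 0.0
        cov = self.coverage_to(pairs.ravel()).reshape(-1, 2)
        return float(np.sum(cov[:, 1] - cov[:, 0]))

    def covers(self, positions) -> np.ndarray:
        """Boolean membership for an array of base positions."""
        positions = np.asarray(positions, dtype=np.int64)
        if not len(self.starts):
            return np.zeros(positions.shape, dtype=bool)
        i = np.searchsorted(self.starts, positions, side="right") - 1
        ok = i >= 0
        return ok & (positions < self.ends[np.maximum(i, 0)])

    def any_overlap(self, start, end) -> bool:
        return self.overlap_bp(start, end) > 0


def build_index(intervals) -> dict:
    """Group intervals by chromosome into IntervalSet indexes."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: IntervalSet(p) for c, p in by_chrom.items()}


def build_family_index(tes, key: str = "family") -> dict:
    """family (or element) name -> {chrom -> IntervalSet} over TE intervals."""
    groups: dict = {}
    for te in tes:
        name = te.family if key == "family" else te.element_name
        groups.setdefault(name, []).append(te.interval)
    return {name: build_index(ivs) for name, ivs in groups.items()}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def parse_gtf(text: str) -> Catalog:
    """Parse GTF exon features into a Catalog.

    1-based inclusive GTF coordinates are converted to 0-based half-open.
    Only ``exon`` features are consumed; each must carry ``gene_id`` and
    ``transcript_id`` attributes.
    """
    import gffutils

    # Pre-scan for line-addressable errors; gffutils then does the parsing.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"GTF line {lineno}: expected 9 tab-separated fields")
        if fields[2] != "exon":
            continue
        attrs = fields[8]
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise ValueError(
                f"GTF line {lineno}: exon feature missing gene_id/transcript_id"
            )
    try:
        db = gffutils.create_db(
            text, ":memory:", from_string=True, force=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - delegated parser details
        raise ValueError(f"GTF parse error: {exc}") from exc

    exons_by_tx: dict = {}
    gene_of: dict = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        if tid in gene_of and gene_of[tid] != gid:
            raise ValueError(f"transcript {tid} mapped to multiple genes")
        gene_of[tid] = gid
        exons_by_tx.setdefault(tid, []).append(
            Interval(f.seqid, f.start - 1, f.end, f.strand)
        )

    transcripts = []
    for tid in sorted(exons_by_tx):
        merged_by_strand: dict = {}
        raw = exons_by_tx[tid]
        chroms = {e.chrom for e in raw}
        strands = {e.strand for e in raw}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {tid}: exons on mixed chromosomes/strands")
        strand = raw[0].strand
        exons = [Interval(raw[0].chrom, s, e, strand)
                 for s, e in merge_pairs((e.start, e.end) for e in raw)]
        transcripts.append(Transcript(tid, gene_of[tid], exons))
    return Catalog(transcripts)


def write_gtf(catalog: Catalog, source: str = "telinc") -> str:
    """Serialize a Catalog as canonical GTF exon lines (round-trips parse_gtf)."""
    out = io.StringIO()
    for t in sorted(catalog, key=lambda t: (t.chrom, t.start, t.transcript_id)):
        for e in t.exons:
            out.write(
                f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                f"{t.strand}\t.\tgene_id \"{t.gene_id}\"; "
                f"transcript_id \"{t.transcript_id}\";\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# RepeatMasker / BED
# ---------------------------------------------------------------------------

def _classify(raw_class: str) -> str:
    base = raw_class.rstrip("?")
    if base in ("LINE", "SINE", "LTR", "DNA"):
        return base
    return "Other"


def _family_class(family: str) -> str:
    if family in FAMILY_TO_CLASS:
        return FAMILY_TO_CLASS[family]
    logger.warning("unknown TE family %r: keeping with te_class=Other", family)
    return "Other"


def _is_non_te(raw_class: str) -> bool:
    base = raw_class.rstrip("?")
    return base in NON_TE_CLASSES or base.endswith("RNA")


def parse_repeatmasker_with_report(text: str, mode: str = "out"):
    """Parse RepeatMasker annotations; return (annotations, dropped Counter).

    ``mode='out'`` reads the native space-delimited ``.out`` table (1-based
    inclusive, strand 'C' = minus); ``mode='bed'`` reads BED6+ with the name
    column formatted ``family/element``.  Non-TE repeat classes (satellite,
    low complexity, simple repeats, structural RNAs) are dropped and counted.
    """
    annotations = []
    dropped: Counter = Counter()
    if mode == "out":
        for line in text.splitlines():
            fields = line.split()
            if len(fields) < 11:
                continue
            try:
                int(fields[0].replace("*", ""))
            except ValueError:
                continue  # header lines
            perc_div = float(fields[1])
            chrom = fields[4]
            start, end = int(fields[5]) - 1, int(fields[6])
            strand = "-" if fields[8] in ("C", "-") else "+"
            element = fields[9]
            raw = fields[10]
            if _is_non_te(raw.split("/")[0]):
                dropped[raw] += 1
                continue
            parts = raw.split("/")
            te_class = _classify(parts[0])
            family = parts[1] if len(parts) > 1 else parts[0]
            if te_class == "Other":
                logger.warning("unknown repeat class %r kept as Other", raw)
            consensus = None
            if len(fields) >= 14:
                try:
                    consensus = tuple(
                        int(x.strip("()")) for x in fields[11:14]
                    )
                except ValueError:
                    consensus = None
            annotations.append(TEAnnotation(
                Interval(chrom, start, end, strand), family, element,
                te_class, perc_div, consensus,
            ))
    elif mode == "bed":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED line {lineno}: need >= 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            parts = name.split("/")
            family = parts[0]
            element = parts[1] if len(parts) > 1 else parts[0]
            if _is_non_te(family):
                dropped[name] += 1
                continue
            perc_div = float(fields[6]) if len(fields) > 6 else 0.0
            annotations.append(TEAnnotation(
                Interval(chrom, int(start), int(end), strand),
                family, element, _family_class(family), perc_div,
            ))
    else:
        raise ValueError(f"unknown RepeatMasker mode {mode!r}")
    if dropped:
        logger.info("dropped %d non-TE repeat annotations", sum(dropped.values()))
    return annotations, dropped


def parse_repeatmasker(text: str, mode: str = "out") -> list:
    """Parse RepeatMasker ``.out`` or BED TE annotations (see the _with_report
    variant for the dropped-repeat counter)."""
    return parse_repeatmasker_with_report(text, mode)[0]


def write_te_bed(tes) -> str:
    """Serialize TE annotations as BED6+1 (name = family/element, col 7 = %div)."""
    lines = []
    for te in sorted(tes, key=lambda t: (t.interval.chrom, t.interval.start)):
        iv = te.interval
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.family}/{te.element_name}"
            f"\t0\t{iv.strand}\t{te.perc_div:g}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_bed_intervals(text: str) -> list:
    """Read a BED3+ file into Interval objects (strand from col 6 if present)."""
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
        out.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed_intervals(intervals) -> str:
    lines = [f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}"
             for iv in intervals]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# chrom.sizes / bedGraph / expression
# ---------------------------------------------------------------------------

def read_chrom_sizes(text: str) -> dict:
    sizes = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict) -> str:
    return "".join(f"{c}\t{l}\n" for c, l in sizes.items())


def genome_from_files(chrom_sizes_text: str, gaps_bed_text: str | None = None) -> GenomeLayout:
    sizes = read_chrom_sizes(chrom_sizes_text)
    excluded: dict = {}
    if gaps_bed_text:
        for iv in read_bed_intervals(gaps_bed_text):
            excluded.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return GenomeLayout(list(sizes), sizes, excluded)


def read_bedgraph(text: str) -> dict:
    """Read a bedGraph into a sparse per-base score track:
    chrom -> (positions int64 array, values float64 array), sorted."""
    by_chrom: dict = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, value = line.split()[:4]
        start, end, value = int(start), int(end), float(value)
        pos, val = by_chrom.setdefault(chrom, ([], []))
        pos.extend(range(start, end))
        val.extend([value] * (end - start))
    track = {}
    for chrom, (pos, val) in by_chrom.items():
        pos = np.asarray(pos, dtype=np.int64)
        val = np.asarray(val, dtype=np.float64)
        order = np.argsort(pos, kind="stable")
        track[chrom] = (pos[order], val[order])
    return track


def write_bedgraph(track: dict) -> str:
    """Write a sparse score track as bedGraph, run-length compressing equal
    consecutive scores."""
    out = io.StringIO()
    for chrom in sorted(track):
        pos, val = track[chrom]
        if len(pos) == 0:
            continue
        run_start = 0
        for i in range(1, len(pos) + 1):
            boundary = (
                i == len(pos)
                or pos[i] != pos[i - 1] + 1
                or val[i] != val[i - 1]
            )
            if boundary:
                out.write(
                    f"{chrom}\t{pos[run_start]}\t{pos[i - 1] + 1}\t"
                    f"{val[run_start]:g}\n"
                )
                run_start = i
    return out.getvalue()


def read_expression_table(text: str):
    """Read a gene x sample FPKM TSV into an ExpressionMatrix."""
    from .expression_analysis import ExpressionMatrix

    return ExpressionMatrix.from_tsv(text)
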