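# Methods

`telinc` quantifies how transposable elements (TEs) intersect a catalog of
long intergenic noncoding RNAs (lincRNAs): how much of the transcribed
sequence is TE-derived, which families are over- or under-represented
relative to a positional null, where elements sit relative to transcript
ends and in which orientation, and how TE content stratifies expression,
conservation and ChIP-Seq signal. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Coordinates and inputs

All internal coordinates are 0-based half-open on the forward strand. GTF
(1-based inclusive) and RepeatMasker `.out` (1-based, strand `C` = minus)
are converted at the parse boundary. The TSS of a minus-strand transcript
is its maximal genomic coordinate; every upstream/downstream computation is
strand-flipped. TE annotations carry a family (e.g. `L1`, `Alu`, `ERV1`), a
subfamily/element name (e.g. `LTR7`, `AluY`), a class (LINE/SINE/LTR/DNA/
Other) and percent divergence from the library consensus; consensus
identity is `100 − divergence`. Non-TE repeat classes (satellite, low
complexity, simple repeats, structural RNAs) are dropped when building the
TE catalog, with a counter, never silently per element.

## Catalog filters

The filter cascade reproduces the standard lincRNA definition on an
already-assembled catalog, in five stages: (1) structure — at least 2 exons
and mature (summed-exon) length > 200 bp; (2) expression — > 1 FPKM in at
least one sample; (3) coding potential — removal on sense overlap with a
protein exon or a precomputed PhyloCSF score > 100; (4) overlap with
tRNA/rRNA/small-RNA annotations; (5) removal of transcripts antisense to
protein exons or overlapping pseudogenes. Every rule is a pure predicate,
so the survivor set is independent of stage order; only the report's
attribution of removals depends on it. A whitelist (curated lncRNAs added
back from reference annotation) bypasses stages 2–3 but not stage 5.
"Length" means mature length by default because that is the lncRNA
convention; locus-span mode is a flag. Primary-isoform selection takes, per
gene locus, the isoform with the greatest pseudocounted geometric mean FPKM
(`exp(mean log(FPKM + c)) − c`, c = 0.25), ties broken lexicographically.

## Composition statistics

TE coverage is computed against merged exons by default ("exonic" space),
because the headline quantities are fractions of *transcript sequence*;
locus space (introns included) is one flag away. A transcript "contains" a
TE at ≥ 1 bp exonic overlap — no minimum-overlap threshold. Overlapping
elements of different families each count for family membership, but
per-transcript TE bp uses the merged union, so fractions are invariant to
splitting an element into abutting pieces. Splice-site statistics define the
donor site as the first intronic base past an exon in transcription
direction and the acceptor as the last intronic base before the next exon.

Conservation partitioning splits exonic bases into three disjoint sets —
all bases of TE-devoid transcripts, TE bases of TE-containing transcripts,
and their remaining bases — and reports per-base pooled means (a
per-transcript mean-of-means mode exists behind a flag). Bases missing from
the sparse score track count as 0 by default (`skip` is available); this
mirrors how genome-wide conservation tracks treat unalignable repeat-rich
sequence, which is exactly the sequence class under study.

## The shuffling null

Family enrichment is tested against an empirical positional null:
transcript models are relocated uniformly at random while TE annotations
stay frozen, the statistic (exonic family bp, or transcript count behind a
flag) is recomputed 100 times, a normal distribution is fit to the null
sample (moment fit, SD with n−1), and the two-sided p-value is read from
its CDF; q-values are Benjamini–Hochberg across the families of one
invocation. Placement preserves, per transcript: chromosome, strand, exon
count, exon/intron lengths. Same-chromosome placement keeps
chromosome-scale TE composition as a conditioned-on confounder, the most
conservative simple reading of "shuffle the annotations"; placements are
rejection-sampled against excluded regions (assembly gaps) with a retry cap
of 1000, erroring with the transcript's name rather than biasing the law.
Shuffled transcripts may overlap each other — the null asks where a locus
*could* sit, not for a non-overlapping repacking. With a fixed generator
seed the whole test is bit-reproducible. A degenerate null (SD = 0) yields
p = 1 when the observation equals the null mean and the smallest positive
float otherwise, with a warning.

The two-sided choice reflects that one family set is screened for both
enrichments and depletions. The normal fit makes p-values far below 1/100
an extrapolation of the fitted tail, not an empirical frequency — the
standard trade-off of parameterized permutation tests.

## Position and orientation

Endpoint meta-profiles average a 0/1 per-base family-coverage indicator
over transcripts at strand-oriented offsets (default flank 2000 bp) around
the TSS or 3' end; transcripts whose window runs off the chromosome
contribute only in-bounds offsets (per-offset denominators), which keeps
small genomes usable. Interior profiles tile each locus span with 100 bins
5'→3' and average fractional coverage per bin, with exact fractional bin
boundaries. Orientation tests count (element, transcript) pairs — sense
means equal strands — in three regions: element-contains-TSS-base, a 500 bp
strand-oriented window past the 3' end (sized to capture element peaks a
few hundred bp downstream), or any exonic overlap. The null is an exact
two-sided binomial at 1/2, the two-sided p summing point masses no larger
than the observed one. Unstranded elements are tallied separately, never
mixed in. A full-length element filter accepts elements whose consensus
span covers ≥ 90% of the family consensus, falling back to a length
threshold when consensus coordinates are absent.

## Expression classes and specificity

Class comparisons (e.g. transcripts containing a family vs those devoid of
it) use a two-sided Mann–Whitney rank-sum test per sample: exact by
enumeration of group assignments for combined n ≤ 12 (valid under ties),
otherwise the normal approximation with tie and continuity corrections.
Genes under 0.5 FPKM in the tested sample are excluded from both classes
first — low-level differences are dominated by multi-mapping artifacts, and
exclusion (not flooring) is what "ignoring" them means here. Fold changes
are ratios of pseudocounted geometric means (c = 0.25 throughout, the same
constant used for log display scales). Tissue specificity of a gene is
1 minus the Jensen–Shannon distance (square root of the base-2 JS
divergence) between its pseudocounted, normalized expression profile and
the nearest single-sample indicator profile; the score is 1 exactly for
one-sample expression, 0.4421 for expression split evenly over two of the
samples, and scale-invariant when c → 0.

## ChIP-Seq enrichment

Each single-best-alignment read is a Bernoulli draw whose success
probability is the family's merged bp over the alignable genome (total
minus excluded regions); reads are assigned to elements by their midpoint
base, which avoids double counting at element borders. Both exact binomial
tails are reported (enrichment P(X ≥ k), depletion P(X ≤ k)). Peak/element
co-location (fraction of elements overlapping ≥ 1 peak bp) is tested by
relocating the elements uniformly on their own chromosomes with peaks
frozen — the same null machinery as the transcript shuffle — because a
read- or peak-level null is not derivable from peak calls alone. TSS
coverage profiles subtract control from treatment after scaling each to
reads per million (hence depth-invariant and possibly negative), optionally
restricted to transcripts carrying a named family inside a promoter window
of 2,000 bp upstream to 200 bp downstream of the TSS.

## Synthetic data

The generator emulates the statistical structure the pipeline measures, at
a desk scale of 4 chromosomes × 250 kb, 500 two-or-more-exon genes and 6
samples (full pipeline in seconds on one CPU). Gene loci are laid out
non-overlapping with ≥ 500 bp intergenic spacing — these are intergenic
RNAs — and one 5 kb assembly gap per chromosome becomes the excluded
region. Six TE families ship as defaults: L1 (6% target density, ~900 bp
elements), Alu (5%, ~300 bp), MIR (2%), ERVL (1%), ERV1 (0.6% background
plus exonic copies planted so the expected shuffle-test fold is 3.0), and
an LTR7-like family planted across the window [−400, +100) around the TSS
of 50 genes, sense-stranded with probability 0.9. The enrichment planting
solves `P = B·ρ(f−1)/(1−fρ)` for the extra exonic bp `P` given background
bp `B`, exonic genome fraction `ρ` and target fold `f`.

Expression is log-normal: per-gene level exp(N(log 3, 0.5)) times
per-sample noise exp(N(0, 0.3)); the planted class (by default the 50
TSS-planted genes, mirroring the LTR-at-TSS/stem-cell coupling the pipeline
is designed to detect) is multiplied by 4 in one target sample. The
per-sample noise scale is set below the planted induction so that the
planted sample is reliably each planted gene's maximum — the regime in
which a specificity-recovery check is informative. Conservation scores are
per-base Beta draws: Beta(8,2) over TE-devoid transcripts, Beta(1,9) over
TE bases, Beta(2,8) over the rest. ChIP treatment reads put extra midpoint
mass on the planted elements, with the targeting probability solved so the
expected binomial-test fold equals the configured 5.0; control reads are
uniform over the alignable genome; peaks cover a configured 80% of planted
elements plus random background peaks. Every planted quantity is recorded
in `SimTruth` *as realized* (e.g. the sense fraction actually drawn), not
as requested.

What the synthetic data do not emulate: nucleotide sequence (no reads, no
motifs), TE age structure or nested insertions, transcript isoform
diversity beyond one isoform per gene, expression correlation between
samples, and mappability structure. Passing recovery tests therefore
demonstrates the estimators' correctness and calibration under the stated
generative model, not robustness to alignment artifacts or annotation error
in real data.

## Numerical choices and degenerate inputs

Interval queries run on merged arrays with prefix-sum coverage lookups
(O(log n) per query, exact for fractional bin boundaries); equivalence with
per-base bitmask oracles on genomes ≤ 10 kb is asserted in the test suite.
BH correction delegates to statsmodels, exact binomials and normal tails to
scipy. Ties in primary-isoform selection break lexicographically (logged);
empty classes after the FPKM floor flag the comparison invalid (p = NA)
rather than erroring a whole batch; families absent from the annotation
raise immediately. Problem sizes in the default test/acceptance runs — 100
shuffles for enrichment, 10,000 for the toy exhaustive-null check, 200
families for null calibration — balance the tightness of the stated
tolerances against a few seconds of runtime each.

## Known limitations

- The shuffle null relocates transcripts independently and permits
  overlaps; clustering of real lincRNA loci is not modeled.
- Normal-fit p-values far in the tails extrapolate beyond the 100-shuffle
  empirical support.
- The peak-overlap p-value uses the element-shuffle null and is not
  comparable in magnitude to pipelines that model per-read backgrounds.
- Conservation "treat missing as 0" conflates unalignable and neutral
  sequence; use `skip` mode when the track is genuinely sparse.
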