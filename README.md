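# telinc

**Transposable-element composition of lincRNA catalogs.**

Long intergenic noncoding RNAs (lincRNAs) are unusually rich in
transposable-element (TE) sequence, and specific families — endogenous
retrovirus LTRs above all — sit at their transcription start sites in
biased orientations, plausibly donating the promoters that created the
genes. `telinc` is a library and CLI for quantifying this: it intersects a
transcript catalog (GTF) with RepeatMasker TE annotations and measures

- **composition** — per-transcript and catalog-wide TE coverage fractions,
  the TE/dTE transcript partition, distinct families per transcript, and
  TE overlap at splice donor/acceptor sites;
- **family enrichment** — a shuffling null: transcripts are relocated
  uniformly (TEs frozen), the exonic family bp recomputed over 100
  shuffles, a normal fitted to the null sample, and two-sided p-values
  read from its CDF with Benjamini–Hochberg q-values across families;
- **position and orientation** — strand-aware coverage meta-profiles
  around TSSs and 3' ends, 100-bin interior profiles, and exact two-sided
  binomial tests of sense/antisense orientation against a 50/50 null;
- **expression classes** — Mann–Whitney rank-sum comparisons of FPKM
  between TE-defined gene classes (exact for small samples), geometric-mean
  folds with a 0.25 pseudocount and a 0.5 FPKM floor, and Jensen–Shannon
  tissue-specificity scores;
- **conservation** — per-base score means over the disjoint partition
  {dTE-transcript bases, TE bases, non-TE bases of TE-transcripts};
- **ChIP-Seq enrichment** — exact binomial read enrichment in TE families
  (success probability = family bp / alignable genome), element/peak
  co-location with a shuffle-based p, and control-subtracted,
  per-million-scaled TSS coverage profiles.

A first-class synthetic-data generator (`telinc.synthetic_data`) produces
genomes, TE annotations, catalogs, expression matrices, conservation
tracks and ChIP reads with *planted, recorded* signal — a TE family
enriched at a known fold, an LTR-like family planted across TSSs with a
known sense bias, a cell-type-specific expression class, ChIP reads
concentrated on the planted elements — so every estimator has a recovery
test with ground truth and no downloads.

## Worked example

```bash
telinc --seed 9 simulate --outdir demo          # writes GTF/BED/TSV/bedGraph
telinc --seed 9 enrich --gtf demo/catalog.gtf --te demo/tes.bed \
    --chrom-sizes demo/genome.chrom.sizes --gaps demo/gaps.bed \
    --families ERV1,L1 --shuffles 30 --out -
```

```text
family  observed  null_mean  null_sd  fold   z      p          q          ...
ERV1    11050.0   4151.73    769.70   2.66   8.96   3.18e-19   6.36e-19   enriched
L1      14855.0   14508.77   2234.17  1.02   0.15   8.77e-01   8.77e-01   enriched
```

The dataset planted extra exonic ERV1 copies targeting a 3-fold
enrichment: observed exonic ERV1 bp (11,050) is 2.7× the shuffle-null mean
with q ≈ 6e-19, while the unplanted L1 family sits at fold 1.02, p 0.88 —
exactly the null behavior. The planted LTR7-like sense bias at TSSs is
equally visible:

```bash
telinc orient --gtf demo/catalog.gtf --te demo/tes.bed \
    --families LTR7 --region tss --out -
```

```text
family  region  n_sense  n_antisense  n_unstranded  p             q
LTR7    tss     44       7            0             1.21e-07      1.21e-07
```

44/51 elements sense-oriented (the generator drew a 0.9 sense bias): the
exact binomial test rejects the 50/50 null at p ≈ 1.2e-07. Library use
mirrors the CLI:

```python
from telinc import synthetic_data, enrichment_shuffle
import numpy as np

sim = synthetic_data.simulate(seed=9)
results = enrichment_shuffle.family_enrichment(
    sim.catalog, sim.tes, sim.genome, rng=np.random.default_rng(0))
```

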