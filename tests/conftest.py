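"""Shared fixtures: per-base oracles and the default synthetic dataset."""

import numpy as np
import pytest
from hypothesis import settings

from telinc.genomic_core import Catalog, Interval, TEAnnotation, Transcript
from telinc import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: Seed of the session-wide default synthetic dataset.
SIM_SEED = 1


@pytest.fixture(scope="session")
def sim():
    """Default synthetic dataset with planted signal (seeded, shared)."""
    return sd.simulate(seed=SIM_SEED)


# ---------------------------------------------------------------------------
# Independent per-base oracles (brute force on small genomes)
# ---------------------------------------------------------------------------

def bitmask(pairs, size):
    """Boolean per-base occupancy mask for (start, end) pairs."""
    mask = np.zeros(size, dtype=bool)
    for s, e in pairs:
        mask[s:e] = True
    return mask


def bitmask_merge(pairs, size):
    """Merged (start, end) pairs recovered from a per-base mask."""
    mask = bitmask(pairs, size)
    out, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def bitmask_overlap(a_pairs, b_pairs, size):
    return int((bitmask(a_pairs, size) & bitmask(b_pairs, size)).sum())


def random_pairs(rng, size, n, max_len=None):
    max_len = max_len or max(2, size // 4)
    out = []
    for _ in range(n):
        s = int(rng.integers(0, size - 1))
        e = int(rng.integers(s + 1, min(size, s + max_len) + 1))
        out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Tiny hand-built genome fixtures
# ---------------------------------------------------------------------------

def make_transcript(tid, chrom, exon_pairs, strand="+", gene=None, scores=None):
    exons = [Interval(chrom, s, e, strand) for s, e in exon_pairs]
    return Transcript(tid, gene or tid.split(".")[0], exons, scores or {})


def make_te(chrom, start, end, family="L1", element=None, strand="+",
            te_class="LINE", perc_div=10.0, consensus=None):
    return TEAnnotation(Interval(chrom, start, end, strand), family,
                        element or f"{family}_elt", te_class, perc_div,
                        consensus)


@pytest.fixture
def two_exon_catalog():
    return Catalog([
        make_transcript("t1.1", "chr1", [(100, 200), (300, 400)], "+"),
        make_transcript("t2.1", "chr1", [(800, 900), (950, 1000)], "-"),
    ])
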