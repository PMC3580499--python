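"""Expression comparisons between TE-defined transcript classes.

Pseudocounted geometric means, exact/asymptotic Mann-Whitney rank-sum tests,
class-vs-class fold comparisons with a low-expression floor, and
Jensen-Shannon tissue-specificity scores.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

logger = logging.getLogger(__name__)

#: Pseudocount convention used for all log-scale expression summaries.
DEFAULT_PSEUDOCOUNT = 0.25

#: Genes below this FPKM in a sample are excluded from class comparisons, to
#: ignore expression differences at very low levels (multi-mapping artifacts).
DEFAULT_MIN_FPKM = 0.5

#: Combined sample size at or below which the rank-sum test is exact.
EXACT_RANKSUM_MAX_N = 12


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix (non-negative, no missing cells)."""

    fpkm: pd.DataFrame  # index = gene ids, columns = sample names

    def __post_init__(self):
        if self.fpkm.index.has_duplicates:
            dups = self.fpkm.index[self.fpkm.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.fpkm.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.fpkm.values < 0).any():
            raise ValueError("negative FPKM values")

    @property
    def genes(self) -> list:
        return list(self.fpkm.index)

    @property
    def samples(self) -> list:
        return list(self.fpkm.columns)

    def values_for(self, gene_ids, sample: str) -> np.ndarray:
        return self.fpkm.loc[list(gene_ids), sample].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, text: str) -> "ExpressionMatrix":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        return cls(df.astype(float))

    def to_tsv(self) -> str:
        out = io.StringIO()
        self.fpkm.to_csv(out, sep="\t", index_label="gene_id")
        return out.getvalue()


@dataclass
class ClassComparison:
    """Rank-sum comparison of FPKM between two gene classes in one sample."""

    sample: str
    n_a: int
    n_b: int
    geomean_a: float
    geomean_b: float
    fold: float
    u_statistic: float
    p: float
    q: float = float("nan")
    valid: bool = True


@dataclass
class SpecificityScore:
    """Jensen-Shannon tissue specificity of one gene's expression profile."""

    gene: str
    score: float
    max_sample: str


def geometric_mean_expr(values, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Pseudocounted geometric mean: exp(mean(log(v + c))) - c."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("geometric mean of empty vector")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (values < 0).any():
        raise ValueError("negative expression values")
    return float(np.exp(np.mean(np.log(values + pseudocount))) - pseudocount)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Counts assignments whose U deviates from the null center n_a*n_b/2 at
    least as much as observed; handles ties because enumeration uses the
    actual pooled values.
    """
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    center = n_a * (n - n_a) / 2.0
    dev_obs = abs(u_obs - center)
    hits = total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a (count of (a_i > b_j) pairs, ties half)."""
    greater = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def rank_sum_test(a_values, b_values) -> tuple:
    """Two-sided Mann-Whitney rank-sum test.

    Exact by enumeration when n_a + n_b <= 12 (valid under ties); otherwise
    the normal approximation with tie and continuity corrections.

    Returns
    -------
    (U, p) : U statistic for the first group and the two-sided p-value.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: both groups must be non-empty")
    u = _u_statistic(a, b)
    if a.size + b.size <= EXACT_RANKSUM_MAX_N:
        p = _exact_ranksum_p(a, b, u)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return u, min(p, 1.0)


def class_comparison(expr: ExpressionMatrix, class_a, class_b, sample: str,
                     min_fpkm: float = DEFAULT_MIN_FPKM,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ClassComparison:
    """Compare FPKM of two disjoint gene classes in one sample.

    Genes below ``min_fpkm`` in the sample are excluded from both classes
    before testing.  Fold is the ratio of pseudocounted geometric means.
    """
    class_a, class_b = list(class_a), list(class_b)
    if set(class_a) & set(class_b):
        raise ValueError("classes must be disjoint")
    va = expr.values_for(class_a, sample)
    vb = expr.values_for(class_b, sample)
    va = va[va >= min_fpkm]
    vb = vb[vb >= min_fpkm]
    if va.size == 0 or vb.size == 0:
        logger.warning("class emptied by min_fpkm=%g filter in %s", min_fpkm, sample)
        return ClassComparison(sample, int(va.size), int(vb.size),
                               float("nan"), float("nan"), float("nan"),
                               float("nan"), float("nan"), valid=False)
    ga = geometric_mean_expr(va, pseudocount)
    gb = geometric_mean_expr(vb, pseudocount)
    u, p = rank_sum_test(va, vb)
    fold = (ga + pseudocount) / (gb + pseudocount) if gb <= 0 else ga / gb
    return ClassComparison(sample, int(va.size), int(vb.size), ga, gb,
                           fold, u, p)


def compare_classes(expr: ExpressionMatrix, class_a, class_b, samples=None,
                    min_fpkm: float = DEFAULT_MIN_FPKM,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list:
    """class_comparison across samples, with BH correction over the samples
    of this invocation (invalid comparisons keep q = NaN)."""
    from .enrichment_shuffle import bh_correct

    samples = list(samples) if samples is not None else expr.samples
    results = [class_comparison(expr, class_a, class_b, s, min_fpkm, pseudocount)
               for s in samples]
    valid = [r for r in results if r.valid]
    if valid:
        qs = bh_correct([r.p for r in valid])
        for r, q in zip(valid, qs):
            r.q = float(q)
    return results


def js_specificity(expr_vector, sample_names=None,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   gene: str = "") -> SpecificityScore:
    """Jensen-Shannon tissue specificity of one expression profile.

    The profile is pseudocounted and normalized to a distribution p; the
    score is 1 minus the smallest JS distance (sqrt of the base-2 JS
    divergence) between p and any single-sample indicator profile.  Score 1
    means expression concentrated in one sample; low scores mean broad
    expression.
    """
    v = np.asarray(expr_vector, dtype=float)
    if v.size < 2:
        raise ValueError("specificity needs >= 2 samples")
    if (v < 0).any():
        raise ValueError("negative expression values")
    if pseudocount < 0 or (pseudocount == 0 and v.sum() == 0):
        raise ValueError("all-zero profile with zero pseudocount")
    p = (v + pseudocount) / (v + pseudocount).sum()
    best_d, best_i = math.inf, 0
    for t in range(v.size):
        e = np.zeros(v.size)
        e[t] = 1.0
        d = float(jensenshannon(p, e, base=2))
        if d < best_d:
            best_d, best_i = d, t
    name = sample_names[best_i] if sample_names is not None else str(best_i)
    return SpecificityScore(gene, 1.0 - best_d, name)


def specificity_table(expr: ExpressionMatrix,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """js_specificity for every gene, as a DataFrame (score, max_sample)."""
    rows = []
    for g in expr.genes:
        s = js_specificity(expr.fpkm.loc[g].to_numpy(), expr.samples,
                           pseudocount, gene=g)
        rows.append((g, s.score, s.max_sample))
    return pd.DataFrame(rows, columns=["gene_id", "specificity", "max_sample"]
                        ).set_index("gene_id")
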