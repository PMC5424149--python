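"""Retained vs non-retained intron feature statistics.

Covers the comparisons typically reported alongside IR calls: Welch t-tests
on intron length / GC content / CpG density, the genomic clustering of
IR genes (pairwise same-chromosome distances against randomly drawn gene
pairs), the within-gene adjacency of retained introns (permutation null
preserving per-gene retained counts), and an OLS regression of log gene
expression on IR level with an F-test of the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from irtools.genome_annotation import GeneModel


@dataclass
class FeatureComparison:
    feature: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float | None
    df: float | None
    p: float | None
    extra: dict | None = None


def compare_feature(
    retained: Sequence[float],
    non_retained: Sequence[float],
    feature: str = "",
    equal_var: bool = False,
) -> FeatureComparison:
    """Two-sample t-test (Welch by default; ``equal_var`` for pooled Student)."""
    a = np.asarray(retained, dtype=float)
    b = np.asarray(non_retained, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            raise ValueError("degenerate comparison: both groups constant and identical")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return FeatureComparison(
        feature=feature,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=a.size,
        n_b=b.size,
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
    )


def _same_chrom_pair_distances(genes: Sequence[GeneModel]) -> list[float]:
    out = []
    for g1, g2 in combinations(genes, 2):
        if g1.chrom != g2.chrom:
            continue
        (s1, e1), (s2, e2) = g1.span, g2.span
        gap = max(s2 - e1, s1 - e2, 0)  # edge-to-edge; 0 if overlapping
        out.append(float(gap))
    return out


def gene_distance_stat(
    ir_genes: Sequence[GeneModel],
    all_genes: Sequence[GeneModel],
    n_random_pairs: int = 1000,
    seed: int = 0,
) -> FeatureComparison:
    """Are IR genes closer together than random gene pairs?

    Observed: pairwise edge-to-edge distances between same-chromosome IR-gene
    pairs. Null: distances of ``n_random_pairs`` same-chromosome pairs drawn
    uniformly (each pair without replacement) from ``all_genes``. Welch
    t-test between the two distance sets.
    """
    if len(ir_genes) < 2:
        raise ValueError("need at least 2 IR genes")
    observed = _same_chrom_pair_distances(ir_genes)
    if not observed:
        raise ValueError("no same-chromosome IR gene pair")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    eligible = [c for c, gs in by_chrom.items() if len(gs) >= 2]
    if not eligible:
        raise ValueError("no chromosome with 2+ genes to draw random pairs from")
    weights = np.array([len(by_chrom[c]) for c in eligible], dtype=float)
    weights /= weights.sum()
    null: list[float] = []
    for _ in range(n_random_pairs):
        chrom = eligible[rng.choice(len(eligible), p=weights)]
        i, j = rng.choice(len(by_chrom[chrom]), size=2, replace=False)
        null.extend(_same_chrom_pair_distances([by_chrom[chrom][i], by_chrom[chrom][j]]))
    return compare_feature(observed, null, feature="gene_distance")


def adjacency_stat(
    retained_by_gene: dict[str, set[int]],
    introns_per_gene: dict[str, int],
    n_draws: int = 1000,
    seed: int = 0,
) -> FeatureComparison:
    """Do retained introns cluster adjacently within genes?

    ``retained_by_gene`` maps gene -> retained intron ordinals;
    ``introns_per_gene`` gives each gene's intron count. Observed statistic:
    among all within-gene pairs of retained introns, the fraction that are
    ordinal neighbours. Null: the same number of retained introns per gene
    placed uniformly, resampled ``n_draws`` times. One-sided resampling p
    (null >= observed).
    """
    multi = {g: s for g, s in retained_by_gene.items() if len(s) >= 2}
    if not multi:
        raise ValueError("no gene with 2+ retained introns")

    def frac_adjacent(sets: dict[str, set[int]]) -> float:
        adj = tot = 0
        for s in sets.values():
            for a, b in combinations(sorted(s), 2):
                tot += 1
                adj += b - a == 1
        return adj / tot if tot else float("nan")

    observed = frac_adjacent(multi)
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_draws)
    for d in range(n_draws):
        draw = {
            g: set(rng.choice(introns_per_gene[g], size=len(s), replace=False))
            for g, s in multi.items()
        }
        null_vals[d] = frac_adjacent(draw)
    p = float((np.sum(null_vals >= observed) + 1) / (n_draws + 1))
    return FeatureComparison(
        feature="intron_adjacency",
        mean_a=observed,
        mean_b=float(null_vals.mean()),
        n_a=sum(len(s) for s in multi.values()),
        n_b=n_draws,
        t=None,
        df=None,
        p=p,
        extra={"observed": observed, "null_mean": float(null_vals.mean())},
    )


def ir_expression_regression(
    ir_levels: Sequence[float], expression: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of log expression on IR level: (slope, F, p) via the slope F-test."""
    ir = np.asarray(ir_levels, dtype=float)
    expr = np.asarray(expression, dtype=float)
    if ir.size != expr.size:
        raise ValueError("vectors must be matched per gene")
    if ir.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(expr <= 0):
        raise ValueError("expression must be positive for log transform")
    y = np.log(expr)
    if np.std(y) == 0 or np.std(ir) == 0:
        raise ValueError("degenerate regression: constant variable")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(ir)).fit()
    return float(model.params[1]), float(model.fvalue), float(model.f_pvalue)
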