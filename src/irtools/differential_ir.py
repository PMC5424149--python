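"""Two-sample differential IR testing.

The Audic-Claverie statistic compares two digital counts x, y observed under
normalization totals N1, N2. The posterior probability of observing y in
sample 2 given x in sample 1 is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

i.e. Y|x is negative-binomial with x+1 successes and success probability
N1/(N1+N2). Tail sums are evaluated in log space; the infinite upper tail is
obtained as the complement of the finite lower sum. The two-sided p-value
doubles the smaller tail, capped at 1.

An intron passes the significance filter iff p < 0.05, exonic splice
abundance is above 10 in both samples, and the IR ratio exceeds 0.1 in at
least one. Direction bias across a result set is assessed with an exact
two-sided binomial test (doubled smaller tail) under p0 = 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from irtools.ir_quant import IRQuant

logger = logging.getLogger(__name__)


@dataclass
class ACTestInput:
    x: int
    y: int
    n1: float = 1.0
    n2: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("normalization totals must be positive")


def _log_pmf(x: int, ys: np.ndarray, log_r: float) -> np.ndarray:
    # log p(y|x) with r = N2/N1
    return (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * np.logaddexp(0.0, log_r)
    )


def audic_claverie_tails(x: int, y: int, n1: float = 1.0, n2: float = 1.0) -> tuple[float, float]:
    """(P(Y <= y | x), P(Y >= y | x)) under the posterior for sample 2.

    Computed in log space; the upper tail is 1 minus the finite lower sum
    P(Y <= y-1), so no infinite summation is needed.
    """
    ACTestInput(x, y, n1, n2)
    log_r = math.log(n2) - math.log(n1)
    ys = np.arange(y + 1)
    logs = _log_pmf(x, ys, log_r)
    lower = float(np.exp(logsumexp(logs)))
    lower_excl = float(np.exp(logsumexp(logs[:-1]))) if y > 0 else 0.0
    upper = 1.0 - lower_excl
    return min(lower, 1.0), min(max(upper, 0.0), 1.0)


def audic_claverie_p(x: int, y: int, n1: float = 1.0, n2: float = 1.0) -> float:
    """Two-sided Audic-Claverie p-value: doubled smaller tail, capped at 1.

    Each direction's tail is the inclusive upper tail of the appropriate
    conditional — P(Y >= y | x) for an excess in sample 2 and P(X >= x | y)
    (with totals swapped) for an excess in sample 1 — which makes the
    construction exchangeable: p(x, y, N1, N2) == p(y, x, N2, N1).
    """
    _, up_2 = audic_claverie_tails(x, y, n1, n2)
    _, up_1 = audic_claverie_tails(y, x, n2, n1)
    return min(1.0, 2.0 * min(up_1, up_2))


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


@dataclass
class DifferentialIRResult:
    intron_id: str
    ir_ratio_1: float
    ir_ratio_2: float
    p_value: float
    direction: str  # 'increased' or 'decreased' (sample 2 relative to sample 1)
    fold_change: float
    pass_p: bool
    pass_splice: bool
    pass_ir: bool

    @property
    def passes_filter(self) -> bool:
        return self.pass_p and self.pass_splice and self.pass_ir


def differential_filter(
    q1: IRQuant,
    q2: IRQuant,
    p_value: float | None = None,
    alpha: float = 0.05,
    splice_floor: int = 10,
    ir_floor: float = 0.1,
    epsilon: float = 0.01,
) -> DifferentialIRResult:
    """Apply the three-part significance filter to one intron's pair of
    quantifications.

    When ``p_value`` is not supplied the Audic-Claverie test is run on the
    rounded intronic abundances with per-intron totals (intronic + splice)
    as normalization — i.e. the test asks whether the intron's share of its
    local fragment pool shifted between samples.

    Criteria (all strict as stated): p < alpha; splice abundance > splice_floor
    in both samples; IR ratio > ir_floor in at least one sample.
    """
    if not (q1.assessable and q2.assessable):
        raise ValueError(f"{q1.intron_id}: quantification not assessable")
    if p_value is None:
        x = _round_half_up(q1.intronic_abundance)
        y = _round_half_up(q2.intronic_abundance)
        n1 = max(q1.intronic_abundance + q1.splice_abundance, 1e-9)
        n2 = max(q2.intronic_abundance + q2.splice_abundance, 1e-9)
        p_value = audic_claverie_p(x, y, n1, n2)
    r1, r2 = q1.ir_ratio, q2.ir_ratio
    return DifferentialIRResult(
        intron_id=q1.intron_id,
        ir_ratio_1=r1,
        ir_ratio_2=r2,
        p_value=p_value,
        direction="increased" if r2 >= r1 else "decreased",
        fold_change=(r2 + epsilon) / (r1 + epsilon),
        pass_p=p_value < alpha,
        pass_splice=q1.splice_abundance > splice_floor and q2.splice_abundance > splice_floor,
        pass_ir=r1 > ir_floor or r2 > ir_floor,
    )


def direction_bias_test(n_increased: int, n_decreased: int) -> float:
    """Exact two-sided binomial p (doubled smaller tail) under p0=0.5."""
    n = n_increased + n_decreased
    if n < 1:
        raise ValueError("need at least one event")
    lower = float(binom.cdf(n_increased, n, 0.5))
    upper = float(binom.sf(n_increased - 1, n, 0.5))
    return min(1.0, 2.0 * min(lower, upper))


def run_differential(
    quants1: Sequence[IRQuant],
    quants2: Sequence[IRQuant],
    alpha: float = 0.05,
    splice_floor: int = 10,
    ir_floor: float = 0.1,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Compare two samples intron-by-intron.

    Returns (per-intron table, summary with increased/decreased tallies among
    filter-passing introns and the direction-bias binomial p). Introns not
    assessable in either sample are skipped and logged. Raw p-values are used
    by default; Benjamini-Hochberg adjustment is available behind
    ``bh_correct``.
    """
    by_id = {q.intron_id: q for q in quants2}
    results: list[DifferentialIRResult] = []
    skipped = 0
    for q1 in quants1:
        q2 = by_id.get(q1.intron_id)
        if q2 is None:
            continue
        if not (q1.assessable and q2.assessable):
            skipped += 1
            continue
        results.append(
            differential_filter(
                q1, q2, alpha=alpha, splice_floor=splice_floor, ir_floor=ir_floor
            )
        )
    if skipped:
        logger.info("skipped %d introns with non-assessable quantification", skipped)
    df = pd.DataFrame(
        [
            {
                "intron_id": r.intron_id,
                "ir_ratio_1": r.ir_ratio_1,
                "ir_ratio_2": r.ir_ratio_2,
                "p_value": r.p_value,
                "fold_change": r.fold_change,
                "direction": r.direction,
                "pass_p": r.pass_p,
                "pass_splice": r.pass_splice,
                "pass_ir": r.pass_ir,
                "passes_filter": r.passes_filter,
            }
            for r in results
        ]
    )
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        rej, q, *_ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["q_value"] = q
        df["pass_p"] = rej
        df["passes_filter"] = df["pass_p"] & df["pass_splice"] & df["pass_ir"]
    if len(df):
        sig = df[df["passes_filter"]]
        n_inc = int((sig["direction"] == "increased").sum())
        n_dec = int((sig["direction"] == "decreased").sum())
    else:
        n_inc = n_dec = 0
    summary = {
        "n_tested": len(df),
        "n_skipped": skipped,
        "n_significant": n_inc + n_dec,
        "n_increased": n_inc,
        "n_decreased": n_dec,
        "direction_bias_p": direction_bias_test(n_inc, n_dec) if n_inc + n_dec else None,
    }
    return df, summary
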