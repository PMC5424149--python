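"""Sliding-window epigenomic metaprofiles around splice junctions.

Per-CpG methylation levels (beta values, kept only above a coverage floor)
or ChIP fold-enrichment intervals are pooled across all introns of a stratum
(retained vs non-retained) into 20 non-overlapping 10-bp windows spanning
+/-100 bp of an anchor: the 5' junction, the 3' junction, or the intron
midpoint. Profiles are strand-aware — minus-strand introns are flipped so
the negative offsets of a 5'-junction profile always lie on the exonic side.
A paired t-test across the 20 window-mean pairs assesses the overall
retained vs non-retained difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from irtools.genome_annotation import IntronRecord

Anchor = Literal["junction5", "junction3", "midpoint"]


class DegenerateTestError(ValueError):
    """Paired test with zero variance of a non-zero mean difference."""


@dataclass
class CpGMethylationRecord:
    chrom: str
    position: int  # 0-based genomic coordinate of the C of the CpG
    strand: str
    n_methylated: int
    n_unmethylated: int

    @property
    def coverage(self) -> int:
        return self.n_methylated + self.n_unmethylated

    @property
    def beta(self) -> float:
        return self.n_methylated / self.coverage


@dataclass
class SignalRecord:
    chrom: str
    start: int
    end: int
    value: float  # fold enrichment (ChIP/input)


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """Read a cytosine-report-style TSV: chrom, 1-based pos, strand,
    methylated count, unmethylated count. Positions become 0-based."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "position", "strand", "n_methylated", "n_unmethylated"],
        dtype={"chrom": str},
        comment="#",
    )
    df["position"] = df["position"].astype(int) - 1
    return df


def write_cpg_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["position"] = out["position"].astype(int) + 1
    out[["chrom", "position", "strand", "n_methylated", "n_unmethylated"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_signal_bed(path: str | Path) -> list[SignalRecord]:
    """BED+value / bedGraph: chrom, start, end, fold enrichment."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            out.append(SignalRecord(chrom, int(s), int(e), float(v)))
    return out


def compute_beta_table(
    counts: pd.DataFrame | Iterable[CpGMethylationRecord], min_coverage: int = 6
) -> list[CpGMethylationRecord]:
    """Keep CpG sites with coverage >= min_coverage (i.e. more than five
    reads at the default) and attach beta values."""
    if isinstance(counts, pd.DataFrame):
        records = (
            CpGMethylationRecord(
                r.chrom, int(r.position), r.strand, int(r.n_methylated), int(r.n_unmethylated)
            )
            for r in counts.itertuples()
        )
    else:
        records = counts
    return [r for r in records if r.coverage >= min_coverage]


@dataclass
class MetaProfile:
    anchor: Anchor
    stratum: str
    window: int
    flank: int
    offsets: np.ndarray  # window start offsets: -flank, -flank+window, ...
    means: np.ndarray  # NaN where the window holds no sites
    counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "stratum": self.stratum,
                "window_start_offset": self.offsets,
                "mean": self.means,
                "n": self.counts,
            }
        )


def _anchor_coord(intron: IntronRecord, anchor: Anchor) -> int:
    if anchor == "junction5":
        return intron.junction5
    if anchor == "junction3":
        return intron.junction3
    if anchor == "midpoint":
        return intron.midpoint
    raise ValueError(f"unknown anchor {anchor!r}")


def _relative_offset(pos: int, anchor_coord: int, strand: str) -> int:
    """Transcription-oriented offset of base ``pos`` from a boundary anchor.

    Plus strand: rel = pos - anchor (base just left of the boundary is -1).
    Minus strand the axis flips: rel = anchor - 1 - pos, an involution that
    restores the genomic assignment when applied twice.
    """
    return pos - anchor_coord if strand == "+" else anchor_coord - 1 - pos


def window_profile(
    data: Sequence[CpGMethylationRecord] | Sequence[SignalRecord],
    introns: Sequence[IntronRecord],
    anchor: Anchor,
    stratum: str = "",
    window: int = 10,
    flank: int = 100,
) -> MetaProfile:
    """Pool site values across introns into fixed windows around the anchor.

    Point records (CpGs) land in the single window containing their offset;
    interval records (ChIP signal) contribute their fold enrichment once to
    every window they overlap. Window mean = sum of values / number of
    contributing sites. Midpoint profiles are clipped to the intron so that
    junction-adjacent signal is not double-counted.
    """
    if flank % window != 0:
        raise ValueError("flank must be divisible by window")
    n_win = 2 * flank // window
    sums = np.zeros(n_win)
    counts = np.zeros(n_win, dtype=int)

    by_chrom: dict[str, list] = {}
    for rec in data:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    point_data = bool(data) and isinstance(data[0], CpGMethylationRecord)

    for intron in introns:
        a = _anchor_coord(intron, anchor)
        recs = by_chrom.get(intron.chrom, [])
        for rec in recs:
            if point_data:
                pos = rec.position
                if anchor == "midpoint" and not (intron.start <= pos < intron.end):
                    continue
                rel = _relative_offset(pos, a, intron.strand)
                if -flank <= rel < flank:
                    idx = (rel + flank) // window
                    sums[idx] += rec.beta
                    counts[idx] += 1
            else:
                # interval record: hit every overlapped window
                for idx in range(n_win):
                    lo = -flank + idx * window
                    hi = lo + window
                    if intron.strand == "+":
                        ws, we = a + lo, a + hi
                    else:
                        ws, we = a - hi, a - lo
                    if anchor == "midpoint":
                        ws, we = max(ws, intron.start), min(we, intron.end)
                    if ws < we and rec.start < we and rec.end > ws:
                        sums[idx] += rec.value
                        counts[idx] += 1

    means = np.full(n_win, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return MetaProfile(
        anchor=anchor,
        stratum=stratum,
        window=window,
        flank=flank,
        offsets=np.arange(-flank, flank, window),
        means=means,
        counts=counts,
    )


def stratified_profiles(
    data,
    introns: Sequence[IntronRecord],
    labels: dict[str, bool],
    anchor: Anchor,
    window: int = 10,
    flank: int = 100,
) -> tuple[MetaProfile, MetaProfile]:
    """(retained, non_retained) profiles from per-intron boolean labels."""
    retained = [it for it in introns if labels.get(it.intron_id)]
    non_retained = [it for it in introns if labels.get(it.intron_id) is False]
    return (
        window_profile(data, retained, anchor, "retained", window, flank),
        window_profile(data, non_retained, anchor, "non_retained", window, flank),
    )


def paired_window_test(
    profile_a: MetaProfile, profile_b: MetaProfile
) -> tuple[float, int, float]:
    """Classical paired t-test on matched window means: (t, df, p).

    Windows missing in either profile are excluded pairwise; fewer than 3
    complete pairs is an error. Identical profiles give t=0, p=1; zero
    variance of a non-zero mean difference is degenerate (no p).
    """
    if profile_a.anchor != profile_b.anchor or profile_a.window != profile_b.window:
        raise ValueError("profiles must share anchor and window grid")
    ok = ~np.isnan(profile_a.means) & ~np.isnan(profile_b.means)
    d = profile_a.means[ok] - profile_b.means[ok]
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 complete window pairs, got {n}")
    df = n - 1
    if np.all(d == d[0]):  # constant differences: zero variance exactly
        if d[0] == 0:
            return 0.0, df, 1.0
        raise DegenerateTestError("zero variance of non-zero window differences")
    sd = d.std(ddof=1)
    from scipy.stats import t as t_dist

    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * t_dist.sf(abs(t), df)
    return float(t), df, float(p)
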