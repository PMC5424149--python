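"""Per-intron IR quantification from spliced alignments.

Splice abundance counts fragments whose alignment gap spans the intron:
exactly, or anchored at the donor (junction5) or acceptor (junction3) side
with the other end elsewhere; the larger one-sided tally is used, with exact
spanners counted in both sides. Intronic abundance is a 30%-trimmed mean of
per-base fragment depth over the measurable intron area (poor mappability
and foreign features removed, not zero-filled). IR ratio = intronic /
(intronic + splice); 0/0 is not assessable (distinct from an IR ratio of 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from irtools.genome_annotation import IntronRecord
from irtools.intervals import Interval


@dataclass
class AlignedFragment:
    """One sequenced fragment: aligned blocks separated by junction gaps.

    Blocks are genomic intervals covered by the alignment (N cigar operations
    split blocks; deletions do not). ``junction_gaps`` are the skipped
    intervals between consecutive blocks.
    """

    chrom: str
    blocks: list[Interval]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("fragment blocks overlap")

    @property
    def junction_gaps(self) -> list[Interval]:
        return [
            (e1, s2)
            for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:])
            if s2 > e1
        ]

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


def _blocks_from_cigar(pos: int, cigartuples) -> list[Interval]:
    """Reference blocks split only at N operations (D stays within a block)."""
    blocks: list[Interval] = []
    cur_start, cur = pos, pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            cur += length
        elif op == 3:  # N: junction gap
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        # I, S, H, P do not consume reference
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def fragments_from_sam(
    path: str | Path, sample_id: str = "", merge_pairs: bool = False
) -> list[AlignedFragment]:
    """Read primary alignments from SAM/BAM into fragments.

    Unmapped, secondary and supplementary records are skipped (multi-mapping
    reads are expected to be excluded upstream by the aligner). With
    ``merge_pairs`` the two mates of a pair are merged into one fragment by
    uniting their blocks, so a pair contributes once to splice counts and
    depth.
    """
    import pysam

    singles: list[AlignedFragment] = []
    pending: dict[str, AlignedFragment] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            frag = AlignedFragment(
                chrom=rec.reference_name,
                blocks=_blocks_from_cigar(rec.reference_start, rec.cigartuples or []),
                sample_id=sample_id,
            )
            if merge_pairs and rec.is_paired:
                mate = pending.pop(rec.query_name, None)
                if mate is None:
                    pending[rec.query_name] = frag
                elif mate.chrom == frag.chrom:
                    merged = _merge_blocks(mate.blocks + frag.blocks)
                    singles.append(AlignedFragment(frag.chrom, merged, sample_id))
                else:
                    singles.extend([mate, frag])
            else:
                singles.append(frag)
    singles.extend(pending.values())
    return singles


def _merge_blocks(blocks: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class IRQuant:
    intron_id: str
    sample_id: str
    splice_exact: int
    splice_left: int
    splice_right: int
    splice_abundance: int
    intronic_abundance: float | None  # None = not assessable (no measurable bases)
    measurable_bases: int
    ir_ratio: float | None = None
    retained: bool | None = None

    @property
    def assessable(self) -> bool:
        return self.ir_ratio is not None


def count_splice(
    fragments: Iterable[AlignedFragment], intron: IntronRecord
) -> tuple[int, int, int, int]:
    """(splice_exact, splice_left, splice_right, splice_abundance).

    A gap matching the intron span exactly counts in both one-sided tallies;
    splice_abundance = max(left, right).
    """
    exact = left = right = 0
    j5, j3 = intron.junction5, intron.junction3
    for frag in fragments:
        if frag.chrom != intron.chrom:
            continue
        frag_exact = frag_left = frag_right = False
        for gs, ge in frag.junction_gaps:
            donor, acceptor = (gs, ge) if intron.strand == "+" else (ge, gs)
            if (gs, ge) == intron.span:
                frag_exact = True
            if donor == j5:
                frag_left = True
            if acceptor == j3:
                frag_right = True
        exact += frag_exact
        left += frag_left
        right += frag_right
    return exact, left, right, max(left, right)


def depth_vector(
    fragments: Iterable[AlignedFragment], intron: IntronRecord
) -> np.ndarray:
    """Per-base fragment depth over the measurable spans (concatenated).

    Any fragment base overlapping a measurable span adds depth, including
    boundary-spanning reads; junction gaps contribute nothing. Masked
    positions are absent from the vector, not zero-filled.
    """
    spans = intron.measurable_spans
    n = sum(e - s for s, e in spans)
    depth = np.zeros(n, dtype=np.int64)
    offsets = []
    off = 0
    for s, e in spans:
        offsets.append((s, e, off))
        off += e - s
    for frag in fragments:
        if frag.chrom != intron.chrom:
            continue
        for bs, be in frag.blocks:
            for s, e, off0 in offsets:
                lo, hi = max(bs, s), min(be, e)
                if lo < hi:
                    depth[off0 + (lo - s) : off0 + (hi - s)] += 1
    return depth


def trimmed_mean_depth(depths: Sequence[float] | np.ndarray, trim_fraction: float = 0.30) -> float | None:
    """Mean after dropping floor(trim_fraction*n) values from each end.

    Returns None (not assessable) for an empty vector.
    """
    arr = np.sort(np.asarray(depths, dtype=float))
    n = arr.size
    if n == 0:
        return None
    k = math.floor(trim_fraction * n)
    return float(arr[k : n - k].mean())


def ir_ratio(intronic_abundance: float, splice_abundance: float) -> float | None:
    """intronic / (intronic + splice); 0/0 -> None (not assessable)."""
    if intronic_abundance < 0 or splice_abundance < 0:
        raise ValueError("abundances must be non-negative")
    denom = intronic_abundance + splice_abundance
    if denom == 0:
        return None
    return intronic_abundance / denom


def classify_retained(ratio: float | None, threshold: float = 0.10) -> bool | None:
    """Retained iff IR ratio >= threshold (inclusive); None propagates."""
    if ratio is None:
        return None
    return ratio >= threshold


def quantify(
    fragments: Sequence[AlignedFragment],
    introns: Sequence[IntronRecord],
    sample_id: str = "",
    trim_fraction: float = 0.30,
    retention_threshold: float = 0.10,
) -> list[IRQuant]:
    """Quantify every intron against one sample's fragments.

    Fragments are pre-bucketed by chromosome and sorted so only candidates
    overlapping each intron's neighbourhood are scanned.
    """
    by_chrom: dict[str, list[AlignedFragment]] = {}
    for frag in fragments:
        by_chrom.setdefault(frag.chrom, []).append(frag)
    for frags in by_chrom.values():
        frags.sort(key=lambda f: f.span[0])
    out: list[IRQuant] = []
    for intron in introns:
        frags = by_chrom.get(intron.chrom, [])
        starts = [f.span[0] for f in frags]
        # fragments whose span could touch the intron
        hi = np.searchsorted(starts, intron.end)
        cand = [f for f in frags[:hi] if f.span[1] > intron.start]
        exact, left, right, splice = count_splice(cand, intron)
        depths = depth_vector(cand, intron)
        intronic = trimmed_mean_depth(depths, trim_fraction)
        ratio = None if intronic is None else ir_ratio(intronic, splice)
        out.append(
            IRQuant(
                intron_id=intron.intron_id,
                sample_id=sample_id,
                splice_exact=exact,
                splice_left=left,
                splice_right=right,
                splice_abundance=splice,
                intronic_abundance=intronic,
                measurable_bases=int(depths.size),
                ir_ratio=ratio,
                retained=classify_retained(ratio, retention_threshold),
            )
        )
    return out


def quant_table(quants: Iterable[IRQuant], introns: Sequence[IntronRecord] | None = None) -> pd.DataFrame:
    """Tabulate quantifications; optionally joins intron coordinates."""
    rows = []
    meta = {it.intron_id: it for it in introns or []}
    for q in quants:
        row = {
            "intron_id": q.intron_id,
            "sample_id": q.sample_id,
            "splice_exact": q.splice_exact,
            "splice_left": q.splice_left,
            "splice_right": q.splice_right,
            "splice_abundance": q.splice_abundance,
            "intronic_abundance": q.intronic_abundance,
            "measurable_bases": q.measurable_bases,
            "ir_ratio": q.ir_ratio,
            "retained": q.retained,
        }
        it = meta.get(q.intron_id)
        if it is not None:
            row.update(
                gene_id=it.gene_id, chrom=it.chrom, start=it.start, end=it.end, strand=it.strand
            )
        rows.append(row)
    return pd.DataFrame(rows)
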