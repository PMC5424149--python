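"""Synthetic-read mappability screen.

Error-bearing reads (default 70 bp, stepped every 10 bp, alternating
orientation, one substituted central base) are taken from the genome and
re-aligned. Reads that map uniquely back to their origin are tallied onto
every base of that origin; an interior base can be overlapped by at most
ceil(read_len/step) = 7 such reads. Any base with fewer than ``min_unique``
(default 5) uniquely-mapping overlapping reads is poorly mappable; maximal
runs of failing bases form the mask.

The built-in aligner is an exhaustive both-strand substring search allowing
up to one mismatch (the planted error), suitable for toy genomes. For large
genomes the reads can be exported as FASTA, aligned externally, and the
resulting SAM consumed by :func:`tally_from_sam`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from irtools.genome_annotation import GenomeSequence
from irtools.intervals import Interval

logger = logging.getLogger(__name__)

# deterministic central-base substitution: no random seed needed
SUBSTITUTION = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticRead:
    read_id: str  # "<chrom>:<start>:<F|R>"
    chrom: str
    start: int  # origin interval [start, start+len)
    sequence: str
    reverse: bool

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def generate_synthetic_reads(
    genome: GenomeSequence,
    read_len: int = 70,
    step: int = 10,
    center: int | None = None,
) -> Iterator[SyntheticRead]:
    """Yield error-bearing reads stepped across every chromosome.

    Reads start at 0, step, 2*step, ... per chromosome; every second read
    (per chromosome, starting forward) is reverse-complemented. The central
    substitution (0-based index ``center``, default read_len//2 - 1) is
    applied before the orientation flip.
    """
    if read_len <= 0 or step <= 0:
        raise ValueError("read_len and step must be positive")
    if center is None:
        center = read_len // 2 - 1
    for chrom in genome.chrom_names:
        L = genome.chrom_length(chrom)
        if L < read_len:
            warnings.warn(f"chromosome {chrom} shorter than read length; no reads")
            continue
        for ordinal, start in enumerate(range(0, L - read_len + 1, step)):
            ref = genome.sequence(chrom, start, start + read_len)
            seq = ref[:center] + SUBSTITUTION[ref[center]] + ref[center + 1 :]
            reverse = ordinal % 2 == 1
            if reverse:
                seq = reverse_complement(seq)
            yield SyntheticRead(
                read_id=f"{chrom}:{start}:{'R' if reverse else 'F'}",
                chrom=chrom,
                start=start,
                sequence=seq,
                reverse=reverse,
            )


def write_reads_fasta(reads: Iterable[SyntheticRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


class BruteForceAligner:
    """Exhaustive both-strand substring search allowing <=1 mismatch.

    A read is uniquely mapped iff exactly one genome-wide location attains
    the best score among all locations within the mismatch allowance; a
    second location at equal or better score makes it ambiguous.
    """

    def __init__(self, genome: GenomeSequence, max_mismatch: int = 1):
        self.genome = genome
        self.max_mismatch = max_mismatch
        self._encoded = {
            c: np.frombuffer(
                genome.sequence(c, 0, genome.chrom_length(c)).encode(), dtype=np.uint8
            )
            for c in genome.chrom_names
        }
        self._windows: dict[int, dict[str, np.ndarray]] = {}

    def _window_view(self, read_len: int) -> dict[str, np.ndarray]:
        if read_len not in self._windows:
            views = {}
            for chrom, arr in self._encoded.items():
                if len(arr) >= read_len:
                    views[chrom] = np.lib.stride_tricks.sliding_window_view(arr, read_len)
            self._windows[read_len] = views
        return self._windows[read_len]

    def best_locations(self, sequence: str) -> tuple[int, list[tuple[str, int, str]]]:
        """Return (best mismatch count, locations at that count).

        Locations are (chrom, start, strand-of-genome-match); the search
        considers the read as given and its reverse complement.
        """
        L = len(sequence)
        views = self._window_view(L)
        queries = {
            "+": np.frombuffer(sequence.encode(), dtype=np.uint8),
            "-": np.frombuffer(reverse_complement(sequence).encode(), dtype=np.uint8),
        }
        best = self.max_mismatch + 1
        locations: list[tuple[str, int, str]] = []
        for strand, q in queries.items():
            for chrom, win in views.items():
                mm = np.count_nonzero(win != q, axis=1)
                within = np.nonzero(mm <= self.max_mismatch)[0]
                for idx in within:
                    score = int(mm[idx])
                    if score < best:
                        best = score
                        locations = [(chrom, int(idx), strand)]
                    elif score == best:
                        locations.append((chrom, int(idx), strand))
        return best, locations

    def maps_uniquely_to_origin(self, read: SyntheticRead) -> bool:
        best, locs = self.best_locations(read.sequence)
        if best > self.max_mismatch or len(locs) != 1:
            return False
        chrom, start, _ = locs[0]
        return chrom == read.chrom and start == read.start


def unique_mapping_tally(
    reads: Iterable[SyntheticRead],
    genome: GenomeSequence,
    aligner: BruteForceAligner | None = None,
) -> dict[str, np.ndarray]:
    """Per-base count of overlapping reads that map uniquely to their origin."""
    if aligner is None:
        aligner = BruteForceAligner(genome)
    tallies = {
        c: np.zeros(genome.chrom_length(c), dtype=np.int32) for c in genome.chrom_names
    }
    for read in reads:
        if aligner.maps_uniquely_to_origin(read):
            tallies[read.chrom][read.start : read.end] += 1
    return tallies


def tally_from_sam(sam_path: str | Path, genome: GenomeSequence) -> dict[str, np.ndarray]:
    """Tally uniquely-and-correctly mapped synthetic reads from an external
    aligner's SAM output.

    Read names must carry the origin as ``chrom:start:orientation``.
    Uniqueness is taken from the NH tag when present (NH==1), otherwise from
    the record being the only primary alignment.
    """
    import pysam

    tallies = {
        c: np.zeros(genome.chrom_length(c), dtype=np.int32) for c in genome.chrom_names
    }
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            parts = rec.query_name.rsplit(":", 2)
            if len(parts) != 3 or parts[2] not in ("F", "R"):
                raise ValueError(f"read id not parseable into an origin: {rec.query_name!r}")
            chrom, start = parts[0], int(parts[1])
            if rec.has_tag("NH") and rec.get_tag("NH") != 1:
                continue
            if rec.reference_name == chrom and rec.reference_start == start:
                read_len = rec.query_length or rec.infer_query_length() or 0
                tallies[chrom][start : start + read_len] += 1
    return tallies


@dataclass
class MappabilityMask:
    """Per-chromosome sorted disjoint intervals of poorly mappable bases."""

    intervals: dict[str, list[Interval]]
    read_len: int = 70
    step: int = 10
    min_unique: int = 5
    possible: int = 7

    def is_masked(self, chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals.get(chrom, []))

    def masked_bases(self, chrom: str) -> int:
        return sum(e - s for s, e in self.intervals.get(chrom, []))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @classmethod
    def from_bed(cls, path: str | Path, **params) -> "MappabilityMask":
        intervals: dict[str, list[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, s, e = line.split()[:3]
                intervals.setdefault(chrom, []).append((int(s), int(e)))
        return cls({c: sorted(iv) for c, iv in intervals.items()}, **params)


def build_mask(
    tallies: dict[str, np.ndarray],
    min_unique: int = 5,
    read_len: int = 70,
    step: int = 10,
) -> MappabilityMask:
    """Flag every base with tally < min_unique; merge runs into intervals.

    The threshold is absolute, so chromosome ends (where fewer than 7 reads
    are geometrically possible) are masked by construction.
    """
    intervals: dict[str, list[Interval]] = {}
    for chrom, tally in tallies.items():
        fail = tally < min_unique
        ivs: list[Interval] = []
        # boundaries of runs of failing bases
        padded = np.concatenate([[False], fail, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        ivs = [(int(s), int(e)) for s, e in zip(starts, ends)]
        intervals[chrom] = ivs
    return MappabilityMask(
        intervals,
        read_len=read_len,
        step=step,
        min_unique=min_unique,
        possible=int(np.ceil(read_len / step)),
    )


def compute_mask(
    genome: GenomeSequence,
    read_len: int = 70,
    step: int = 10,
    min_unique: int = 5,
    center: int | None = None,
) -> MappabilityMask:
    """One-call pipeline: generate reads, re-align, tally, build mask."""
    reads = generate_synthetic_reads(genome, read_len=read_len, step=step, center=center)
    tallies = unique_mapping_tally(reads, genome)
    return build_mask(tallies, min_unique=min_unique, read_len=read_len, step=step)
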