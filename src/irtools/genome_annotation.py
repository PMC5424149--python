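"""Genome/annotation parsing and the intron catalogue.

Internal coordinates are 0-based half-open throughout; GTF input (1-based
inclusive, Ensembl dialect) is converted at the parser boundary. Introns are
derived per gene as the distinct genomic gaps between consecutive exons of
any transcript, then trimmed to their *measurable* sub-regions by excluding
overlapping foreign features (e.g. miRNA/snoRNA exons of other genes) and,
later, poorly mappable regions — both applied regardless of strand.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from irtools.intervals import Interval, merge, subtract, intersect, total_length


class MalformedAnnotationError(ValueError):
    """Raised when transcript exons overlap or lie off their chromosome."""


class GenomeSequence:
    """Random-access genome over the A/C/G/T/N alphabet.

    Backed either by an in-memory dict of chromosome strings or by an
    indexed FASTA file (via :mod:`pyfaidx`).
    """

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: str(seq).upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Substring for half-open 0-based [start, end)."""
        seq = self._chroms[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"request {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: list[list[Interval]]  # exon intervals per transcript, genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for exons in self.transcripts:
            prev_end = None
            for s, e in sorted(exons):
                if s >= e:
                    raise MalformedAnnotationError(
                        f"{self.gene_id}: empty exon interval ({s},{e})"
                    )
                if prev_end is not None and s < prev_end:
                    raise MalformedAnnotationError(
                        f"{self.gene_id}: overlapping exons within a transcript"
                    )
                prev_end = e

    @property
    def span(self) -> Interval:
        starts = [s for ex in self.transcripts for s, _ in ex]
        ends = [e for ex in self.transcripts for _, e in ex]
        return (min(starts), max(ends))


@dataclass
class IntronRecord:
    """One annotated intron with strand-aware junction anchors.

    ``junction5`` (donor) and ``junction3`` (acceptor) are genomic boundary
    coordinates: on the plus strand junction5 is the left span edge; on the
    minus strand it is the right edge. ``measurable_spans`` is the span minus
    ``excluded_spans`` (foreign features + poor mappability).
    """

    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ordinal: int = 0  # 1-based position in transcription order within the gene
    excluded_spans: list[Interval] = field(default_factory=list)
    measurable_spans: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.measurable_spans and not self.excluded_spans:
            self.measurable_spans = [(self.start, self.end)]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def junction5(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def junction3(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.width // 2

    @property
    def measurable_length(self) -> int:
        return total_length(self.measurable_spans)

    def exclude(self, spans: Iterable[Interval]) -> None:
        """Add exclusions (clipped to the intron span) and recompute
        measurable_spans."""
        for iv in spans:
            clipped = intersect(iv, self.span)
            if clipped is not None:
                self.excluded_spans.append(clipped)
        self.excluded_spans = merge(self.excluded_spans)
        self.measurable_spans = subtract(self.span, self.excluded_spans)


def derive_introns(models: Iterable[GeneModel]) -> list[IntronRecord]:
    """One IntronRecord per distinct inter-exon gap per gene.

    Gaps are deduplicated by span within a gene (identical gaps shared by
    several transcripts yield one record); deduplication is per-gene, so
    overlapping genes keep separate records. Single-exon transcripts
    contribute nothing. Ordinals number introns 1..n in transcription order.
    """
    out: list[IntronRecord] = []
    for gene in models:
        gaps: set[Interval] = set()
        for exons in gene.transcripts:
            exons = sorted(exons)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 < s2:
                    gaps.add((e1, s2))
        ordered = sorted(gaps, reverse=(gene.strand == "-"))
        for i, (s, e) in enumerate(ordered, start=1):
            out.append(
                IntronRecord(
                    intron_id=f"{gene.gene_id}:I{i}:{gene.chrom}:{s}-{e}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=s,
                    end=e,
                    ordinal=i,
                )
            )
    return out


def apply_feature_exclusions(
    introns: list[IntronRecord],
    foreign_features: Iterable[tuple[str, int, int]],
) -> list[IntronRecord]:
    """Exclude overlaps with foreign features (chrom, start, end) in place.

    Feature strand is deliberately ignored: any transcribed overlap can
    confound the intronic depth measurement, whichever strand it sits on.
    Returns the same list for chaining.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in foreign_features:
        by_chrom.setdefault(chrom, []).append((s, e))
    for intron in introns:
        feats = by_chrom.get(intron.chrom, [])
        hits = [iv for iv in feats if intersect(iv, intron.span)]
        if hits:
            intron.exclude(hits)
    return introns


def apply_mappability_mask(introns: list[IntronRecord], mask) -> list[IntronRecord]:
    """Exclude poorly mappable regions (a :class:`~irtools.mappability.MappabilityMask`)."""
    for intron in introns:
        ivs = mask.intervals.get(intron.chrom, [])
        hits = [iv for iv in ivs if intersect(iv, intron.span)]
        if hits:
            intron.exclude(hits)
    return introns


def sequence_features(intron: IntronRecord, genome: GenomeSequence) -> tuple[int, float, float]:
    """(length, GC fraction, CpG density) over the full intron span.

    CpG density counts forward-strand CG dinucleotides per nucleotide of
    intron length.
    """
    if intron.width == 0:
        raise ValueError(f"{intron.intron_id}: zero-length intron")
    seq = genome.sequence(intron.chrom, intron.start, intron.end)
    n = len(seq)
    gc = (seq.count("G") + seq.count("C")) / n
    cpg = seq.count("CG") / n
    return n, gc, cpg


# ---------------------------------------------------------------------------
# GTF / BED I/O


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from an Ensembl-dialect GTF into gene models.

    Parsing is delegated to :mod:`gffutils` (in-memory database); 1-based
    inclusive GTF coordinates become 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_exons: dict[tuple[str, str], list[Interval]] = {}
    tx_meta: dict[tuple[str, str], tuple[str, str]] = {}  # -> (chrom, strand)
    for feat in db.features_of_type("exon"):
        try:
            gene_id = feat["gene_id"][0]
            tx_id = feat["transcript_id"][0]
        except KeyError as exc:
            raise MalformedAnnotationError(
                f"exon at {feat.seqid}:{feat.start} missing gene_id/transcript_id"
            ) from exc
        key = (gene_id, tx_id)
        tx_exons.setdefault(key, []).append((feat.start - 1, feat.end))
        tx_meta[key] = (feat.seqid, feat.strand)
    genes: dict[str, GeneModel] = {}
    for (gene_id, tx_id), exons in tx_exons.items():
        chrom, strand = tx_meta[(gene_id, tx_id)]
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, chrom, strand, [])
        if genes[gene_id].chrom != chrom:
            raise MalformedAnnotationError(f"{gene_id}: transcripts on different chromosomes")
        genes[gene_id].transcripts.append(sorted(exons))
    # re-validate now that transcripts are attached
    for g in genes.values():
        GeneModel(g.gene_id, g.chrom, g.strand, g.transcripts)
    return list(genes.values())


def write_intron_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """Emit the intron catalogue as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for it in introns:
            fh.write(f"{it.chrom}\t{it.start}\t{it.end}\t{it.intron_id}\t0\t{it.strand}\n")
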