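"""Self-contained simulator: toy genome, annotation, spliced fragments at
known true retention fractions, CpG methylation counts and ChIP signal.

The retention fraction ``r`` of an intron is defined at the transcript-
molecule level: a fraction r of a gene's mature transcripts retain the
intron. Fragments are drawn from the molecule pool with the usual
length-weighting of shotgun libraries (a molecule contributes fragments in
proportion to its length), which is the sampling model under which the
IR-ratio estimator — trimmed-mean intronic depth over depth plus
junction-spanning count — is a consistent estimator of r.

Methylation emulates the junction-proximal hypomethylation of retained
introns: beta values sit at a genome-wide baseline and dip by a configured
depth within a configured distance of the junctions (and midpoint) of
retained introns. ChIP fold enrichment mirrors the same shape scaled to a
positive range. No sequencing-error or bisulfite-conversion-failure
modelling; fragments are emitted pre-aligned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from irtools.genome_annotation import GenomeSequence, GeneModel, IntronRecord, derive_introns
from irtools.ir_quant import AlignedFragment
from irtools.junction_metaprofile import SignalRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a compact but realistically proportioned locus set:
    multi-exon genes whose exonic length dominates intron length (as in
    mammalian mRNA), deep fragment sampling, high-coverage bisulfite counts,
    and a 0.3 beta dip within 100 bp of retained-intron junctions.
    """

    seed: int = 0
    n_chroms: int = 1
    n_genes: int = 10
    exons_per_gene: int = 3
    exon_length: tuple[int, int] = (400, 800)
    intron_length: tuple[int, int] = (150, 400)
    intergenic: int = 300
    retention: float | None = None  # fixed true r; None -> draw from range
    retention_range: tuple[float, float] = (0.0, 0.8)
    fragments_per_gene: int = 2000
    fragment_length: int = 100
    duplication_block: int | None = None  # plant an exact duplicate of this many bp
    n_foreign_features: int = 0
    foreign_feature_length: int = 60
    # methylation / ChIP
    baseline_beta: float = 0.8
    dip_depth: float = 0.3
    dip_width: int = 100
    mean_coverage: float = 30.0
    chip_baseline: float = 4.0
    chip_dip: float = 2.0
    chip_tile: int = 20


@dataclass
class GroundTruth:
    """What was planted: per-intron true r and labels, foreign features,
    duplicated-block coordinates."""

    introns: pd.DataFrame  # intron_id, gene_id, chrom, start, end, strand, ordinal, true_r, retained
    foreign_features: list[tuple[str, int, int]] = field(default_factory=list)
    duplication: tuple[str, int, int, int] | None = None  # chrom, src, dst, length

    def true_r(self, intron_id: str) -> float:
        return float(self.introns.set_index("intron_id").loc[intron_id, "true_r"])

    def to_tsv(self, path: str | Path) -> None:
        self.introns.to_csv(path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Build a random genome with planted multi-exon genes on both strands.

    Optionally plants an exact duplicated block (mappability stress) and
    foreign ncRNA features inside the first introns. Deterministic for a
    fixed config.
    """
    rng = np.random.default_rng(config.seed)
    if config.exon_length[0] <= 0 or config.intron_length[0] <= 0:
        raise ValueError("length ranges must be positive")

    genes: list[GeneModel] = []
    chrom_parts: dict[str, list[int]] = {}  # chrom -> running length
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursor = {c: config.intergenic for c in chrom_names}

    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursor[chrom]
        exons: list[tuple[int, int]] = []
        for ei in range(config.exons_per_gene):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if ei < config.exons_per_gene - 1:
                ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                pos += ilen
        cursor[chrom] = pos + config.intergenic
        genes.append(GeneModel(f"g{gi + 1}", chrom, strand, [exons]))

    dup = None
    if config.duplication_block:
        # duplicate the interior of the first gene's first intron into the tail
        g0 = genes[0]
        ex = g0.transcripts[0]
        src = ex[0][1] + 10
        length = config.duplication_block
        dst = cursor[g0.chrom]
        cursor[g0.chrom] = dst + length + config.intergenic
        dup = (g0.chrom, src, dst, length)

    seqs = {c: _random_sequence(rng, cursor[c]) for c in chrom_names}
    if dup is not None:
        chrom, src, dst, length = dup
        s = seqs[chrom]
        seqs[chrom] = s[:dst] + s[src : src + length] + s[dst + length :]
    genome = GenomeSequence(seqs)

    introns = derive_introns(genes)
    if config.retention is not None:
        rs = np.full(len(introns), float(config.retention))
    else:
        rs = rng.uniform(*config.retention_range, size=len(introns))
    truth_rows = [
        {
            "intron_id": it.intron_id,
            "gene_id": it.gene_id,
            "chrom": it.chrom,
            "start": it.start,
            "end": it.end,
            "strand": it.strand,
            "ordinal": it.ordinal,
            "true_r": float(r),
            "retained": bool(r >= 0.1),
        }
        for it, r in zip(introns, rs)
    ]

    foreign: list[tuple[str, int, int]] = []
    for it in introns[: config.n_foreign_features]:
        mid = it.midpoint
        half = config.foreign_feature_length // 2
        fs = max(it.start, mid - half)
        fe = min(it.end, fs + config.foreign_feature_length)
        foreign.append((it.chrom, fs, fe))

    truth = GroundTruth(pd.DataFrame(truth_rows), foreign_features=foreign, duplication=dup)
    return genome, genes, truth


def write_gtf(
    genes: Sequence[GeneModel],
    path: str | Path,
    foreign_features: Sequence[tuple[str, int, int]] = (),
) -> None:
    """Ensembl-dialect GTF (1-based inclusive); foreign features are emitted
    as single-exon ncRNA genes."""
    with open(path, "w") as fh:
        for g in genes:
            for ti, exons in enumerate(g.transcripts, start=1):
                tx = f"{g.gene_id}.t{ti}"
                for s, e in exons:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx}"; gene_biotype "protein_coding";'
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
        for i, (chrom, s, e) in enumerate(foreign_features, start=1):
            attrs = f'gene_id "nc{i}"; transcript_id "nc{i}.t1"; gene_biotype "snoRNA";'
            fh.write(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n")


def _isoform_table(
    gene: GeneModel, intron_rs: list[tuple[IntronRecord, float]]
) -> tuple[list[list[tuple[int, int]]], np.ndarray]:
    """Enumerate 2^k isoforms of a gene: exon blocks with each retained
    intron merged in, weighted by molar probability times length."""
    exons = sorted(gene.transcripts[0])
    isoforms: list[list[tuple[int, int]]] = []
    weights: list[float] = []
    k = len(intron_rs)
    for keep in itertools.product((False, True), repeat=k):
        prob = 1.0
        retained_spans = []
        for (it, r), kept in zip(intron_rs, keep):
            prob *= r if kept else (1.0 - r)
            if kept:
                retained_spans.append(it.span)
        if prob == 0.0:
            continue
        blocks = _merge_with_retained(exons, retained_spans)
        length = sum(e - s for s, e in blocks)
        isoforms.append(blocks)
        weights.append(prob * length)
    w = np.asarray(weights)
    return isoforms, w / w.sum()


def _merge_with_retained(
    exons: list[tuple[int, int]], retained: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    blocks = sorted(exons + retained)
    out = [blocks[0]]
    for s, e in blocks[1:]:
        if s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def simulate_fragments(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    sample_id: str = "s1",
    retention_overrides: dict[str, float] | None = None,
    seed: int | None = None,
) -> list[AlignedFragment]:
    """Draw fragments per gene from the molar isoform pool.

    Each fragment picks an isoform (retention status of every intron jointly,
    length-weighted molar sampling) and a uniform start along it; the
    alignment blocks follow by mapping isoform coordinates back to the
    genome, with junction gaps at spliced-out introns.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    overrides = retention_overrides or {}
    introns = truth.introns
    frags: list[AlignedFragment] = []
    flen = config.fragment_length
    for gene in genes:
        sub = introns[introns.gene_id == gene.gene_id]
        intron_rs = [
            (
                IntronRecord(
                    row.intron_id, row.gene_id, row.chrom, row.strand, row.start, row.end
                ),
                float(overrides.get(row.intron_id, row.true_r)),
            )
            for row in sub.itertuples()
        ]
        isoforms, probs = _isoform_table(gene, intron_rs)
        lengths = [sum(e - s for s, e in blocks) for blocks in isoforms]
        if min(lengths) < flen:
            raise ValueError(
                f"{gene.gene_id}: fragment length {flen} exceeds an isoform length"
            )
        choices = rng.choice(len(isoforms), size=config.fragments_per_gene, p=probs)
        for iso_idx in choices:
            blocks = isoforms[iso_idx]
            L = lengths[iso_idx]
            start = int(rng.integers(0, L - flen + 1))
            frags.append(
                AlignedFragment(
                    chrom=gene.chrom,
                    blocks=_project_to_genome(blocks, start, flen),
                    sample_id=sample_id,
                )
            )
    return frags


def _project_to_genome(
    blocks: list[tuple[int, int]], start: int, length: int
) -> list[tuple[int, int]]:
    """Map isoform interval [start, start+length) onto genomic blocks."""
    out: list[tuple[int, int]] = []
    remaining = length
    offset = start
    for s, e in blocks:
        blen = e - s
        if offset >= blen:
            offset -= blen
            continue
        take = min(blen - offset, remaining)
        out.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return out


def write_sam(
    fragments: Sequence[AlignedFragment],
    genome: GenomeSequence,
    path: str | Path,
) -> None:
    """Write fragments as coordinate-sorted single-end SAM records."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": genome.chrom_length(c)} for c in genome.chrom_names
        ],
    }
    ordered = sorted(enumerate(fragments), key=lambda kv: (kv[1].chrom, kv[1].span[0]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(genome.chrom_names)}
        for i, frag in ordered:
            rec = pysam.AlignedSegment()
            rec.query_name = f"frag{i}"
            rec.reference_id = tid[frag.chrom]
            rec.reference_start = frag.blocks[0][0]
            rec.mapping_quality = 60
            cigar = []
            prev_end = None
            for s, e in frag.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N
                cigar.append((0, e - s))  # M
                prev_end = e
            rec.cigartuples = cigar
            rec.query_sequence = "".join(
                genome.sequence(frag.chrom, s, e) for s, e in frag.blocks
            )
            rec.flag = 0
            out.write(rec)


def _dip_regions(truth: GroundTruth, config: SimulationConfig) -> dict[str, list[tuple[int, int]]]:
    """Hypomethylated intervals: within dip_width of each retained intron's
    junctions and midpoint."""
    w = config.dip_width
    regions: dict[str, list[tuple[int, int]]] = {}
    for row in truth.introns.itertuples():
        if not row.retained:
            continue
        mid = row.start + (row.end - row.start) // 2
        for centre in (row.start, row.end, mid):
            regions.setdefault(row.chrom, []).append((max(0, centre - w), centre + w))
    return regions


def beta_at(
    chrom: str, pos: int, dip_regions: dict[str, list[tuple[int, int]]], config: SimulationConfig
) -> float:
    for s, e in dip_regions.get(chrom, []):
        if s <= pos < e:
            return max(0.0, config.baseline_beta - config.dip_depth)
    return config.baseline_beta


def simulate_methylation(
    config: SimulationConfig,
    genome: GenomeSequence,
    truth: GroundTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[SignalRecord]]:
    """Per-CpG counts and ChIP fold-enrichment tiles.

    Every forward-strand CG dinucleotide of the genome becomes a site with
    coverage ~ Poisson(mean_coverage) and methylated count ~ Binomial(cov,
    beta(pos)), where beta dips near retained-intron junctions. ChIP signal
    tiles the genome at ``chip_tile`` resolution with fold enrichment
    mirroring the beta shape, scaled into a positive range.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    dips = _dip_regions(truth, config)
    rows = []
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom, 0, genome.chrom_length(chrom))
        pos = seq.find("CG")
        positions = []
        while pos != -1:
            positions.append(pos)
            pos = seq.find("CG", pos + 1)
        for p in positions:
            cov = int(rng.poisson(config.mean_coverage))
            beta = beta_at(chrom, p, dips, config)
            meth = int(rng.binomial(cov, beta)) if cov else 0
            rows.append(
                {
                    "chrom": chrom,
                    "position": p,
                    "strand": "+",
                    "n_methylated": meth,
                    "n_unmethylated": cov - meth,
                }
            )
    cpg = pd.DataFrame(rows)

    signals: list[SignalRecord] = []
    lo = max(0.0, config.baseline_beta - config.dip_depth)
    for chrom in genome.chrom_names:
        L = genome.chrom_length(chrom)
        for s in range(0, L - config.chip_tile + 1, config.chip_tile):
            centre = s + config.chip_tile // 2
            b = beta_at(chrom, centre, dips, config)
            # map beta range [lo, baseline] onto [chip_baseline - chip_dip, chip_baseline]
            frac = 0.0 if config.dip_depth == 0 else (config.baseline_beta - b) / config.dip_depth
            value = config.chip_baseline - config.chip_dip * frac
            signals.append(SignalRecord(chrom, s, s + config.chip_tile, value))
    return cpg, signals


def write_signal_bed(signals: Sequence[SignalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in signals:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.value:.4f}\n")


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k} = {v}\n")
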