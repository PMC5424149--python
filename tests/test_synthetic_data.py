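"""Simulator determinism, round-trips and ground-truth consistency."""

import numpy as np
import pytest

from irtools.genome_annotation import derive_introns, read_gtf, apply_feature_exclusions
from irtools.ir_quant import fragments_from_sam, quantify
from irtools.junction_metaprofile import compute_beta_table, read_cpg_table, write_cpg_table
from irtools.mappability import compute_mask
from irtools.synthetic_data import (
    SimulationConfig,
    simulate_fragments,
    simulate_genome_annotation,
    simulate_methylation,
    write_gtf,
    write_sam,
    write_signal_bed,
)


class TestGenomeAnnotation:
    def test_gene_structure(self):
        cfg = SimulationConfig(seed=1, n_genes=1, exons_per_gene=3)
        _, genes, truth = simulate_genome_annotation(cfg)
        assert len(genes[0].transcripts[0]) == 3
        assert len(truth.introns) == 2

    def test_same_seed_identical_fasta(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_genes=3)
        for name in ("a", "b"):
            genome, *_ = simulate_genome_annotation(cfg)
            genome.to_fasta(tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_planted_duplication_is_masked(self):
        cfg = SimulationConfig(seed=4, n_genes=1, exons_per_gene=2,
                               exon_length=(200, 300), intron_length=(300, 400),
                               duplication_block=200)
        genome, genes, truth = simulate_genome_annotation(cfg)
        chrom, src, dst, length = truth.duplication
        assert genome.sequence(chrom, src, src + length) == genome.sequence(chrom, dst, dst + length)
        mask = compute_mask(genome)
        assert mask.is_masked(chrom, src + length // 2)
        assert mask.is_masked(chrom, dst + length // 2)

    def test_foreign_features_inside_introns(self):
        cfg = SimulationConfig(seed=2, n_genes=2, n_foreign_features=2)
        _, genes, truth = simulate_genome_annotation(cfg)
        introns = derive_introns(genes)
        apply_feature_exclusions(introns, truth.foreign_features)
        excluded = [it for it in introns if it.excluded_spans]
        assert len(excluded) == 2
        for it in excluded:
            assert it.measurable_length < it.width

    def test_truth_labels_consistent(self):
        cfg = SimulationConfig(seed=3, n_genes=5)
        _, _, truth = simulate_genome_annotation(cfg)
        assert (truth.introns.retained == (truth.introns.true_r >= 0.1)).all()


class TestFragments:
    def test_r_zero_gives_ratio_zero(self):
        cfg = SimulationConfig(seed=5, n_genes=1, retention=0.0, fragments_per_gene=500)
        _, genes, truth = simulate_genome_annotation(cfg)
        introns = derive_introns(genes)
        frags = simulate_fragments(cfg, genes, truth)
        for q in quantify(frags, introns):
            assert q.ir_ratio == 0.0

    def test_r_one_gives_ratio_one(self):
        cfg = SimulationConfig(seed=5, n_genes=1, retention=1.0, fragments_per_gene=500)
        _, genes, truth = simulate_genome_annotation(cfg)
        introns = derive_introns(genes)
        frags = simulate_fragments(cfg, genes, truth)
        for q in quantify(frags, introns):
            assert q.splice_abundance == 0 and q.ir_ratio == 1.0

    def test_intermediate_r_recovered(self):
        cfg = SimulationConfig(seed=6, n_genes=1, exons_per_gene=2,
                               exon_length=(1000, 1000), intron_length=(200, 200),
                               retention=0.3, fragments_per_gene=5000)
        _, genes, truth = simulate_genome_annotation(cfg)
        introns = derive_introns(genes)
        (q,) = quantify(simulate_fragments(cfg, genes, truth), introns)
        assert abs(q.ir_ratio - 0.3) <= 0.05

    def test_fragment_longer_than_transcript_is_error(self):
        cfg = SimulationConfig(seed=5, n_genes=1, exons_per_gene=2,
                               exon_length=(40, 50), intron_length=(150, 150),
                               fragment_length=200, fragments_per_gene=10)
        _, genes, truth = simulate_genome_annotation(cfg)
        with pytest.raises(ValueError):
            simulate_fragments(cfg, genes, truth)

    def test_sam_roundtrip(self, tmp_path):
        """Fragments written as SAM re-parse with identical blocks."""
        cfg = SimulationConfig(seed=7, n_genes=2, fragments_per_gene=100)
        genome, genes, truth = simulate_genome_annotation(cfg)
        frags = simulate_fragments(cfg, genes, truth)
        path = tmp_path / "frags.sam"
        write_sam(frags, genome, path)
        back = fragments_from_sam(path)
        assert sorted(f.blocks[0] for f in back) == sorted(f.blocks[0] for f in frags)
        assert sorted(tuple(f.blocks) for f in back) == sorted(tuple(f.blocks) for f in frags)

    def test_retention_overrides(self):
        cfg = SimulationConfig(seed=8, n_genes=1, retention=0.0, fragments_per_gene=2000)
        _, genes, truth = simulate_genome_annotation(cfg)
        introns = derive_introns(genes)
        target = introns[0].intron_id
        frags = simulate_fragments(cfg, genes, truth, retention_overrides={target: 0.5})
        quants = {q.intron_id: q for q in quantify(frags, introns)}
        assert quants[target].ir_ratio > 0.3
        others = [q for i, q in quants.items() if i != target]
        assert all(q.ir_ratio == 0.0 for q in others)


class TestMethylation:
    def test_low_coverage_everywhere_yields_empty_beta_table(self):
        cfg = SimulationConfig(seed=9, n_genes=1, mean_coverage=0.5)
        genome, genes, truth = simulate_genome_annotation(cfg)
        cpg, _ = simulate_methylation(cfg, genome, truth)
        kept = compute_beta_table(cpg, min_coverage=6)
        assert len(kept) < 0.01 * len(cpg)

    def test_cpg_positions_are_cg_dinucleotides(self):
        cfg = SimulationConfig(seed=10, n_genes=1)
        genome, genes, truth = simulate_genome_annotation(cfg)
        cpg, _ = simulate_methylation(cfg, genome, truth)
        for row in cpg.head(50).itertuples():
            assert genome.sequence(row.chrom, row.position, row.position + 2) == "CG"

    def test_tsv_roundtrip_lossless(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_genes=1)
        genome, genes, truth = simulate_genome_annotation(cfg)
        cpg, signals = simulate_methylation(cfg, genome, truth)
        path = tmp_path / "cpg.tsv"
        write_cpg_table(cpg, path)
        back = read_cpg_table(path)
        assert (back.position.values == cpg.position.values).all()
        assert (back.n_methylated.values == cpg.n_methylated.values).all()
        write_signal_bed(signals, tmp_path / "chip.bed")

    def test_zero_dip_strata_indistinguishable(self):
        """With dip depth 0 the retained and non-retained metaprofiles carry
        no systematic difference (null calibration over seeds)."""
        from irtools.junction_metaprofile import stratified_profiles, paired_window_test

        insignificant = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_genes=25, dip_depth=0.0)
            genome, genes, truth = simulate_genome_annotation(cfg)
            introns = derive_introns(genes)
            cpg, _ = simulate_methylation(cfg, genome, truth)
            recs = compute_beta_table(cpg)
            labels = {r.intron_id: bool(r.retained) for r in truth.introns.itertuples()}
            ret, non = stratified_profiles(recs, introns, labels, "junction5")
            _, _, p = paired_window_test(ret, non)
            insignificant += p > 0.05
        assert insignificant >= 0.75 * n_seeds

    def test_determinism(self):
        cfg = SimulationConfig(seed=12, n_genes=2)
        genome, genes, truth = simulate_genome_annotation(cfg)
        a, _ = simulate_methylation(cfg, genome, truth)
        b, _ = simulate_methylation(cfg, genome, truth)
        assert a.equals(b)
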