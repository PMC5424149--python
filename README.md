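# irtools

Quantification and differential analysis of **intron retention (IR)** from
spliced RNA-seq alignments, with junction-centred epigenomic metaprofiles.

Intron retention — an intron surviving in the mature transcript — is a
widespread, regulated splicing outcome that often down-tunes gene
expression. Measuring it well requires care: intronic read depth is easily
confounded by poorly mappable sequence and by other genes transcribed
inside introns, and calling a *change* in retention between conditions is a
comparison of noisy digital counts. `irtools` packages that measurement
discipline for anyone analysing bulk RNA-seq alongside whole-genome
bisulfite or ChIP-seq data.

## What it computes

**Mappability mask.** Synthetic 70-nt reads are taken from the genome every
10 bp (every second one reverse-complemented, one substituted central
base) and re-aligned. Bases overlapped by fewer than 5 of the 7 possible
uniquely-mapping reads are poorly mappable and excluded from intronic
measurement.

**IR ratio.** For each intron *i* in sample *s*,

    IR_i = D_i / (D_i + S_i)

where `D_i` is the 30%-trimmed mean of per-base fragment depth over the
intron's measurable region (mask and foreign features removed) and `S_i`
is the splice abundance: the count of fragments whose alignment gap spans
the intron, taking the larger of the donor-anchored and acceptor-anchored
tallies. An intron with `IR ≥ 0.10` is called retained.

**Differential IR.** Counts are compared between two samples with the
exact Audic–Claverie test for digital counts,

    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)),

two-sided by doubling the smaller inclusive upper tail over the two sample
orderings (computed in log space). An intron is differential when
`p < 0.05`, splice abundance is above 10 in both samples, and the IR ratio
exceeds 0.1 in at least one. The excess of increased over decreased events
is tested with an exact binomial test.

**Metaprofiles.** Per-CpG beta values (coverage > 5 reads) or ChIP fold
enrichment are averaged in twenty 10-bp windows spanning ±100 bp of 5′ /
3′ splice junctions or intron midpoints, strand-aware, stratified by
retained vs non-retained; a paired t-test across the window pairs scores
the overall difference.

A fully deterministic simulator (`irtools.synthetic_data`) generates toy
genomes, annotation, spliced/retaining fragments at known true retention,
and methylation/ChIP tables with programmed junction dips, so the entire
pipeline runs and is validated without any external data.

## Worked example

```python
from irtools.synthetic_data import (SimulationConfig, simulate_genome_annotation,
                                    simulate_fragments)
from irtools.genome_annotation import derive_introns
from irtools.ir_quant import quantify
from irtools.differential_ir import run_differential

cfg = SimulationConfig(seed=42, n_genes=3, fragments_per_gene=3000)
genome, genes, truth = simulate_genome_annotation(cfg)
introns = derive_introns(genes)

f1 = simulate_fragments(cfg, genes, truth, "wt", seed=1)
shift = {i: min(1.0, truth.true_r(i) + 0.25)          # raise IR in two introns
         for i in list(truth.introns.intron_id)[:2]}
f2 = simulate_fragments(cfg, genes, truth, "ko", retention_overrides=shift, seed=2)

q1, q2 = quantify(f1, introns, "wt"), quantify(f2, introns, "ko")
for q, r in zip(q1, truth.introns.true_r):
    print(f"{q.intron_id:26s} true_r={r:.3f} ir={q.ir_ratio:.3f} splice={q.splice_abundance}")

table, summary = run_differential(q1, q2)
print(table[["intron_id", "ir_ratio_1", "ir_ratio_2", "p_value", "passes_filter"]])
```

prints

```
g1:I1:chr1:1795-2160       true_r=0.613 ir=0.614 splice=60
g1:I2:chr1:962-1222        true_r=0.702 ir=0.666 splice=52
g2:I1:chr1:3573-3855       true_r=0.416 ir=0.463 splice=57
g2:I2:chr1:4646-4980       true_r=0.666 ir=0.639 splice=46
g3:I1:chr1:7508-7771       true_r=0.146 ir=0.126 splice=136
g3:I2:chr1:6590-6772       true_r=0.055 ir=0.059 splice=136
           intron_id  ir_ratio_1  ir_ratio_2  p_value  passes_filter
g1:I1:chr1:1795-2160    0.613599    0.881490 0.009782           True
 g1:I2:chr1:962-1222    0.666152    0.978402 0.003849          False
g2:I1:chr1:3573-3855    0.462531    0.418930 0.686057          False
...
```

The quantified IR ratio tracks the simulated truth; the first shifted
intron is called differential, while the second — despite a smaller
p-value — fails the splice-abundance floor because near-complete retention
(IR → 0.98) leaves fewer than the required 10 spliced fragments in the
knockdown sample. The unshifted introns are not called.

The same pipeline is available from the shell:

```
irtools simulate --seed 5 --n-genes 6 --out-dir sim/
irtools mappability --genome sim/genome.fa --out-dir mask/
irtools quantify --gtf sim/annotation.gtf --sam sim/fragments.sam \
        --mask mask/mappability_mask.bed --sample-id s1 --out-dir quant/
irtools diff --quant1 quant/ir_quant_s1.tsv --quant2 ... --out-dir diff/
irtools metaprofile --gtf sim/annotation.gtf --quant quant/ir_quant_s1.tsv \
        --cpg sim/cpg_counts.tsv --out-dir profiles/
```

Every output directory receives a `manifest.json` with parameters, input
checksums and the tool version.

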