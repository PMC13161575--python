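# hapmeth

Haplotype-aware analysis of whole-genome bisulfite sequencing (WGBS) data:
weighted methylation levels, sliding-window calling of differentially
methylated regions (DMRs), allele-specific methylation (ASM) between the two
subgenomes of a hybrid, and the association between ASM and allele-specific
expression (ASE).

The package targets studies of interspecific hybrids with a
haplotype-resolved reference, where per-cytosine methylation calls are
available separately for the two parental subgenomes (here called HM and
HC) across developmental stages with replicate libraries, together with an
allele-pair map and per-allele expression (FPKM). Because such datasets are
rarely public, the package ships a first-class synthetic-data generator
that emulates the full study design — two haplotypes × five stages (LS1–LS5)
× three replicates — with planted, machine-readable ground truth, so every
stage of the pipeline is validated end to end.

## The statistics at the core

**Weighted methylation level.** For a region *R* and context
*c* ∈ {CG, CHG, CHH}, the level is Σᵢ mᵢ / Σᵢ nᵢ over covered cytosines
*i* of context *c* in *R* (mᵢ methylated reads, nᵢ total reads, cytosines
with nᵢ ≥ 4 only). Regions with no covered cytosine are *missing*, never 0.

**DMR calling.** For one pairwise comparison (replicate read counts pooled
per group), 200-bp windows advance in 50-bp steps. Each window with
coverage in both groups yields a two-sided Fisher's exact test on
[(m₁, n₁−m₁), (m₂, n₂−m₂)]; p-values are Benjamini–Hochberg adjusted per
context. Windows with FDR < 0.05 and level fold change ≥ 1.5 (max/min of
ε-shifted levels, ε = 0.01) are candidates. Cytosines inside candidate
windows are DMCs when the per-cytosine Fisher p ≤ 0.01, fold change ≥ 2 and
|Δ level| ≥ 0.4 (CG), 0.2 (CHG) or 0.1 (CHH). Overlapping candidate windows
collapse to runs; runs with ≥ 7 distinct DMCs are retained, and retained
regions of one context/direction separated by ≤ 100 bp merge. Genes whose
body (promoter 2 kb) overlaps a DMR are DMGs (DMPs).

**ASM and ASE.** ASM reuses the DMR machinery verbatim with group 1 = HC
libraries and group 2 = HM libraries on the homologous coordinates: an
allele pair is *a-biased* (HM hypermethylated) in a region and stage when a
retained hyper-DMR overlaps it. A pair shows *consistent* ASM when the same
direction is called at every stage. ASE per stage requires
mean(a)/mean(b) ≥ 2 and BH-adjusted Welch-t q < 0.05 on log2(FPKM+1).
The ASM–ASE association contrasts the per-pair methylation difference
(a − b) between ASE-bias groups with one-tailed t-tests in the repressive
direction.

## Worked example

```python
from hapmeth import (simulate_all, default_config, DifferentialMethylation,
                     AlleleSpecificMethylation)

res = simulate_all(default_config(seed=1))
filtered = {k: c[c["cov"] >= 4] for k, c in res.samples.items()}
g1 = [c for (h, s, r), c in sorted(filtered.items()) if s == "LS1"]
g2 = [c for (h, s, r), c in sorted(filtered.items()) if s == "LS5"]
fit = DifferentialMethylation(g1, g2, res.genome.contig_lengths,
                              name1="LS1", name2="LS5").fit()
print(fit.summary())
```

prints

```
Differential methylation: LS5 vs LS1
windows 200 bp / step 50 bp; FDR<0.05, FC>=1.5; DMC p<=0.01, FC>=2.0, |delta|>={'CG': 0.4, 'CHG': 0.2, 'CHH': 0.1}; >= 7 DMCs; merge <= 100 bp
context    tested  candidate    DMCs   hyper    hypo
CG          12000          0       0       0       0
CHG         12000          0       0       0       0
CHH         12000      11945   46147       6       4
```

The generator plants a genome-wide CHH rise across stages plus eight
CHH gene-body effects, and no CG/CHG stage effects: accordingly the LS5 vs
LS1 comparison finds differential methylation only in the CHH context —
nearly all CHH windows are candidates because of the global rise, and the
retained DMRs concentrate where planted effects push past the per-cytosine
gates. The haplotype comparison shows the opposite structure:

```python
asm = AlleleSpecificMethylation(filtered, res.genome.pairs,
                                res.genome.features, res.genome.contig_map,
                                res.genome.contig_lengths).fit()
print(asm.summary())
```

```
Allele-specific methylation (a = HM allele, b = HC allele)
CG   gene_body    records a/b  135/45   consistent a/b  27/9
CG   promoter2kb  records a/b  135/45   consistent a/b  27/9
CHG  gene_body    records a/b    0/0    consistent a/b   0/0
CHG  promoter2kb  records a/b    0/0    consistent a/b   0/0
CHH  gene_body    records a/b   20/20   consistent a/b   0/0
CHH  promoter2kb  records a/b   20/17   consistent a/b   0/0
```

Consistent ASM appears only in the CG context and is majority a-biased
(27 vs 9 pairs per region, 75%), mirroring the planted 3:1 HM bias; CHH
ASM records exist only in the stages where the planted stage-specific
effects are active, so none are consistent.

The same analyses are available from the shell:

```sh
hapmeth simulate --seed 1 --out run/
hapmeth dmr --calls-dir run/calls --gff run/genes.gff3 --te-bed run/te.bed \
        --group1 LS1 --group2 LS5 --out run/dmr
hapmeth asm --calls-dir run/calls --gff run/genes.gff3 \
        --pairs run/allele_pairs.tsv --out run/asm
hapmeth associate --calls-dir run/calls --gff run/genes.gff3 \
        --pairs run/allele_pairs.tsv --expression run/expression.tsv \
        --stage LS1 --out run/assoc
```

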