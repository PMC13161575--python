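# Methods

## Scope and model

`hapmeth` implements a haplotype-aware WGBS analysis for a two-subgenome
hybrid sampled over developmental stages. The observation unit is a
cytosine call: chromosome, 1-based position, strand, sequence context
(CG/CHG/CHH), methylated read count and total read count. Cytosines on the
two strands are independent records throughout; no CpG-dyad symmetrisation
is applied (a dialect choice — per-cytosine reporting matches the call
format the pipeline consumes). Input positions are 1-based; all internal
intervals are 0-based half-open; BED output is 0-based half-open and GFF
output 1-based closed.

Only cytosines with coverage ≥ 4 reads enter any level computation; the
threshold is exposed as `min_cov`.

"Methylation level" always means the *weighted* level Σmc/Σcov over the
covered cytosines of one context in a region — not the mean of
per-cytosine ratios — because it is robust at low coverage and additive
over disjoint regions (the property the window pooling and the region
summaries rely on). A region with no covered cytosine is reported missing
(NaN), never zero.

## Differential methylation

One comparison is two groups of replicate libraries. Replicates are pooled
by summing read counts per cytosine before testing: Fisher's exact test
needs a single 2×2 table per window, and the comparison of interest is
between conditions, not between replicates. Replicate-to-replicate
variance is instead exercised through the generator's overdispersion (see
below), which the downstream gates must tolerate.

The procedure and all constants:

| step | rule |
|---|---|
| windows | 200 bp, 50-bp step, trailing short windows kept (flagged) |
| window test | two-sided Fisher on pooled counts; windows lacking coverage in either group are skipped, not tested, so they never dilute the FDR |
| FDR | Benjamini–Hochberg per (comparison, context); q < 0.05 strictly |
| window fold change | (max+ε)/(min+ε) of the two levels, ε = 0.01; ≥ 1.5 |
| DMC | per-cytosine Fisher p ≤ 0.01, fold change ≥ 2, \|Δ\| ≥ 0.4 (CG) / 0.2 (CHG) / 0.1 (CHH); raw p, no FDR |
| retention | overlapping candidate windows of one context+direction collapse to runs; ≥ 7 distinct DMCs |
| merging | retained regions of one context+direction with gap ≤ 100 bp merge transitively left-to-right; DMC counts recomputed; merging never bridges directions |

The ε pseudocount keeps fold changes finite at level 0 and is exposed as a
flag. Boundary inclusivities are literal: q < 0.05 strict, FC ≥ 1.5,
p ≤ 0.01, \|Δ\| ≥ threshold, ≥ 7 DMCs, gap ≤ 100 inclusive.

A consequence worth knowing: a hyper-DMC starting from a high base level
can be impossible — from level 0.6 the maximum fold change is
1.01/0.61 ≈ 1.66 < 2 — so hyper calls require a low starting level. The
recovery benchmark plants level *pairs* (0.2↔0.6 CG, 0.1↔0.3 CHG,
0.05↔0.15 CHH) so both directions clear every gate.

### Exact-test implementation

The two-sided Fisher p-value sums all hypergeometric terms whose
probability does not exceed the observed one (relative tie tolerance
1+1e-7, the scipy/R convention). Because the pmf is unimodal, those terms
are the two tails outside a contiguous interval around the mode; the
implementation locates the interval with a vectorised binary search on the
log-pmf (shared log-factorial table) and sums the tails with the
hypergeometric CDF/SF. This makes a genome scan of tens of thousands of
windows with read counts in the thousands cost O(log support) per table.
Tests verify exact agreement with `scipy.stats.fisher_exact` and, for every
2×2 table with total ≤ 40, with exhaustive integer enumeration (where the
smallest relative gap between distinct hypergeometric terms is ~1.2e-3, so
the 1e-7 tie tolerance cannot misclassify a term).

BH adjustment is the step-up formula p·m/rank with suffix minima, capped at
1, stable-sorted; it is order-invariant and cross-checked against
statsmodels.

## Features and annotation

Gene models come from GFF3, TEs from BED6. Each gene contributes a
gene body, a strand-aware 2-kb promoter upstream of the TSS and a 2-kb
downstream flank past the TTS, clipped at contig edges (flagged
truncated). Intergenic is the residual complement. Classes may overlap and
a DMR is annotated with *every* kind it overlaps by ≥ 1 bp (no TE
precedence); genes whose body/promoter overlaps a DMR are DMGs/DMPs.

Metagene profiles length-normalise bodies into proportional bins
(default 20) and add fixed-width 2-kb flank bins; minus-strand targets are
reversed so bin 0 is always 5′. Replicates are averaged per bin by
default; pooling read counts across replicates is available
(`pool_replicates=True`) since conventions differ between studies.
Display tables report mean ± SD across the replicates; pooling is reserved
for hypothesis tests.

## ASM and ASE

ASM is defined as DMRs between alleles: the DMR machinery and thresholds
are reused verbatim with group 1 = HC and group 2 = HM libraries of one
stage, on the shared homologous coordinate system (allele regions are
compared coordinate-wise via the allele map; no realignment or liftover —
real-data liftover is out of scope). The scan is genome-wide per stage, so
the FDR family is all tested windows of a context, consistent with the
stage-comparison convention; a pair's region is then a-biased when a
retained hyper-DMR overlaps it by ≥ 1 bp (b-biased for hypo). A region
with no testable window is *untestable*, a distinct outcome from
*none* (testable, no bias) in every tally. A region-level Fisher variant
was considered and rejected to keep one set of thresholds; the window
route also preserves the ≥ 7-DMC evidence requirement.

Consistency: a pair shows consistent ASM in a (context, region) when the
same direction is called at *every* stage; any flip is inconsistent; 4/5
stages is not consistent.

ASE per (pair, stage): a-biased iff mean(a)/mean(b) ≥ 2 and BH-adjusted
(within stage) Welch t-test on log2(FPKM+1) replicate values gives
q < 0.05; symmetric for b; balanced otherwise; fewer than two replicates
per allele is untestable. The exact upstream ASE read-counting procedure
is study-specific; these thresholds are declared package defaults and all
three constants are exposed.

The ASM–ASE association groups pairs by ASE direction and tests the
methylation difference Δ = level(a) − level(b) with one-tailed one-sample
t-tests in the repressive direction (b-biased expression ⇒ Δ > 0,
a-biased ⇒ Δ < 0). Degenerate zero-variance groups receive the limiting
p-values (0.5 at Δ ≡ 0, else 0/1) rather than NaN. Overlap statistics are
\|ASM ∩ ASE\| / \|ASM\|.

## The synthetic-data generator

The generator emulates the study design the analysis assumes, with a
machine-readable truth ledger for every planted effect. What it models:

* **Design**: 2 haplotypes × 5 stages × 3 replicates; 1:1 allele gene
  pairs at homologous coordinates. The two haplotypes share one simulated
  sequence and identical gene models — divergence is modelled in
  methylation and expression, not sequence, which makes coordinate-wise
  allele comparison exact by construction.
* **Contexts from sequence**: cytosines and their CG/CHG/CHH contexts are
  scanned from the simulated sequence on both strands, so context
  proportions are sequence-consistent (≈ 1/4 CG, 3/16 CHG, 9/16 CHH of
  cytosines under uniform base composition).
* **True levels**: per-context baselines CG 0.60, CHG 0.35, CHH 0.08 —
  typical plant leaf methylome magnitudes, chosen once as generator
  defaults, not estimates; CHH gains +0.02 per stage (a clear but modest
  developmental rise); haplotype M carries a +0.05 genome-wide CG offset
  (subgenome imbalance large enough to dominate direction tallies but far
  below the 0.4 CG DMC gate, so consistent CG ASM comes only from planted
  region effects). Planted effects override the baseline inside their
  region; everything is clamped to [0, 1].
* **Observation model**: coverage ~ Poisson(30); methylated counts
  beta-binomial with dispersion ρ = 0.05 (mild replicate overdispersion, so
  Fisher pooling is exercised against realistic extra variance; ρ → 0
  recovers binomial). Cytosines drawing zero coverage are unobserved.
* **Planted structure (default configuration)**: 18 a-biased + 6 b-biased
  promoter CG ASM pairs and 9 + 3 gene-body pairs (3:1 HM bias, levels
  0.8 vs 0.2); coupled ASE with log2(a/b) = −4 × (promoter level
  difference), i.e. negative methylation–expression coupling; 4 hyper and
  4 hypo CHH gene-body regions active in LS4/LS5 with ∓1.5 log2 expression
  shifts. Expression baselines are log-normal (log2 mean 5, SD 1.5) with
  replicate noise SD 0.15 (log2).
* **Determinism**: one seed drives everything through spawned
  `SeedSequence` children per sample; identical seeds give byte-identical
  output files.

What it does **not** model: read-level data (no FASTQ), sequencing error,
incomplete bisulfite conversion, mapping bias between haplotypes, sequence
divergence between alleles, linked methylation (each cytosine's counts are
independent given its true level), or realistic gene-length/GC structure.
Passing tests therefore demonstrate the *statistical machinery* — error
control, thresholds, recovery, symmetry — under the declared generative
assumptions, not robustness to alignment artefacts or conversion failure
in real libraries.

## Problem sizes used in tests and the acceptance script

Chosen so the full validation runs comfortably on one CPU:

* **Null control**: 250-kb contig per haplotype, two stages, no planted
  effects, no offsets — 10,000 testable windows per context per run;
  20 seeds. Expected outcome: ~0 retained DMRs (the FC and DMC gates
  dominate; BH alone admits overdispersion-inflated windows, the gates
  remove them) and direction-balanced ASM counts.
* **Recovery benchmark**: 50 planted 400-bp regions (≥ 5 windows each, so
  merging is exercised), 5-kb spacing, alternating directions, one
  haplotype; coverage 30 (CG) or 60 (CHG/CHH).
* **Full-structure simulation**: 300-kb contig per haplotype, 45 gene
  pairs, all planted structure above.

## Known limitations

* The ASM caller assumes exact coordinate homology between haplotypes; on
  real assemblies an allele-aware liftover must precede it.
* Pooling replicates before Fisher discards replicate variance from the
  test itself; with strongly overdispersed data the window p-values are
  anti-conservative and error control rests on the fold-change and DMC
  gates (which the null sweep verifies under ρ = 0.05). A beta-binomial
  regression test would model this directly but is a different procedure.
* A genome-wide level shift (like the planted CHH rise) makes most windows
  of that context candidates, and retained DMRs can grow very large after
  merging; DMG sets then include many genes whose expression is not
  coupled to methylation. The expression contrast is reported with its
  group sizes for that reason.
* `intergenic` is defined relative to the annotated gene/TE set only.
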