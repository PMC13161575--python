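"""Synthetic two-haplotype methylome generator.

Emulates the data layout of a haplotype-resolved WGBS/RNA-seq study of an
interspecific hybrid: two parental subgenomes (HM, HC) carrying 1:1 allele
gene pairs at homologous coordinates, five leaf developmental stages
(LS1..LS5) with three replicate libraries each, and an FPKM expression table
per allele. The statistical structure mirrors what the analysis assumes:

* per-context baseline levels (CG high, CHG intermediate, CHH low) with the
  CHH level rising by a fixed increment per stage;
* a genome-wide CG offset on haplotype M (subgenome imbalance);
* planted differentially methylated regions, allele-biased (ASM) regions
  and allele-biased expression (ASE), with promoter-methylation bias and
  expression bias negatively coupled;
* beta-binomial read counts (Poisson coverage, configurable dispersion)
  so replicate variance is mildly overdispersed relative to binomial.

Sequence contexts are scanned from the simulated sequence itself, so
context proportions are sequence-consistent. Every planted effect is
recorded in a machine-readable :class:`TruthTable`. A fixed seed makes all
outputs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .io import CONTEXTS, STAGES

__all__ = [
    "SimConfig", "PlantedDMR", "PlantedASM", "PlantedASE", "Genome",
    "TruthTable", "SimulationResult", "simulate_genome_and_annotation",
    "simulate_methylomes", "simulate_expression", "simulate_all",
    "default_config", "null_config", "dmr_benchmark_config",
    "write_simulation",
]


@dataclass
class PlantedDMR:
    """A region whose true level switches between two values across stages.

    ``level1`` holds in all stages, except in ``stages2`` where ``level2``
    applies — so a comparison of a ``stages2`` member against any other
    stage sees a differential region. Coordinates are absolute on ``chrom``;
    alternatively ``pair_index``/``region``/``haplotype`` resolve to a gene
    feature at genome-build time. ``expr_log2fc`` shifts the owning gene's
    log2 expression in ``stages2`` (methylation-expression coupling).
    """

    context: str
    level1: float
    level2: float
    stages2: tuple[str, ...] = ("LS4", "LS5")
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    pair_index: int | None = None
    region: str = "gene_body"
    haplotype: str = "HM"
    expr_log2fc: float = 0.0

    @property
    def direction(self) -> str:
        return "hyper" if self.level2 > self.level1 else "hypo"


@dataclass
class PlantedASM:
    """An allele pair whose two members hold different levels in one region
    (all stages). ``level_a`` is the HM member; a-biased means a > b."""

    pair_index: int
    region: str
    context: str
    level_a: float
    level_b: float

    @property
    def direction(self) -> str:
        return "a-biased" if self.level_a > self.level_b else "b-biased"


@dataclass
class PlantedASE:
    """Fixed log2(a/b) expression ratio for one allele pair; ``coupled``
    marks ratios derived (with opposite sign) from a planted promoter
    methylation difference."""

    pair_index: int
    log2_ratio: float
    coupled: bool = False

    @property
    def direction(self) -> str:
        if self.log2_ratio > 0:
            return "a-biased"
        return "b-biased" if self.log2_ratio < 0 else "balanced"


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions the
    analysis is exercised under (see docs/methods.md for rationale)."""

    seed: int = 1
    contig_length: int = 300_000
    n_contigs: int = 1
    haplotypes: tuple[str, ...] = ("HM", "HC")
    stages: tuple[str, ...] = STAGES
    n_replicates: int = 3
    n_genes: int = 45
    gene_length: int = 2000
    flank: int = 2000
    te_fraction: float = 0.05
    te_length: int = 500
    mean_coverage: float = 30.0
    base_levels: dict = field(default_factory=lambda: {
        "CG": 0.60, "CHG": 0.35, "CHH": 0.08})
    chh_stage_increment: float = 0.02
    hm_cg_offset: float = 0.05
    dispersion: float = 0.05
    expression_log2_mean: float = 5.0
    expression_log2_sd: float = 1.5
    expression_noise_sd: float = 0.15
    planted_dmrs: list = field(default_factory=list)
    planted_asm: list = field(default_factory=list)
    planted_ase: list = field(default_factory=list)

    def validate(self) -> None:
        slot = (self.contig_length - 2 * self.flank) // max(
            1, -(-self.n_genes // self.n_contigs))
        if slot < self.gene_length + 2 * self.flank:
            raise ValueError(
                f"{self.n_genes} genes of {self.gene_length} bp plus "
                f"{self.flank} bp flanks do not fit {self.n_contigs} "
                f"contig(s) of {self.contig_length} bp")
        for name, v in (("te_fraction", self.te_fraction),
                        ("dispersion", self.dispersion)):
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        for lv in self.base_levels.values():
            if not (0 <= lv <= 1):
                raise ValueError("base levels must be in [0, 1]")


@dataclass
class Genome:
    """Simulated haplotype pair: sequences, cytosine inventory, features."""

    sequences: dict  # chrom -> str
    contig_lengths: dict
    cytosines: dict  # chrom -> DataFrame(pos, strand, context)
    features: pd.DataFrame
    pairs: pd.DataFrame
    contig_map: list  # (shared name, HM chrom, HC chrom)


@dataclass
class TruthTable:
    """Machine-readable ledger of every planted effect."""

    dmrs: pd.DataFrame
    asm: pd.DataFrame
    ase: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k).to_dict(orient="records")
                   for k in ("dmrs", "asm", "ase")}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def write_tsv(self, directory) -> None:
        directory = Path(directory)
        for k in ("dmrs", "asm", "ase"):
            getattr(self, k).to_csv(directory / f"truth_{k}.tsv", sep="\t",
                                    index=False)


@dataclass
class SimulationResult:
    config: SimConfig
    genome: Genome
    samples: dict  # (haplotype, stage, replicate) -> calls DataFrame
    expression: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _scan_contexts(codes: np.ndarray) -> pd.DataFrame:
    """Cytosine positions, strands and contexts from integer base codes
    (A=0, C=1, G=2, T=3). Contig-edge cytosines with incomplete context
    are skipped."""
    L = codes.shape[0]
    rows = []
    # plus strand: C at i, context from i+1, i+2
    ip = np.flatnonzero(codes == 1)
    ip = ip[ip + 1 < L]
    nxt = codes[ip + 1]
    cg = nxt == 2
    rest = ip[~cg]
    rest = rest[rest + 2 < L]
    chg = codes[rest + 2] == 2
    rows.append((ip[cg], "+", "CG"))
    rows.append((rest[chg], "+", "CHG"))
    rows.append((rest[~chg], "+", "CHH"))
    # minus strand: G at i, context from i-1, i-2 (complemented)
    im = np.flatnonzero(codes == 2)
    im = im[im - 1 >= 0]
    prv = codes[im - 1]
    cg = prv == 1
    rest = im[~cg]
    rest = rest[rest - 2 >= 0]
    chg = codes[rest - 2] == 1
    rows.append((im[cg], "-", "CG"))
    rows.append((rest[chg], "-", "CHG"))
    rows.append((rest[~chg], "-", "CHH"))
    frames = [pd.DataFrame({"pos": p, "strand": s, "context": c})
              for p, s, c in rows if p.size]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["pos", "strand", "context"])
    return out.sort_values(["pos", "strand"], ignore_index=True)


def simulate_genome_and_annotation(config: SimConfig) -> Genome:
    """Generate the haplotype pair, gene/TE annotation and allele map.

    The two haplotypes share one sequence and identical gene models at
    homologous coordinates (the generator models divergence in methylation
    and expression, not in sequence), so allele regions can be compared
    coordinate-wise without liftover. Gene ids are ``gM####``/``gC####``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sequences: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    cytosines: dict[str, pd.DataFrame] = {}
    feat_rows = []
    pair_rows = []
    contig_map = []
    genes_per_contig = -(-config.n_genes // config.n_contigs)
    gene_no = 0
    for ci in range(config.n_contigs):
        codes = rng.integers(0, 4, size=config.contig_length, dtype=np.uint8)
        seq = _BASES[codes].tobytes().decode()
        cyt = _scan_contexts(codes)
        shared = f"chr{ci + 1}"
        hm_chrom = f"HM_{shared}"
        hc_chrom = f"HC_{shared}"
        contig_map.append((shared, hm_chrom, hc_chrom))
        for chrom in (hm_chrom, hc_chrom):
            sequences[chrom] = seq
            contig_lengths[chrom] = config.contig_length
            cytosines[chrom] = cyt.copy()
        n_here = min(genes_per_contig, config.n_genes - ci * genes_per_contig)
        slot = (config.contig_length - 2 * config.flank) // max(n_here, 1)
        spans = []
        for gi in range(n_here):
            gene_no += 1
            start = config.flank + 500 + gi * slot
            end = start + config.gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            a_id, b_id = f"gM{gene_no:04d}", f"gC{gene_no:04d}"
            pair_rows.append((f"{a_id}|{b_id}", a_id, b_id, hm_chrom, hc_chrom,
                              start, end, strand))
            for hap, chrom, gid in (("HM", hm_chrom, a_id), ("HC", hc_chrom, b_id)):
                feat_rows.append((chrom, start, end, strand, "gene_body", gid,
                                  hap, False))
                if strand == "+":
                    ps, pe = start - config.flank, start
                    ds, de = end, end + config.flank
                else:
                    ps, pe = end, end + config.flank
                    ds, de = start - config.flank, start
                feat_rows.append((chrom, max(0, ps), pe, strand, "promoter2kb",
                                  gid, hap, ps < 0))
                feat_rows.append((chrom, ds, min(config.contig_length, de),
                                  strand, "downstream2kb", gid, hap,
                                  de > config.contig_length))
            spans.append((start - config.flank, end + config.flank))
        # TEs in the gaps between gene spans, until the bp budget is spent
        te_budget = int(config.te_fraction * config.contig_length)
        te_no = 0
        gaps = []
        cursor = 0
        for s, e in sorted(spans):
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < config.contig_length:
            gaps.append((cursor, config.contig_length))
        placed = 0
        for gs, ge in gaps:
            p = gs + 50
            while p + config.te_length <= ge - 50 and placed < te_budget:
                te_no += 1
                for hap, chrom in (("HM", hm_chrom), ("HC", hc_chrom)):
                    feat_rows.append((chrom, p, p + config.te_length, "+",
                                      "TE", f"TE{ci + 1}_{te_no:04d}", hap, False))
                placed += config.te_length
                p += config.te_length + 300
            if placed >= te_budget:
                break
    features = pd.DataFrame(feat_rows, columns=[
        "chrom", "start", "end", "strand", "kind", "gene_id", "haplotype",
        "truncated"])
    # intergenic residual per contig
    inter = []
    for chrom, clen in contig_lengths.items():
        sub = features[features["chrom"] == chrom]
        from .io import _complement
        for s, e in _complement(sub[["start", "end"]].to_numpy(np.int64), clen):
            inter.append((chrom, s, e, ".", "intergenic", None,
                          mio.infer_haplotype(chrom), False))
    features = pd.concat([features, pd.DataFrame(inter, columns=features.columns)],
                         ignore_index=True)
    pairs = pd.DataFrame(pair_rows, columns=[
        "pair_id", "a", "b", "chrom_a", "chrom_b", "start", "end", "strand"])
    return Genome(sequences, contig_lengths, cytosines, features, pairs,
                  contig_map)


# ---------------------------------------------------------------------------
# Planted-effect resolution and truth ledger
# ---------------------------------------------------------------------------

def _resolve_region(genome: Genome, pair_index: int, region: str,
                    haplotype: str) -> tuple[str, int, int, str]:
    pair = genome.pairs.iloc[pair_index]
    gid = pair["a"] if haplotype == "HM" else pair["b"]
    feat = genome.features[(genome.features["gene_id"] == gid)
                           & (genome.features["kind"] == region)]
    if feat.empty:
        raise ValueError(f"pair {pair_index}: no {region} feature for {gid}")
    r = feat.iloc[0]
    return r["chrom"], int(r["start"]), int(r["end"]), gid


def build_truth(config: SimConfig, genome: Genome) -> TruthTable:
    """Resolve planted effects to coordinates and assemble the ledger."""
    dmr_rows = []
    for d in config.planted_dmrs:
        if d.chrom is None:
            chrom, start, end, gid = _resolve_region(
                genome, d.pair_index, d.region, d.haplotype)
        else:
            chrom, start, end, gid = d.chrom, d.start, d.end, None
        if chrom not in genome.contig_lengths or \
                not (0 <= start < end <= genome.contig_lengths[chrom]):
            raise ValueError(f"planted DMR outside simulated coordinates: "
                             f"{chrom}:{start}-{end}")
        dmr_rows.append((chrom, start, end, d.context, d.direction,
                         d.level1, d.level2, ",".join(d.stages2), gid,
                         d.expr_log2fc))
    asm_rows = []
    for a in config.planted_asm:
        chrom_a, start, end, gid_a = _resolve_region(
            genome, a.pair_index, a.region, "HM")
        chrom_b, _, _, gid_b = _resolve_region(
            genome, a.pair_index, a.region, "HC")
        pair_id = genome.pairs.iloc[a.pair_index]["pair_id"]
        asm_rows.append((pair_id, gid_a, gid_b, a.region, a.context,
                         a.direction, a.level_a, a.level_b, chrom_a, chrom_b,
                         start, end))
    ase_rows = []
    for e in config.planted_ase:
        pair_id = genome.pairs.iloc[e.pair_index]["pair_id"]
        ase_rows.append((pair_id, e.log2_ratio, e.direction, e.coupled))
    return TruthTable(
        dmrs=pd.DataFrame(dmr_rows, columns=[
            "chrom", "start", "end", "context", "direction", "level1",
            "level2", "stages2", "gene_id", "expr_log2fc"]),
        asm=pd.DataFrame(asm_rows, columns=[
            "pair_id", "gene_a", "gene_b", "region", "context", "direction",
            "level_a", "level_b", "chrom_a", "chrom_b", "start", "end"]),
        ase=pd.DataFrame(ase_rows, columns=[
            "pair_id", "log2_ratio", "direction", "coupled"]),
    )


# ---------------------------------------------------------------------------
# Methylomes and expression
# ---------------------------------------------------------------------------

def _true_levels(config: SimConfig, genome: Genome, truth: TruthTable,
                 chrom: str, stage: str) -> np.ndarray:
    cyt = genome.cytosines[chrom]
    ctx = cyt["context"].to_numpy()
    pos = cyt["pos"].to_numpy()
    level = np.empty(len(cyt), dtype=np.float64)
    for c in CONTEXTS:
        level[ctx == c] = config.base_levels[c]
    stage_idx = config.stages.index(stage)
    level[ctx == "CHH"] += config.chh_stage_increment * stage_idx
    if mio.infer_haplotype(chrom) == "HM":
        level[ctx == "CG"] += config.hm_cg_offset
    for d in truth.dmrs.itertuples(index=False):
        if d.chrom != chrom:
            continue
        mask = (ctx == d.context) & (pos >= d.start) & (pos < d.end)
        level[mask] = d.level2 if stage in d.stages2.split(",") else d.level1
    hap = mio.infer_haplotype(chrom)
    for a in truth.asm.itertuples(index=False):
        tchrom = a.chrom_a if hap == "HM" else a.chrom_b
        if tchrom != chrom:
            continue
        mask = (ctx == a.context) & (pos >= a.start) & (pos < a.end)
        level[mask] = a.level_a if hap == "HM" else a.level_b
    return np.clip(level, 0.0, 1.0)


def _beta_binomial(rng: np.random.Generator, cov: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(cov, p)
    pp = p.copy()
    interior = (p > 0) & (p < 1)
    a = p[interior] * (1 - rho) / rho
    b = (1 - p[interior]) * (1 - rho) / rho
    pp[interior] = rng.beta(a, b)
    return rng.binomial(cov, pp)


def simulate_methylomes(config: SimConfig, genome: Genome,
                        truth: TruthTable | None = None) -> dict:
    """Per-cytosine call tables for every (haplotype, stage, replicate).

    Observed counts: coverage ~ Poisson(mean_coverage); methylated reads ~
    beta-binomial around the cytosine's true level with the configured
    dispersion. Cytosines drawing zero coverage are omitted (unobserved).
    """
    if truth is None:
        truth = build_truth(config, genome)
    ss = np.random.SeedSequence((config.seed, 1))
    keys = [(hap, stage, rep)
            for hap in config.haplotypes
            for stage in config.stages
            for rep in range(1, config.n_replicates + 1)]
    children = ss.spawn(len(keys))
    samples: dict[tuple, pd.DataFrame] = {}
    level_cache: dict[tuple, np.ndarray] = {}
    for key, child in zip(keys, children):
        hap, stage, rep = key
        rng = np.random.default_rng(child)
        frames = []
        for shared, hm_chrom, hc_chrom in genome.contig_map:
            chrom = hm_chrom if hap == "HM" else hc_chrom
            if chrom not in genome.cytosines:
                continue
            ck = (chrom, stage)
            if ck not in level_cache:
                level_cache[ck] = _true_levels(config, genome, truth, chrom, stage)
            level = level_cache[ck]
            cyt = genome.cytosines[chrom]
            cov = rng.poisson(config.mean_coverage, size=len(cyt))
            mc = _beta_binomial(rng, cov, level, config.dispersion)
            keep = cov > 0
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": cyt["pos"].to_numpy()[keep],
                "strand": cyt["strand"].to_numpy()[keep],
                "context": cyt["context"].to_numpy()[keep],
                "mc": mc[keep].astype(np.int64),
                "cov": cov[keep].astype(np.int64),
            }))
        samples[key] = pd.concat(frames, ignore_index=True)
    return samples


def simulate_expression(config: SimConfig, genome: Genome,
                        truth: TruthTable | None = None) -> pd.DataFrame:
    """FPKM table (gene x stage x replicate) honouring planted ASE ratios
    and any methylation-expression coupling of planted DMRs."""
    if truth is None:
        truth = build_truth(config, genome)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    pairs = genome.pairs
    base = rng.normal(config.expression_log2_mean, config.expression_log2_sd,
                      size=len(pairs))
    ratio = np.zeros(len(pairs))
    by_pair = {pid: i for i, pid in enumerate(pairs["pair_id"])}
    for e in truth.ase.itertuples(index=False):
        ratio[by_pair[e.pair_id]] = e.log2_ratio
    dmr_shift: dict[tuple, float] = {}
    for d in truth.dmrs.itertuples(index=False):
        if d.gene_id is None or not d.expr_log2fc:
            continue
        for stage in d.stages2.split(","):
            k = (d.gene_id, stage)
            dmr_shift[k] = dmr_shift.get(k, 0.0) + d.expr_log2fc
    cols = [(stage, rep) for stage in config.stages
            for rep in range(1, config.n_replicates + 1)]
    data = {}
    gene_ids = []
    log2 = {}
    for i, pair in enumerate(pairs.itertuples(index=False)):
        log2[pair.a] = base[i] + ratio[i] / 2.0
        log2[pair.b] = base[i] - ratio[i] / 2.0
        gene_ids.extend([pair.a, pair.b])
    noise = rng.normal(0.0, config.expression_noise_sd,
                       size=(len(gene_ids), len(cols)))
    values = np.empty((len(gene_ids), len(cols)))
    for gi, gid in enumerate(gene_ids):
        for cj, (stage, rep) in enumerate(cols):
            x = log2[gid] + dmr_shift.get((gid, stage), 0.0) + noise[gi, cj]
            values[gi, cj] = 2.0 ** x
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=pd.MultiIndex.from_tuples(
                            cols, names=["stage", "replicate"]))
    return expr


def simulate_all(config: SimConfig) -> SimulationResult:
    """Genome, truth ledger, methylomes and expression in one call."""
    genome = simulate_genome_and_annotation(config)
    truth = build_truth(config, genome)
    samples = simulate_methylomes(config, genome, truth)
    expression = simulate_expression(config, genome, truth)
    return SimulationResult(config, genome, samples, expression, truth)


# ---------------------------------------------------------------------------
# Canned configurations (the study conditions)
# ---------------------------------------------------------------------------

def default_config(seed: int = 1) -> SimConfig:
    """Full-structure simulation: 2 haplotypes x 5 stages x 3 replicates.

    Plants (all CG unless noted): 18 a-biased + 6 b-biased promoter ASM
    pairs and 9 a-biased + 3 b-biased gene-body ASM pairs (3:1 HM bias,
    levels 0.8 vs 0.2); coupled ASE with log2(a/b) = -4 x (promoter level
    difference); 4 hyper + 4 hypo CHH gene-body DMRs active in LS4/LS5 with
    repressive (resp. activating) expression shifts.
    """
    cfg = SimConfig(seed=seed)
    asm, ase = [], []
    idx = 0
    for region, n_a, n_b in (("promoter2kb", 18, 6), ("gene_body", 9, 3)):
        for j in range(n_a + n_b):
            a_biased = j < n_a
            la, lb = (0.8, 0.2) if a_biased else (0.2, 0.8)
            asm.append(PlantedASM(idx, region, "CG", la, lb))
            if region == "promoter2kb":
                ase.append(PlantedASE(idx, -4.0 * (la - lb), coupled=True))
            idx += 1
    dmrs = []
    for j in range(8):
        hyper = j < 4
        l1, l2 = (0.05, 0.30) if hyper else (0.30, 0.05)
        dmrs.append(PlantedDMR(
            context="CHH", level1=l1, level2=l2, stages2=("LS4", "LS5"),
            pair_index=idx, region="gene_body", haplotype="HM",
            expr_log2fc=-1.5 if hyper else 1.5))
        idx += 1
    cfg.planted_asm = asm
    cfg.planted_ase = ase
    cfg.planted_dmrs = dmrs
    return cfg


def null_config(seed: int = 1) -> SimConfig:
    """Exchangeable-null simulation: no planted effects, no stage trend, no
    haplotype offset; two stages suffice for a pairwise comparison. The
    contig length yields ~10,000 windows per context across the two
    haplotypes."""
    return SimConfig(
        seed=seed, contig_length=250_000, n_genes=30,
        stages=("LS1", "LS5"), chh_stage_increment=0.0, hm_cg_offset=0.0,
        te_fraction=0.0,
    )


#: Planted (level1, level2) pairs per context for the recovery benchmark;
#: chosen so both directions clear the published per-cytosine gates
#: (|delta| and the fold-change >= 2 with the 0.01 pseudocount).
_BENCH_LEVELS = {
    "CG": (0.20, 0.60),
    "CHG": (0.10, 0.30),
    "CHH": (0.05, 0.15),
}

_BENCH_COVERAGE = {"CG": 30.0, "CHG": 60.0, "CHH": 60.0}


def dmr_benchmark_config(context: str, seed: int = 1, n_dmrs: int = 50,
                         dmr_width: int = 400) -> SimConfig:
    """Recovery benchmark: ``n_dmrs`` planted 400-bp regions of one context
    on a single haplotype, alternating hyper/hypo, active in LS5."""
    lo, hi = _BENCH_LEVELS[context]
    spacing = 5000
    length = n_dmrs * spacing + 5000
    cfg = SimConfig(
        seed=seed, contig_length=length, haplotypes=("HM",),
        stages=("LS1", "LS5"), n_genes=min(20, (length - 4000) // 6500),
        te_fraction=0.0,
        mean_coverage=_BENCH_COVERAGE[context], hm_cg_offset=0.0,
        chh_stage_increment=0.0,
    )
    for i in range(n_dmrs):
        start = 2500 + i * spacing
        l1, l2 = (lo, hi) if i % 2 == 0 else (hi, lo)
        cfg.planted_dmrs.append(PlantedDMR(
            context=context, level1=l1, level2=l2, stages2=("LS5",),
            chrom="HM_chr1", start=start, end=start + dmr_width))
    return cfg


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_simulation(result: SimulationResult, outdir) -> dict:
    """Write FASTA, GFF3, TE BED, allele map, call files, expression and
    truth ledger under ``outdir``; returns a manifest of paths."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = result.genome
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sorted(genome.sequences.items())]
    fasta = outdir / "genome.fa"
    SeqIO.write(records, str(fasta), "fasta")
    gff = outdir / "genes.gff3"
    mio.write_annotations_gff(genome.features, genome.contig_lengths, gff)
    bed = outdir / "te.bed"
    mio.write_te_bed(genome.features, bed)
    amap = outdir / "allele_pairs.tsv"
    mio.write_allele_pairs(genome.pairs, amap)
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    call_paths = {}
    for (hap, stage, rep), calls in sorted(result.samples.items()):
        p = calls_dir / f"{hap}_{stage}_rep{rep}.meth.tsv"
        mio.write_meth_calls(calls, p)
        call_paths[f"{hap}_{stage}_rep{rep}"] = str(p)
    expr = outdir / "expression.tsv"
    mio.write_expression(result.expression, expr)
    result.truth.to_json(outdir / "truth.json")
    result.truth.write_tsv(outdir)
    config = outdir / "sim_config.json"
    config.write_text(json.dumps(dataclasses.asdict(result.config),
                                 default=str, indent=1, sort_keys=True))
    return {"fasta": str(fasta), "gff": str(gff), "te_bed": str(bed),
            "allele_pairs": str(amap), "expression": str(expr),
            "calls": call_paths, "config": str(config)}
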