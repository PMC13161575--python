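"""Allele-specific methylation (ASM) and allele-specific expression (ASE).

ASM between the two subgenome haplotypes is called with the same machinery
and thresholds as stage-wise DMRs: per developmental stage, the haplotype-C
replicate libraries (group 1) are compared against the haplotype-M
libraries (group 2) on the shared homologous coordinate system, and an
allele pair is a-biased (HM hypermethylated) in a region when a retained
hyper-DMR overlaps it, b-biased for a hypo-DMR. A region with no testable
window is "untestable" — distinct from "none" (testable, no bias).

A pair shows *consistent* ASM in a (context, region) when the same bias
direction is called at every developmental stage.

ASE per stage uses the replicate FPKM values: a pair is a-biased when
mean(a)/mean(b) >= 2 and the BH-adjusted two-sample t-test on log2(FPKM+1)
gives q < 0.05 (symmetrically b-biased), otherwise balanced. The ASM-ASE
association contrasts the allele methylation difference (a - b) between
ASE-bias groups with one-tailed t-tests in the repressive direction:
b-biased expression is expected alongside higher HM methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import DifferentialMethylation, DMRParams
from .exact import bh_adjust
from .io import CONTEXTS

ASM_REGIONS = ("gene_body", "promoter2kb")


def remap_chrom(calls: pd.DataFrame, chrom_map: dict[str, str]) -> pd.DataFrame:
    out = calls.copy()
    out["chrom"] = out["chrom"].map(chrom_map)
    return out[out["chrom"].notna()]


class AlleleSpecificMethylation:
    """ASM model: haplotype-resolved call tables + allele map + features.

    Parameters
    ----------
    samples
        Mapping ``(haplotype, stage, replicate) -> call table`` with
        haplotype-specific chromosome names.
    pairs
        Allele map with pair_id, a (HM gene), b (HC gene) columns.
    features
        Feature annotation carrying gene_body/promoter2kb intervals for
        both haplotypes' gene models.
    contig_map
        Triplets ``(shared_name, HM_chrom, HC_chrom)`` defining the
        homologous coordinate system (identical coordinates assumed; no
        liftover is performed).
    contig_lengths
        Haplotype-specific contig lengths (only the shared value is used).
    params
        DMR thresholds, reused verbatim for ASM.
    """

    def __init__(self, samples, pairs, features, contig_map, contig_lengths,
                 params: DMRParams | None = None, contexts=CONTEXTS,
                 regions=ASM_REGIONS, stages=None):
        self.samples = samples
        self.pairs = pairs
        self.features = features
        self.contig_map = list(contig_map)
        self.params = params or DMRParams()
        self.contexts = tuple(contexts)
        self.regions = tuple(regions)
        self.stages = tuple(stages) if stages is not None else tuple(sorted(
            {stage for (_, stage, _) in samples}))
        self.hm_map = {hm: shared for shared, hm, _ in self.contig_map}
        self.hc_map = {hc: shared for shared, _, hc in self.contig_map}
        self.shared_lengths = {}
        for shared, hm, hc in self.contig_map:
            if hm in contig_lengths:
                self.shared_lengths[shared] = contig_lengths[hm]
            elif hc in contig_lengths:  # pragma: no cover
                self.shared_lengths[shared] = contig_lengths[hc]

    def fit(self) -> "ASMResults":
        # per-pair regions on the shared coordinates (HM gene model)
        feats = self.features
        region_of = {}
        for pair in self.pairs.itertuples(index=False):
            for kind in self.regions:
                f = feats[(feats["gene_id"] == pair.a) & (feats["kind"] == kind)]
                if f.empty:
                    continue
                r = f.iloc[0]
                region_of[(pair.pair_id, kind)] = (
                    self.hm_map.get(r["chrom"], r["chrom"]),
                    int(r["start"]), int(r["end"]))
        records = []
        stage_fits = {}
        for stage in self.stages:
            group_hc = [remap_chrom(calls, self.hc_map)
                        for (hap, s, _), calls in sorted(self.samples.items())
                        if s == stage and hap == "HC"]
            group_hm = [remap_chrom(calls, self.hm_map)
                        for (hap, s, _), calls in sorted(self.samples.items())
                        if s == stage and hap == "HM"]
            model = DifferentialMethylation(
                group_hc, group_hm, self.shared_lengths, params=self.params,
                contexts=self.contexts, name1="allele_b", name2="allele_a")
            res = model.fit()
            stage_fits[stage] = res
            tested = res.windows
            dmrs = res.dmrs
            for (pair_id, kind), (chrom, start, end) in region_of.items():
                for ctx in self.contexts:
                    sub_t = tested[(tested["chrom"] == chrom)
                                   & (tested["context"] == ctx)
                                   & (tested["start"] < end)
                                   & (tested["end"] > start)]
                    if sub_t.empty:
                        records.append((pair_id, stage, ctx, kind,
                                        "untestable", 0, np.nan, np.nan))
                        continue
                    hit = dmrs[(dmrs["chrom"] == chrom)
                               & (dmrs["context"] == ctx)
                               & (dmrs["start"] < end) & (dmrs["end"] > start)] \
                        if not dmrs.empty else dmrs
                    delta = _region_delta(sub_t)
                    if hit is None or hit.empty:
                        records.append((pair_id, stage, ctx, kind, "none",
                                        0, np.nan, delta))
                        continue
                    overlap = (np.minimum(hit["end"], end)
                               - np.maximum(hit["start"], start))
                    best = hit.iloc[int(np.argmax(overlap.to_numpy()
                                                  + hit["n_dmcs"].to_numpy() * 1e-9))]
                    direction = "a-biased" if best["direction"] == "hyper" \
                        else "b-biased"
                    records.append((pair_id, stage, ctx, kind, direction,
                                    int(best["n_dmcs"]),
                                    float(sub_t["q_value"].min()), delta))
        rec = pd.DataFrame(records, columns=[
            "pair_id", "stage", "context", "region", "status", "n_dmcs",
            "q_min", "delta"])
        return ASMResults(model=self, records=rec, stage_fits=stage_fits)


def _region_delta(tested_windows: pd.DataFrame) -> float:
    """Weighted level difference (allele a minus allele b) over the tested
    windows of a region (window counts pooled; windows overlap but the bias
    estimate only needs to be monotone in the true difference)."""
    cov1 = tested_windows["cov1"].sum()
    cov2 = tested_windows["cov2"].sum()
    if cov1 == 0 or cov2 == 0:
        return float("nan")
    return float(tested_windows["mc2"].sum() / cov2
                 - tested_windows["mc1"].sum() / cov1)


def consistency_classify(statuses: list[str], n_stages: int) -> str:
    """Classification of one pair/(context, region) across stages."""
    biased = [s for s in statuses if s in ("a-biased", "b-biased")]
    if not biased:
        return "none"
    if len(biased) == n_stages and len(set(biased)) == 1:
        return f"consistent {biased[0]}"
    return "inconsistent"


def count_bias(records: pd.DataFrame, stage: str | None = None,
               context: str | None = None, region: str | None = None
               ) -> tuple[int, int]:
    """(a-biased, b-biased) tallies over the selected records."""
    sub = records
    for col, v in (("stage", stage), ("context", context), ("region", region)):
        if v is not None:
            sub = sub[sub[col] == v]
    col = "status" if "status" in sub.columns else "direction"
    return int((sub[col] == "a-biased").sum()), int((sub[col] == "b-biased").sum())


@dataclass
class ASMResults:
    model: AlleleSpecificMethylation
    records: pd.DataFrame
    stage_fits: dict

    def consistency(self) -> pd.DataFrame:
        """Cross-stage classification per (pair, context, region)."""
        n_stages = len(self.model.stages)
        rows = []
        for (pair_id, ctx, region), grp in self.records.groupby(
                ["pair_id", "context", "region"], observed=True):
            label = consistency_classify(grp["status"].tolist(), n_stages)
            rows.append((pair_id, ctx, region, label))
        return pd.DataFrame(rows, columns=["pair_id", "context", "region",
                                           "classification"])

    def counts(self, stage=None, context=None, region=None) -> tuple[int, int]:
        return count_bias(self.records, stage, context, region)

    def membership(self, context: str, region: str) -> pd.DataFrame:
        """Pair x stage matrix of bias direction (upset/Venn export)."""
        sub = self.records[(self.records["context"] == context)
                           & (self.records["region"] == region)]
        return sub.pivot_table(index="pair_id", columns="stage",
                               values="status", aggfunc="first")

    def summary(self) -> str:
        lines = ["Allele-specific methylation (a = HM allele, b = HC allele)"]
        cons = self.consistency()
        for ctx in self.model.contexts:
            for region in self.model.regions:
                a, b = self.counts(context=ctx, region=region)
                sub = cons[(cons["context"] == ctx) & (cons["region"] == region)]
                ca = int((sub["classification"] == "consistent a-biased").sum())
                cb = int((sub["classification"] == "consistent b-biased").sum())
                lines.append(f"{ctx:<4} {region:<12} records a/b {a:>4}/{b:<4}"
                             f" consistent a/b {ca:>3}/{cb:<3}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Allele-specific expression
# ---------------------------------------------------------------------------

class AlleleSpecificExpression:
    """ASE model over an FPKM table and the allele map.

    Per stage and pair: direction a-biased when mean(a)/mean(b) >=
    ``min_ratio`` and BH-adjusted (within stage) two-sample t-test on
    log2(FPKM+1) replicate values gives q < ``fdr``; b-biased
    symmetrically; balanced otherwise. Pairs with fewer than two replicates
    per allele are untestable.
    """

    def __init__(self, expression: pd.DataFrame, pairs: pd.DataFrame,
                 min_ratio: float = 2.0, fdr: float = 0.05, stages=None):
        if min_ratio < 1:
            raise ValueError("min_ratio must be >= 1")
        self.expression = expression
        self.pairs = pairs
        self.min_ratio = min_ratio
        self.fdr = fdr
        self.stages = tuple(stages) if stages is not None else tuple(
            expression.columns.get_level_values("stage").unique())

    def fit(self) -> "ASEResults":
        rows = []
        for stage in self.stages:
            stage_expr = self.expression.xs(stage, axis=1, level="stage")
            for pair in self.pairs.itertuples(index=False):
                if pair.a not in stage_expr.index or pair.b not in stage_expr.index:
                    rows.append((pair.pair_id, stage, np.nan, np.nan, np.nan,
                                 np.nan, "untestable"))
                    continue
                va = stage_expr.loc[pair.a].to_numpy(dtype=float)
                vb = stage_expr.loc[pair.b].to_numpy(dtype=float)
                mean_a, mean_b = float(va.mean()), float(vb.mean())
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = mean_a / mean_b if mean_b > 0 else np.inf
                if len(va) < 2 or len(vb) < 2:
                    rows.append((pair.pair_id, stage, mean_a, mean_b, ratio,
                                 np.nan, "untestable"))
                    continue
                la, lb = np.log2(va + 1), np.log2(vb + 1)
                if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) \
                        and np.isclose(la[0], lb[0]):
                    p = 1.0
                else:
                    p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
                rows.append((pair.pair_id, stage, mean_a, mean_b, ratio, p,
                             None))
        rec = pd.DataFrame(rows, columns=[
            "pair_id", "stage", "mean_a", "mean_b", "ratio", "p_value",
            "direction"])
        rec["q_value"] = np.nan
        rec["log2_ratio"] = np.log2(rec["ratio"].replace(0, np.nan))
        for stage, idx in rec.groupby("stage").groups.items():
            testable = rec.loc[idx, "p_value"].notna()
            tidx = rec.loc[idx].index[testable]
            if len(tidx):
                rec.loc[tidx, "q_value"] = bh_adjust(
                    rec.loc[tidx, "p_value"].to_numpy())
        undecided = rec["direction"].isna()
        sig = undecided & (rec["q_value"] < self.fdr)
        rec.loc[undecided, "direction"] = "balanced"
        rec.loc[sig & (rec["ratio"] >= self.min_ratio), "direction"] = "a-biased"
        rec.loc[sig & (rec["ratio"] <= 1.0 / self.min_ratio), "direction"] = \
            "b-biased"
        return ASEResults(model=self, records=rec)


@dataclass
class ASEResults:
    model: AlleleSpecificExpression
    records: pd.DataFrame

    def consistency(self) -> pd.DataFrame:
        n_stages = len(self.model.stages)
        rows = []
        for pair_id, grp in self.records.groupby("pair_id"):
            statuses = [s if s in ("a-biased", "b-biased") else "none"
                        for s in grp["direction"]]
            rows.append((pair_id, consistency_classify(statuses, n_stages)))
        return pd.DataFrame(rows, columns=["pair_id", "classification"])

    def counts(self, stage=None) -> tuple[int, int]:
        sub = self.records if stage is None else \
            self.records[self.records["stage"] == stage]
        return (int((sub["direction"] == "a-biased").sum()),
                int((sub["direction"] == "b-biased").sum()))

    def biased_pairs(self, direction: str, stage: str | None = None) -> set:
        sub = self.records[self.records["direction"] == direction]
        if stage is not None:
            sub = sub[sub["stage"] == stage]
        return set(sub["pair_id"])


# ---------------------------------------------------------------------------
# ASM-ASE association
# ---------------------------------------------------------------------------

def allele_delta(level_matrix: pd.DataFrame, stage: str, context: str,
                 region: str) -> pd.Series:
    """Per-pair methylation difference (allele a minus allele b) from the
    per-allele level matrix of :func:`hapmeth.levels.allele_gene_level_matrix`."""
    col = (stage, context, region)
    a = level_matrix.xs("a", level="allele")[col].droplevel("gene_id")
    b = level_matrix.xs("b", level="allele")[col].droplevel("gene_id")
    return (a - b).rename("delta")


def asm_ase_association(level_matrix: pd.DataFrame, ase_records: pd.DataFrame,
                        stage: str, context: str = "CG",
                        region: str = "promoter2kb") -> pd.DataFrame:
    """Methylation difference (a - b) by ASE-bias group, with one-tailed
    one-sample t-tests in the repressive direction: b-biased ASE genes are
    tested for delta > 0 (HM allele hypermethylated) and a-biased ASE genes
    for delta < 0. Groups with fewer than two pairs are flagged untestable.
    """
    delta = allele_delta(level_matrix, stage, context, region)
    sub = ase_records[ase_records["stage"] == stage]
    rows = []
    for group, alternative in (("a-biased", "less"), ("b-biased", "greater")):
        ids = sub.loc[sub["direction"] == group, "pair_id"]
        d = delta.reindex(ids).dropna()
        row = {"ase_group": group, "n": int(len(d)),
               "mean_delta": float(d.mean()) if len(d) else np.nan,
               "alternative": alternative, "p_value": np.nan,
               "testable": len(d) >= 2}
        if row["testable"]:
            if d.std(ddof=1) > 0:
                row["p_value"] = float(stats.ttest_1samp(
                    d, 0.0, alternative=alternative).pvalue)
            else:
                # degenerate (constant) sample: limiting one-tailed values
                m = d.iloc[0]
                if m == 0:
                    row["p_value"] = 0.5
                else:
                    on_side = (m > 0) if alternative == "greater" else (m < 0)
                    row["p_value"] = 0.0 if on_side else 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def asm_ase_overlap(asm_pairs, ase_pairs) -> dict:
    """|ASM intersect ASE| / |ASM| plus the raw counts (Venn export)."""
    asm_pairs, ase_pairs = set(asm_pairs), set(ase_pairs)
    inter = asm_pairs & ase_pairs
    return {"n_asm": len(asm_pairs), "n_ase": len(ase_pairs),
            "intersection": len(inter),
            "fraction": len(inter) / len(asm_pairs) if asm_pairs
            else float("nan")}


def allele_meth_expression_profile(
        pair_id: str, level_matrix: pd.DataFrame, ase_records: pd.DataFrame,
        context: str = "CG", region: str = "promoter2kb") -> pd.DataFrame:
    """Tidy per-stage table of one pair's allele levels and expression, with
    the sign of the Spearman correlation between promoter level and mean
    expression reported per allele (NaN when either series is constant)."""
    sub = ase_records[ase_records["pair_id"] == pair_id].set_index("stage")
    rows = []
    for allele, mean_col in (("a", "mean_a"), ("b", "mean_b")):
        lv = level_matrix.xs(pair_id, level="pair_id") \
                         .xs(allele, level="allele")
        for stage in sub.index:
            level = lv[(stage, context, region)].iloc[0] \
                if (stage, context, region) in lv.columns else np.nan
            rows.append((stage, allele, float(level),
                         float(sub.loc[stage, mean_col])))
    out = pd.DataFrame(rows, columns=["stage", "allele", "level", "fpkm"])
    corr = {}
    for allele, grp in out.groupby("allele"):
        g = grp.dropna(subset=["level", "fpkm"])
        if len(g) < 3 or g["level"].nunique() == 1 or g["fpkm"].nunique() == 1:
            corr[allele] = np.nan
        else:
            corr[allele] = float(stats.spearmanr(g["level"], g["fpkm"]).statistic)
    out["spearman_rho"] = out["allele"].map(corr)
    return out
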