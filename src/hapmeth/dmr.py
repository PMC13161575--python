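"""Sliding-window differential-methylation calling.

The procedure, applied per sequence context to one pairwise comparison of
sample groups (replicates pooled by summing read counts):

1. 200-bp windows at 50-bp steps over every contig.
2. Two-sided Fisher's exact test on the pooled 2x2 read-count table of each
   window containing at least one covered cytosine of the context in both
   groups; windows with no coverage are skipped, not tested.
3. Benjamini-Hochberg adjustment within each context; windows with
   FDR < 0.05 and a level fold change >= 1.5 are candidates. Fold change is
   the max/min ratio of the two weighted levels after adding a pseudocount
   (default 0.01) to each, with the direction (hyper/hypo of group 2
   relative to group 1) stored separately.
4. Cytosines inside candidate windows are DMCs when the per-cytosine Fisher
   p <= 0.01, fold change >= 2 and the absolute level difference is at least
   0.4 (CG), 0.2 (CHG) or 0.1 (CHH).
5. Overlapping candidate windows of one context and direction collapse into
   runs; runs with >= 7 distinct DMCs are retained; retained regions of the
   same context and direction separated by <= 100 bp merge transitively and
   DMC counts are recomputed on the merged intervals.

`DifferentialMethylation` is the model object (data + thresholds);
:meth:`DifferentialMethylation.fit` returns :class:`DMRResults` carrying the
tested windows, DMCs, merged DMRs and summary/annotation/export helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exact import bh_adjust, fisher_exact_2x2
from .io import CONTEXTS
from .windows import DEFAULT_STEP, DEFAULT_WINDOW, pool_calls, window_counts

#: Minimum absolute methylation difference for a DMC, per context.
DMC_DELTA = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}


def fold_change(level1, level2, epsilon: float = 0.01):
    """Max/min ratio of pseudocount-shifted levels (always >= 1)."""
    l1 = np.asarray(level1, dtype=float) + epsilon
    l2 = np.asarray(level2, dtype=float) + epsilon
    return np.maximum(l1, l2) / np.minimum(l1, l2)


@dataclass
class DMRParams:
    """Thresholds of the window/DMC/region procedure (defaults as published
    for this pipeline family; every constant is a constructor knob)."""

    width: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    fdr: float = 0.05
    fc: float = 1.5
    dmc_p: float = 0.01
    dmc_fc: float = 2.0
    dmc_delta: dict = field(default_factory=lambda: dict(DMC_DELTA))
    min_dmcs: int = 7
    merge_gap: int = 100
    epsilon: float = 0.01

    def validate(self) -> None:
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")
        if not (0 < self.dmc_p <= 1):
            raise ValueError("dmc_p must be in (0, 1]")
        if self.fc < 1 or self.dmc_fc < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.min_dmcs < 1 or self.merge_gap < 0:
            raise ValueError("min_dmcs must be >= 1 and merge_gap >= 0")
        if self.width <= 0 or self.step <= 0 or self.width % self.step:
            raise ValueError("window width must be a positive multiple of step")


class DifferentialMethylation:
    """Differential-methylation model for two groups of WGBS libraries.

    Parameters
    ----------
    group1, group2
        Lists of per-cytosine call tables (one per replicate library),
        already coverage-filtered. Replicates are pooled by summing counts.
    contig_lengths
        Mapping contig name -> length (bp) defining the window scan.
    params
        Thresholds; defaults follow the standard window/DMC scheme.
    contexts
        Sequence contexts to analyse (independent FDR family each).
    name1, name2
        Group labels used in outputs ("hyper" means ``name2`` higher).
    """

    def __init__(self, group1, group2, contig_lengths, params: DMRParams | None = None,
                 contexts=CONTEXTS, name1: str = "group1", name2: str = "group2"):
        self.params = params or DMRParams()
        self.params.validate()
        self.group1 = list(group1)
        self.group2 = list(group2)
        self.contig_lengths = dict(contig_lengths)
        self.contexts = tuple(contexts)
        self.name1 = name1
        self.name2 = name2

    def fit(self) -> "DMRResults":
        p = self.params
        pooled1 = pool_calls(self.group1)
        pooled2 = pool_calls(self.group2)
        wc = window_counts(pooled1, pooled2, self.contig_lengths, p.width, p.step)
        wc = wc[wc["context"].isin(self.contexts)].reset_index(drop=True)
        windows = score_windows(wc, epsilon=p.epsilon)
        candidates = select_dm_windows(windows, fdr=p.fdr, fc=p.fc)
        dmcs = call_dmcs(candidates, pooled1, pooled2,
                         dmc_p=p.dmc_p, dmc_fc=p.dmc_fc, dmc_delta=p.dmc_delta,
                         epsilon=p.epsilon)
        dmrs = retain_and_merge(candidates, dmcs, min_dmcs=p.min_dmcs,
                                merge_gap=p.merge_gap)
        return DMRResults(model=self, windows=windows, candidates=candidates,
                          dmcs=dmcs, dmrs=dmrs)


def score_windows(window_table: pd.DataFrame, epsilon: float = 0.01) -> pd.DataFrame:
    """Fisher-test pooled window counts; BH-adjust within each context.

    Only windows covered in both groups are tested (others are dropped so
    they do not dilute the FDR). Adds level1/level2, p_value, q_value,
    fold_change and direction columns.
    """
    w = window_table[(window_table["cov1"] > 0) & (window_table["cov2"] > 0)].copy()
    if w.empty:
        for col in ("level1", "level2", "p_value", "q_value", "fold_change"):
            w[col] = pd.Series(dtype=float)
        w["direction"] = pd.Series(dtype=object)
        return w
    w["level1"] = w["mc1"] / w["cov1"]
    w["level2"] = w["mc2"] / w["cov2"]
    tables = np.column_stack([
        w["mc1"], w["cov1"] - w["mc1"], w["mc2"], w["cov2"] - w["mc2"]])
    w["p_value"] = fisher_exact_2x2(tables)
    w["q_value"] = np.nan
    for ctx, idx in w.groupby("context", observed=True).groups.items():
        w.loc[idx, "q_value"] = bh_adjust(w.loc[idx, "p_value"].to_numpy())
    w["fold_change"] = fold_change(w["level1"], w["level2"], epsilon)
    w["direction"] = np.where(w["level2"] > w["level1"], "hyper", "hypo")
    return w.reset_index(drop=True)


def select_dm_windows(windows: pd.DataFrame, fdr: float = 0.05,
                      fc: float = 1.5) -> pd.DataFrame:
    """Candidate windows: q strictly below ``fdr`` and fold change >= ``fc``.

    Windows with identical levels never pass (their fold change is 1).
    """
    if windows.empty:
        return windows
    keep = (windows["q_value"] < fdr) & (windows["fold_change"] >= fc) \
        & (windows["level1"] != windows["level2"])
    return windows[keep].reset_index(drop=True)


def call_dmcs(candidates: pd.DataFrame, pooled1: pd.DataFrame,
              pooled2: pd.DataFrame, dmc_p: float = 0.01, dmc_fc: float = 2.0,
              dmc_delta: dict = DMC_DELTA, epsilon: float = 0.01) -> pd.DataFrame:
    """Per-cytosine tests inside candidate windows.

    A cytosine must be covered in both groups; it is a DMC when
    p <= ``dmc_p``, fold change >= ``dmc_fc`` and |level2 - level1| meets
    the context threshold. P-values are raw (no FDR at the cytosine level).
    """
    cols = ["chrom", "pos", "strand", "context", "mc1", "cov1", "mc2", "cov2",
            "level1", "level2", "delta", "fold_change", "p_value", "is_dmc"]
    if candidates.empty:
        return pd.DataFrame(columns=cols)
    merged = pd.merge(
        pooled1, pooled2, on=["chrom", "pos", "strand", "context"],
        suffixes=("1", "2"))
    keep = np.zeros(len(merged), dtype=bool)
    for (chrom, ctx), grp in candidates.groupby(["chrom", "context"], observed=True):
        iv = _union_intervals(grp[["start", "end"]].to_numpy(np.int64))
        sel = (merged["chrom"].to_numpy() == chrom) & \
              (merged["context"].to_numpy() == ctx)
        pos = merged.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        inside = (idx >= 0) & (pos < iv[np.maximum(idx, 0), 1])
        keep[np.flatnonzero(sel)[inside]] = True
    sites = merged[keep].reset_index(drop=True)
    if sites.empty:
        return pd.DataFrame(columns=cols)
    sites["level1"] = sites["mc1"] / sites["cov1"]
    sites["level2"] = sites["mc2"] / sites["cov2"]
    sites["delta"] = sites["level2"] - sites["level1"]
    sites["fold_change"] = fold_change(sites["level1"], sites["level2"], epsilon)
    tables = np.column_stack([
        sites["mc1"], sites["cov1"] - sites["mc1"],
        sites["mc2"], sites["cov2"] - sites["mc2"]])
    sites["p_value"] = fisher_exact_2x2(tables)
    thr = sites["context"].map(dmc_delta).to_numpy(dtype=float)
    sites["is_dmc"] = ((sites["p_value"] <= dmc_p)
                       & (sites["fold_change"] >= dmc_fc)
                       & (sites["delta"].abs() >= thr))
    return sites[cols]


def _union_intervals(iv: np.ndarray) -> np.ndarray:
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)


def _count_dmcs(dmc_sites: pd.DataFrame, chrom: str, context: str,
                start: int, end: int) -> int:
    sel = dmc_sites[(dmc_sites["chrom"] == chrom)
                    & (dmc_sites["context"] == context)
                    & dmc_sites["is_dmc"]
                    & (dmc_sites["pos"] >= start) & (dmc_sites["pos"] < end)]
    return len(sel.drop_duplicates(["pos", "strand"]))


def retain_and_merge(candidates: pd.DataFrame, dmc_sites: pd.DataFrame,
                     min_dmcs: int = 7, merge_gap: int = 100) -> pd.DataFrame:
    """Collapse candidate windows into DMRs.

    Overlapping candidate windows of one (chrom, context, direction)
    collapse into maximal runs; a run survives when it holds at least
    ``min_dmcs`` distinct DMCs; surviving regions separated by at most
    ``merge_gap`` bp (inclusive) merge transitively left to right, never
    across direction or context, and DMC counts are recomputed afterwards.
    """
    cols = ["chrom", "start", "end", "context", "direction", "n_dmcs", "n_windows"]
    if candidates.empty:
        return pd.DataFrame(columns=cols)
    out = []
    for (chrom, ctx, direction), grp in candidates.groupby(
            ["chrom", "context", "direction"], observed=True, sort=True):
        grp = grp.sort_values("start")
        runs = []  # [start, end, n_windows]
        for r in grp.itertuples(index=False):
            if runs and r.start < runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], r.end)
                runs[-1][2] += 1
            else:
                runs.append([r.start, r.end, 1])
        retained = [run for run in runs
                    if _count_dmcs(dmc_sites, chrom, ctx, run[0], run[1]) >= min_dmcs]
        merged = []
        for run in retained:
            if merged and run[0] - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], run[1])
                merged[-1][2] += run[2]
            else:
                merged.append(run)
        for start, end, n_win in merged:
            out.append((chrom, start, end, ctx, direction,
                        _count_dmcs(dmc_sites, chrom, ctx, start, end), n_win))
    dmrs = pd.DataFrame(out, columns=cols)
    return dmrs.sort_values(["chrom", "start", "context", "direction"],
                            ignore_index=True)


def annotate_dmrs(dmrs: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Attach every feature kind a DMR overlaps by >= 1 bp (multi-label).

    Adds ``kinds`` (comma-joined sorted set), ``dmg_genes`` (genes whose
    body overlaps; "differentially methylated genes") and ``dmp_genes``
    (genes whose 2-kb promoter overlaps; "differentially methylated
    promoters").
    """
    kinds_col, dmg_col, dmp_col = [], [], []
    ann_by_chrom = dict(tuple(annotations.groupby("chrom")))
    for r in dmrs.itertuples(index=False):
        sub = ann_by_chrom.get(r.chrom)
        if sub is None:
            kinds_col.append(""), dmg_col.append(""), dmp_col.append("")
            continue
        hit = sub[(sub["start"] < r.end) & (sub["end"] > r.start)]
        kinds_col.append(",".join(sorted(set(hit["kind"]))))
        dmg = hit.loc[hit["kind"] == "gene_body", "gene_id"].dropna()
        dmp = hit.loc[hit["kind"] == "promoter2kb", "gene_id"].dropna()
        dmg_col.append(",".join(sorted(set(dmg))))
        dmp_col.append(",".join(sorted(set(dmp))))
    out = dmrs.copy()
    out["kinds"] = kinds_col
    out["dmg_genes"] = dmg_col
    out["dmp_genes"] = dmp_col
    return out


def feature_kind_counts(annotated_dmrs: pd.DataFrame) -> pd.DataFrame:
    """DMR counts per (context, direction, feature kind); a DMR overlapping
    several kinds counts once in each."""
    rows = []
    for r in annotated_dmrs.itertuples(index=False):
        for kind in (r.kinds.split(",") if r.kinds else []):
            rows.append((r.context, r.direction, kind))
    counts = pd.DataFrame(rows, columns=["context", "direction", "kind"])
    if counts.empty:
        return pd.DataFrame(columns=["context", "direction", "kind", "n"])
    return (counts.value_counts().rename("n").reset_index()
            .sort_values(["context", "direction", "kind"], ignore_index=True))


def compare_sets(set1, set2) -> dict:
    """Overlap bookkeeping between two id sets (Venn export)."""
    s1, s2 = set(set1), set(set2)
    inter = s1 & s2
    union = s1 | s2
    return {"n1": len(s1), "n2": len(s2), "intersection": len(inter),
            "union": len(union), "only1": len(s1 - s2), "only2": len(s2 - s1),
            "jaccard": len(inter) / len(union) if union else float("nan")}


def dmg_expression_contrast(hyper_genes, hypo_genes, expression: pd.DataFrame,
                            stage: str | None = None) -> dict:
    """Expression contrast between hyper- and hypo-DMG groups.

    Per gene the statistic is the mean log2(FPKM+1) over replicates (and
    over all stages unless ``stage`` is given). The two gene groups are
    compared with a one-tailed Welch t-test with alternative
    "hyper < hypo" (methylation gain associated with repression). Groups
    with fewer than two genes are flagged untestable.
    """
    logx = np.log2(expression + 1.0)
    if stage is not None:
        logx = logx.xs(stage, axis=1, level="stage")
    per_gene = logx.mean(axis=1)
    hyper = per_gene.reindex([g for g in set(hyper_genes) if g in per_gene.index])
    hypo = per_gene.reindex([g for g in set(hypo_genes) if g in per_gene.index])
    result = {
        "hyper_mean": float(hyper.mean()) if len(hyper) else float("nan"),
        "hypo_mean": float(hypo.mean()) if len(hypo) else float("nan"),
        "n_hyper": int(len(hyper)), "n_hypo": int(len(hypo)),
        "p_value": float("nan"), "testable": len(hyper) >= 2 and len(hypo) >= 2,
    }
    if result["testable"]:
        if hyper.std(ddof=1) == 0 and hypo.std(ddof=1) == 0:
            # degenerate zero-variance groups: limiting one-tailed values
            diff = result["hyper_mean"] - result["hypo_mean"]
            result["p_value"] = 0.5 if diff == 0 else (0.0 if diff < 0 else 1.0)
        else:
            t = stats.ttest_ind(hyper, hypo, equal_var=False,
                                alternative="less")
            result["p_value"] = float(t.pvalue)
    return result


@dataclass
class DMRResults:
    """Fit output of :class:`DifferentialMethylation`."""

    model: DifferentialMethylation
    windows: pd.DataFrame
    candidates: pd.DataFrame
    dmcs: pd.DataFrame
    dmrs: pd.DataFrame

    def annotate(self, annotations: pd.DataFrame) -> pd.DataFrame:
        return annotate_dmrs(self.dmrs, annotations)

    def dmg_ids(self, annotations: pd.DataFrame, context: str | None = None,
                direction: str | None = None) -> set:
        return self._gene_ids(annotations, "dmg_genes", context, direction)

    def dmp_ids(self, annotations: pd.DataFrame, context: str | None = None,
                direction: str | None = None) -> set:
        return self._gene_ids(annotations, "dmp_genes", context, direction)

    def _gene_ids(self, annotations, col, context, direction):
        ann = self.annotate(annotations)
        if context is not None:
            ann = ann[ann["context"] == context]
        if direction is not None:
            ann = ann[ann["direction"] == direction]
        ids: set = set()
        for v in ann[col]:
            if v:
                ids.update(v.split(","))
        return ids

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Differential methylation: "
            f"{self.model.name2} vs {self.model.name1}",
            f"windows {p.width} bp / step {p.step} bp; FDR<{p.fdr}, FC>={p.fc}; "
            f"DMC p<={p.dmc_p}, FC>={p.dmc_fc}, "
            f"|delta|>={p.dmc_delta}; >= {p.min_dmcs} DMCs; merge <= {p.merge_gap} bp",
            f"{'context':<8}{'tested':>9}{'candidate':>11}{'DMCs':>8}"
            f"{'hyper':>8}{'hypo':>8}",
        ]
        for ctx in self.model.contexts:
            tested = int((self.windows["context"] == ctx).sum())
            cand = int((self.candidates["context"] == ctx).sum()) \
                if not self.candidates.empty else 0
            if self.dmcs.empty:
                ndmc = 0
            else:
                sel = self.dmcs[(self.dmcs["context"] == ctx) & self.dmcs["is_dmc"]]
                ndmc = int(len(sel))
            sub = self.dmrs[self.dmrs["context"] == ctx] if not self.dmrs.empty \
                else self.dmrs
            hyper = int((sub["direction"] == "hyper").sum()) if not sub.empty else 0
            hypo = int((sub["direction"] == "hypo").sum()) if not sub.empty else 0
            lines.append(f"{ctx:<8}{tested:>9}{cand:>11}{ndmc:>8}{hyper:>8}{hypo:>8}")
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        """DMRs as BED6: name context:direction, score = DMC count."""
        with open(path, "w") as fh:
            for r in self.dmrs.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                         f"{r.context}:{r.direction}\t{r.n_dmcs}\t.\n")

    def to_tsv(self, path) -> None:
        self.dmrs.to_csv(path, sep="\t", index=False)
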