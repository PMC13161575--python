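"""Weighted methylation levels at genome, feature, per-gene and metagene
resolution.

"Methylation level" throughout is the weighted level: the ratio of summed
methylated read counts to summed total read counts over the covered
cytosines of one sequence context in a region. Regions with no covered
cytosine get a missing value (NaN), never zero. Display tables aggregate
replicates as mean +/- SD; pooling across replicates is reserved for the
hypothesis-testing machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTEXTS


@dataclass
class RegionLevel:
    """Weighted level of one context over one region."""

    level: float
    n_cytosines: int
    mc: int
    cov: int

    @property
    def missing(self) -> bool:
        return self.cov == 0


def weighted_level(calls: pd.DataFrame, context: str | None = None) -> RegionLevel:
    """Weighted level sum(mc)/sum(cov) of ``calls`` (optionally one context).

    Returns a :class:`RegionLevel` whose ``level`` is NaN when no covered
    cytosine is present.
    """
    sub = calls if context is None else calls[calls["context"] == context]
    if context is not None and not calls.empty and \
            context not in set(calls["context"].unique()) | {context}:
        raise ValueError(f"context {context} absent from calls")  # pragma: no cover
    mc = int(sub["mc"].sum())
    cov = int(sub["cov"].sum())
    return RegionLevel(mc / cov if cov > 0 else float("nan"), len(sub), mc, cov)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping [start, end) rows into disjoint sorted rows."""
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _mask_in(pos: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Boolean mask of positions inside any of the disjoint sorted intervals."""
    if merged.size == 0 or pos.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(pos.shape, dtype=bool)
    res[ok] = pos[ok] < merged[idx[ok], 1]
    return res


def region_context_sums(calls: pd.DataFrame,
                        intervals: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-context (mc, cov, n) sums of calls, optionally restricted to the
    union of ``intervals`` (columns chrom/start/end; overlaps counted once)."""
    sub = calls
    if intervals is not None:
        keep = np.zeros(len(calls), dtype=bool)
        for chrom, grp in intervals.groupby("chrom"):
            merged = _merge_intervals(grp[["start", "end"]].to_numpy(np.int64))
            sel = calls["chrom"].to_numpy() == chrom
            keep[sel] = _mask_in(calls.loc[sel, "pos"].to_numpy(), merged)
        sub = calls[keep]
    out = (sub.groupby("context", observed=True)
           .agg(mc=("mc", "sum"), cov=("cov", "sum"), n_cytosines=("pos", "size"))
           .reindex(CONTEXTS, fill_value=0).reset_index())
    out["level"] = np.where(out["cov"] > 0, out["mc"] / out["cov"].replace(0, 1), np.nan)
    return out


def genome_stage_levels(samples: dict[tuple, pd.DataFrame]) -> pd.DataFrame:
    """Genome-wide weighted level per (stage, replicate, context).

    ``samples`` maps ``(haplotype, stage, replicate)`` to a call table;
    haplotypes are pooled (whole-genome view). Use
    :func:`summarize_replicates` for the mean +/- SD display table.
    """
    rows = []
    grouped: dict[tuple, list[pd.DataFrame]] = {}
    for (hap, stage, rep), calls in samples.items():
        grouped.setdefault((stage, rep), []).append(calls)
    for (stage, rep), tables in sorted(grouped.items()):
        sums = region_context_sums(pd.concat(tables, ignore_index=True))
        for r in sums.itertuples(index=False):
            rows.append((stage, rep, r.context, r.level, r.mc, r.cov, r.n_cytosines))
    return pd.DataFrame(rows, columns=["stage", "replicate", "context", "level",
                                       "mc", "cov", "n_cytosines"])


def summarize_replicates(level_table: pd.DataFrame,
                         by: list[str] | None = None) -> pd.DataFrame:
    """Mean +/- SD of ``level`` across replicates (figure-caption convention).

    SD is NaN when a single replicate is present.
    """
    by = by or [c for c in level_table.columns
                if c not in ("replicate", "level", "mc", "cov", "n_cytosines")]
    return (level_table.groupby(by, observed=True)["level"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1), n_replicates="size")
            .reset_index())


def feature_levels(samples: dict[tuple, pd.DataFrame], annotations: pd.DataFrame,
                   split_by_haplotype: bool = True) -> pd.DataFrame:
    """Weighted level per (feature kind, haplotype, stage, replicate, context).

    Feature intervals of one kind are merged before summation so overlapping
    gene flanks are not double counted. With ``split_by_haplotype=False``
    haplotypes are pooled.
    """
    rows = []
    for (hap, stage, rep), calls in sorted(samples.items()):
        ann = annotations
        if split_by_haplotype and hap is not None:
            ann = annotations[annotations["haplotype"] == hap]
        for kind, grp in ann.groupby("kind", observed=True):
            sums = region_context_sums(calls, grp)
            for r in sums.itertuples(index=False):
                if r.cov == 0:
                    continue
                rows.append((kind, hap if split_by_haplotype else None, stage, rep,
                             r.context, r.level, r.mc, r.cov, r.n_cytosines))
    out = pd.DataFrame(rows, columns=["kind", "haplotype", "stage", "replicate",
                                      "context", "level", "mc", "cov", "n_cytosines"])
    if not split_by_haplotype and not out.empty:
        out = (out.groupby(["kind", "stage", "replicate", "context"], observed=True)
               .agg(mc=("mc", "sum"), cov=("cov", "sum"),
                    n_cytosines=("n_cytosines", "sum")).reset_index())
        out["level"] = out["mc"] / out["cov"]
    return out


def metagene_profile(
    samples: list[pd.DataFrame],
    annotations: pd.DataFrame,
    target: str = "gene_body",
    body_bins: int = 20,
    flank: int = 2000,
    flank_bins: int = 20,
    pool_replicates: bool = False,
) -> pd.DataFrame:
    """Average methylation over length-normalised bodies plus fixed flanks.

    Each target (gene body or TE) contributes its covered cytosines to
    ``flank_bins`` fixed-width upstream bins, ``body_bins`` proportional body
    bins and ``flank_bins`` downstream bins; minus-strand targets are
    reversed so bin 0 is always the distal 5' flank. Within each sample the
    bin level is the pooled weighted level across targets; the returned
    level is the mean across samples (``pool_replicates=True`` instead pools
    read counts across samples).

    Returns a tidy frame with columns bin, segment, context, level
    (and per-sample levels pooled as described).
    """
    if body_bins < 1 or flank_bins < 1:
        raise ValueError("body_bins and flank_bins must be >= 1")
    targets = annotations[annotations["kind"] == target]
    n_bins = body_bins + 2 * flank_bins
    flank_w = flank / flank_bins
    per_sample = []
    for calls in samples:
        acc = np.zeros((n_bins, len(CONTEXTS), 2), dtype=np.int64)
        ctx_code = {c: i for i, c in enumerate(CONTEXTS)}
        for chrom, grp in targets.groupby("chrom"):
            sub = calls[calls["chrom"] == chrom].sort_values("pos")
            if sub.empty:
                continue
            pos = sub["pos"].to_numpy()
            ctx = sub["context"].map(ctx_code).to_numpy()
            mc = sub["mc"].to_numpy()
            cov = sub["cov"].to_numpy()
            for t in grp.itertuples(index=False):
                lo = np.searchsorted(pos, t.start - flank, side="left")
                hi = np.searchsorted(pos, t.end + flank, side="left")
                if hi <= lo:
                    continue
                p = pos[lo:hi]
                b = np.empty(p.shape, dtype=np.int64)
                up = p < t.start
                down = p >= t.end
                body = ~(up | down)
                b[up] = np.minimum(((p[up] - (t.start - flank)) / flank_w), flank_bins - 1)
                length = max(t.end - t.start, 1)
                b[body] = flank_bins + np.minimum(
                    (p[body] - t.start) * body_bins // length, body_bins - 1)
                b[down] = flank_bins + body_bins + np.minimum(
                    ((p[down] - t.end) / flank_w), flank_bins - 1)
                if t.strand == "-":
                    b = n_bins - 1 - b
                np.add.at(acc[:, :, 0], (b, ctx[lo:hi]), mc[lo:hi])
                np.add.at(acc[:, :, 1], (b, ctx[lo:hi]), cov[lo:hi])
        per_sample.append(acc)
    if pool_replicates:
        total = np.sum(per_sample, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(total[:, :, 1] > 0,
                             total[:, :, 0] / np.maximum(total[:, :, 1], 1), np.nan)
    else:
        import warnings
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            stack = np.stack([
                np.where(a[:, :, 1] > 0, a[:, :, 0] / np.maximum(a[:, :, 1], 1), np.nan)
                for a in per_sample])
            level = np.nanmean(stack, axis=0) if stack.size else stack
    segs = (["upstream"] * flank_bins + ["body"] * body_bins
            + ["downstream"] * flank_bins)
    rows = []
    for i in range(n_bins):
        for j, ctx in enumerate(CONTEXTS):
            rows.append((i, segs[i], ctx, level[i, j]))
    return pd.DataFrame(rows, columns=["bin", "segment", "context", "level"])


def allele_gene_level_matrix(
    pairs: pd.DataFrame,
    samples: dict[tuple, pd.DataFrame],
    annotations: pd.DataFrame,
    region_kinds: tuple[str, ...] = ("gene_body", "promoter2kb"),
) -> pd.DataFrame:
    """Per-allele weighted levels: rows are alleles (gene ids), columns a
    (stage, context, region_kind) MultiIndex; replicates pooled by counts.

    This is the matrix behind per-allele heatmaps and the ASM-ASE
    association: for each pair, the HM member (allele a) and HC member
    (allele b) appear as separate rows tagged by ``pair_id`` and ``allele``.
    """
    regions = annotations[annotations["kind"].isin(region_kinds)]
    region_of = {(r.gene_id, r.kind): (r.chrom, r.start, r.end)
                 for r in regions.itertuples(index=False)}
    # pool replicates per (haplotype, stage); sort calls per chrom for slicing
    pooled: dict[tuple, dict[str, pd.DataFrame]] = {}
    for (hap, stage, rep), calls in samples.items():
        pooled.setdefault((hap, stage), []).append(calls)
    by_chrom: dict[tuple, dict[str, pd.DataFrame]] = {}
    for key, tables in pooled.items():
        cat = pd.concat(tables, ignore_index=True)
        agg = (cat.groupby(["chrom", "pos", "context"], as_index=False)
               [["mc", "cov"]].sum())
        by_chrom[key] = {c: g.sort_values("pos") for c, g in agg.groupby("chrom")}
    stages = sorted({stage for (_, stage) in by_chrom})
    ctx_list = list(CONTEXTS)
    rows = []
    index = []
    for pair in pairs.itertuples(index=False):
        for allele, gid, hap in (("a", pair.a, "HM"), ("b", pair.b, "HC")):
            vals = {}
            for stage in stages:
                chrom_tables = by_chrom.get((hap, stage), {})
                for kind in region_kinds:
                    reg = region_of.get((gid, kind))
                    for ctx in ctx_list:
                        key = (stage, ctx, kind)
                        if reg is None:
                            vals[key] = np.nan
                            continue
                        chrom, start, end = reg
                        tbl = chrom_tables.get(chrom)
                        if tbl is None:
                            vals[key] = np.nan
                            continue
                        pos = tbl["pos"].to_numpy()
                        lo = np.searchsorted(pos, start, "left")
                        hi = np.searchsorted(pos, end, "left")
                        sl = tbl.iloc[lo:hi]
                        sl = sl[sl["context"] == ctx]
                        cov = int(sl["cov"].sum())
                        vals[key] = sl["mc"].sum() / cov if cov else np.nan
            rows.append(vals)
            index.append((pair.pair_id, allele, gid))
    if not rows:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], [], []],
                                            names=["pair_id", "allele", "gene_id"]))
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["pair_id", "allele", "gene_id"]))
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["stage", "context", "region"])
    return out.sort_index(axis=1)
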