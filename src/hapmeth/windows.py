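"""Sliding-window construction and pooled count aggregation.

The genome scan uses 200-bp windows advanced in 50-bp steps; the trailing
windows of a contig are clipped at the contig end (kept, flagged short).
Replicate libraries within a group are pooled by summing read counts per
cytosine before any aggregation, so each window yields a single 2x2 table
per sequence context.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CONTEXTS

DEFAULT_WINDOW = 200
DEFAULT_STEP = 50


def make_windows(contig_lengths: dict[str, int], width: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Window frame with starts 0, step, 2*step, ... per contig.

    Ends are clipped to the contig length; windows shorter than ``width``
    are flagged ``clipped``.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    frames = []
    for chrom, length in contig_lengths.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "clipped": ends - starts < width,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "clipped"])


def pool_calls(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum mc/cov across replicate call tables per (chrom, pos, strand).

    Context is carried through; a cytosine absent from a replicate (coverage
    filtered) simply contributes nothing.
    """
    if not replicates:
        raise ValueError("no replicate call tables given")
    cat = pd.concat(replicates, ignore_index=True)
    if cat.empty:
        return cat.reindex(columns=["chrom", "pos", "strand", "context", "mc", "cov"])
    pooled = (
        cat.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=True)
        [["mc", "cov"]].sum()
    )
    return pooled


def window_counts(
    pooled1: pd.DataFrame,
    pooled2: pd.DataFrame,
    contig_lengths: dict[str, int],
    width: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Per-(window, context) pooled counts for two groups.

    Returns one row per (chrom, start, end, context) with columns
    ``mc1, cov1, mc2, cov2, n_cyt1, n_cyt2``; only windows with at least one
    covered cytosine of the context in *either* group appear (downstream
    testing additionally requires coverage in both).
    """
    if width % step != 0:
        raise ValueError("width must be a multiple of step")
    k_max = width // step
    rows = []
    ctx_code = {c: i for i, c in enumerate(CONTEXTS)}
    for chrom, length in contig_lengths.items():
        n_win = int(np.ceil(length / step)) if length > 0 else 0
        if n_win == 0:
            continue
        acc = np.zeros((n_win, len(CONTEXTS), 6), dtype=np.int64)
        for gi, pooled in enumerate((pooled1, pooled2)):
            sub = pooled[pooled["chrom"] == chrom]
            if sub.empty:
                continue
            pos = sub["pos"].to_numpy()
            ctx = sub["context"].map(ctx_code).to_numpy()
            mc = sub["mc"].to_numpy()
            cov = sub["cov"].to_numpy()
            base = pos // step
            for k in range(k_max):
                idx = base - k
                ok = idx >= 0
                np.add.at(acc[:, :, gi * 3 + 0], (idx[ok], ctx[ok]), mc[ok])
                np.add.at(acc[:, :, gi * 3 + 1], (idx[ok], ctx[ok]), cov[ok])
                np.add.at(acc[:, :, gi * 3 + 2], (idx[ok], ctx[ok]), 1)
        wi, ci = np.nonzero(acc[:, :, 1] + acc[:, :, 4])
        if wi.size == 0:
            continue
        starts = wi.astype(np.int64) * step
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + width, length),
            "context": np.array(CONTEXTS)[ci],
            "mc1": acc[wi, ci, 0], "cov1": acc[wi, ci, 1], "n_cyt1": acc[wi, ci, 2],
            "mc2": acc[wi, ci, 3], "cov2": acc[wi, ci, 4], "n_cyt2": acc[wi, ci, 5],
        }))
    cols = ["chrom", "start", "end", "context",
            "mc1", "cov1", "n_cyt1", "mc2", "cov2", "n_cyt2"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)[cols]
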