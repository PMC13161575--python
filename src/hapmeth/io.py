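"""Readers and writers for per-cytosine methylation calls, annotations,
allele maps and expression tables.

Coordinate conventions
----------------------
Call files carry 1-based positions (CGmap-style); everything in memory uses
0-based half-open intervals; BED output is 0-based half-open and GFF output
1-based closed. Cytosines on the + and - strand are independent records
(no CpG-dyad collapsing).

Call file format: tab-separated ``chrom  pos(1-based)  strand  context  mc
cov`` with an optional ``#``-prefixed header line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
FEATURE_KINDS = ("gene_body", "promoter2kb", "downstream2kb", "TE", "intergenic")
STAGES = ("LS1", "LS2", "LS3", "LS4", "LS5")

#: Default minimum read depth for a cytosine to enter any level computation.
DEFAULT_MIN_COV = 4

CALL_COLUMNS = ("chrom", "pos", "strand", "context", "mc", "cov")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Well-formed input with semantically invalid content."""


@dataclass
class ParseIssue:
    """One rejected record: file line number (1-based) and reason."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


def read_meth_calls(
    path: str | Path,
    min_cov: int = DEFAULT_MIN_COV,
    on_error: str = "collect",
) -> tuple[pd.DataFrame, list[ParseIssue]]:
    """Read a per-cytosine call file, applying the coverage filter.

    Parameters
    ----------
    path
        Tab-separated file with the six call columns; lines starting with
        ``#`` are ignored.
    min_cov
        Keep only cytosines with ``cov >= min_cov``. The default of 4 reads
        is the conventional depth floor for WGBS level estimation.
    on_error
        ``"collect"`` returns malformed/invalid rows as :class:`ParseIssue`
        objects alongside the good records; ``"raise"`` raises on the first.

    Returns
    -------
    (calls, issues)
        ``calls`` has columns chrom, pos (0-based), strand, context, mc, cov
        sorted as in the file; ``issues`` lists rejected rows with their
        1-based line numbers.
    """
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if on_error not in ("collect", "raise"):
        raise ValueError("on_error must be 'collect' or 'raise'")
    path = Path(path)
    rows: list[tuple] = []
    issues: list[ParseIssue] = []

    def reject(lineno: int, message: str) -> None:
        if on_error == "raise":
            raise ValidationError(f"{path}: line {lineno}: {message}")
        issues.append(ParseIssue(lineno, message))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(CALL_COLUMNS):
                missing = CALL_COLUMNS[len(parts):]
                raise FormatError(
                    f"{path}: line {lineno}: missing column(s) {', '.join(missing)}"
                )
            chrom, pos_s, strand, context, mc_s, cov_s = parts[:6]
            try:
                pos = int(pos_s)
                mc = int(mc_s)
                cov = int(cov_s)
            except ValueError:
                reject(lineno, f"non-integer field in {parts[:6]!r}")
                continue
            if strand not in ("+", "-"):
                reject(lineno, f"invalid strand {strand!r}")
                continue
            if context not in CONTEXTS:
                reject(lineno, f"invalid context {context!r}")
                continue
            if pos < 1:
                reject(lineno, f"position {pos} is not 1-based positive")
                continue
            if mc < 0 or cov < 0 or mc > cov:
                reject(lineno, f"mc={mc} exceeds cov={cov}" if mc > cov else
                       f"negative count mc={mc} cov={cov}")
                continue
            if cov >= min_cov:
                rows.append((chrom, pos - 1, strand, context, mc, cov))

    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if not calls.empty:
        calls["mc"] = calls["mc"].astype(np.int64)
        calls["cov"] = calls["cov"].astype(np.int64)
        calls["pos"] = calls["pos"].astype(np.int64)
    return calls, issues


def write_meth_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls back to the tab-separated format (positions 1-based)."""
    out = calls.loc[:, list(CALL_COLUMNS)].copy()
    out["pos"] = out["pos"] + 1
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CALL_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_SEQREGION_RE = re.compile(r"^##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)")


def read_contig_lengths(gff_path: str | Path) -> dict[str, int]:
    """Contig lengths from ``##sequence-region`` pragmas of a GFF3 file."""
    lengths: dict[str, int] = {}
    with open(gff_path) as fh:
        for line in fh:
            m = _SEQREGION_RE.match(line)
            if m:
                lengths[m.group(1)] = int(m.group(3))
            elif not line.startswith("#"):
                break
    return lengths


def read_annotations(
    gff_path: str | Path,
    te_bed_path: str | Path | None = None,
    flank: int = 2000,
    contig_lengths: dict[str, int] | None = None,
    haplotype_of_chrom=None,
) -> pd.DataFrame:
    """Build the five-way feature annotation from a gene GFF3 and a TE BED.

    Emits, per gene, a ``gene_body`` interval plus strand-aware
    ``promoter2kb`` (upstream of the TSS) and ``downstream2kb`` (past the
    TTS) flanks of ``flank`` bp, clipped at contig edges and flagged
    ``truncated`` when clipped; ``TE`` intervals come from the BED file and
    ``intergenic`` is the per-contig complement of the union of the other
    four classes. Classes may overlap one another.

    Returns a DataFrame with columns chrom, start, end (0-based half-open),
    strand, kind, gene_id, haplotype, truncated.
    """
    import gffutils

    if contig_lengths is None:
        contig_lengths = read_contig_lengths(gff_path)
    if not contig_lengths:
        raise FormatError(f"{gff_path}: no ##sequence-region pragmas and no "
                          "contig_lengths supplied")
    if haplotype_of_chrom is None:
        haplotype_of_chrom = infer_haplotype
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValidationError(f"gene {gene.id}: unknown strand {gene.strand!r}")
        clen = contig_lengths.get(gene.seqid)
        if clen is None:
            raise ValidationError(f"gene {gene.id}: contig {gene.seqid} has no length")
        start, end = gene.start - 1, gene.end  # GFF 1-based closed -> half-open
        if end > clen:
            end = clen  # clipped with a warning-level flag below
        hap = haplotype_of_chrom(gene.seqid)
        gid = gene.id
        rows.append((gene.seqid, start, end, gene.strand, "gene_body", gid, hap, end != gene.end))
        if gene.strand == "+":
            ps, pe = max(0, start - flank), start
            ds, de = end, min(clen, end + flank)
        else:
            ps, pe = end, min(clen, end + flank)
            ds, de = max(0, start - flank), start
        if pe > ps:
            rows.append((gene.seqid, ps, pe, gene.strand, "promoter2kb", gid, hap,
                         pe - ps != flank))
        if de > ds:
            rows.append((gene.seqid, ds, de, gene.strand, "downstream2kb", gid, hap,
                         de - ds != flank))
    if te_bed_path is not None:
        bed = pd.read_csv(
            te_bed_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        ) if Path(te_bed_path).stat().st_size else pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"])
        for r in bed.itertuples(index=False):
            rows.append((r.chrom, int(r.start), int(r.end), str(r.strand),
                         "TE", r.name if isinstance(r.name, str) else None,
                         haplotype_of_chrom(r.chrom), False))

    feats = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "kind", "gene_id",
                       "haplotype", "truncated"],
    )
    # intergenic = complement of everything else, per contig
    inter = []
    for chrom, clen in contig_lengths.items():
        sub = feats[feats["chrom"] == chrom]
        for s, e in _complement(sub[["start", "end"]].to_numpy(), clen):
            inter.append((chrom, s, e, ".", "intergenic", None,
                          haplotype_of_chrom(chrom), False))
    feats = pd.concat(
        [feats, pd.DataFrame(inter, columns=feats.columns)], ignore_index=True
    )
    return feats.sort_values(["chrom", "start", "end", "kind"], ignore_index=True)


def infer_haplotype(chrom: str) -> str | None:
    """Haplotype from a ``HM_``/``HC_`` chromosome-name prefix, else None."""
    if chrom.startswith("HM"):
        return "HM"
    if chrom.startswith("HC"):
        return "HC"
    return None


def _complement(intervals: np.ndarray, length: int) -> list[tuple[int, int]]:
    if intervals.size == 0:
        return [(0, length)] if length > 0 else []
    iv = intervals[np.argsort(intervals[:, 0])]
    out, cursor = [], 0
    for s, e in iv:
        s = max(int(s), 0)
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, int(e))
    if cursor < length:
        out.append((cursor, length))
    return out


def write_annotations_gff(features: pd.DataFrame, contig_lengths: dict[str, int],
                          path: str | Path) -> None:
    """Write gene features as GFF3 (1-based closed) with length pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, clen in contig_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {clen}\n")
        genes = features[features["kind"] == "gene_body"]
        for r in genes.itertuples(index=False):
            attrs = f"ID={r.gene_id}"
            fh.write(f"{r.chrom}\thapmeth\tgene\t{r.start + 1}\t{r.end}\t.\t"
                     f"{r.strand}\t.\t{attrs}\n")


def write_te_bed(features: pd.DataFrame, path: str | Path) -> None:
    """Write TE features as BED6 (0-based half-open)."""
    tes = features[features["kind"] == "TE"]
    with open(path, "w") as fh:
        for i, r in enumerate(tes.itertuples(index=False)):
            name = r.gene_id or f"TE{i:05d}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Allele map and expression
# ---------------------------------------------------------------------------

def read_allele_pairs(
    path: str | Path,
    annotations: pd.DataFrame | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[ParseIssue]]:
    """Read the two-column (HM gene, HC gene) allele map.

    Allele "a" is always the haplotype-M member and allele "b" the
    haplotype-C member. With ``annotations`` given, both ids must be
    annotated genes; a gene appearing in more than one pair is rejected.
    ``on_error="collect"`` reports rejected rows instead of raising.
    """
    if on_error not in ("collect", "raise"):
        raise ValueError("on_error must be 'collect' or 'raise'")
    known = None
    if annotations is not None:
        known = set(annotations.loc[annotations["kind"] == "gene_body", "gene_id"])
    rows, issues = [], []
    seen: set[str] = set()

    def reject(lineno, message):
        if on_error == "raise":
            raise ValidationError(f"{path}: line {lineno}: {message}")
        issues.append(ParseIssue(lineno, message))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            a, b = parts[0], parts[1]
            if known is not None:
                absent = [g for g in (a, b) if g not in known]
                if absent:
                    reject(lineno, f"gene id(s) not annotated: {', '.join(absent)}")
                    continue
            dup = [g for g in (a, b) if g in seen]
            if dup:
                reject(lineno, f"gene(s) in multiple pairs: {', '.join(dup)}")
                continue
            seen.update((a, b))
            rows.append((f"{a}|{b}", a, b))
    pairs = pd.DataFrame(rows, columns=["pair_id", "a", "b"])
    return pairs, issues


def write_allele_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[["a", "b"]].to_csv(path, sep="\t", header=False, index=False)


_EXPR_COL_RE = re.compile(r"^(LS\d+)_rep(\d+)$")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read the FPKM table: ``gene_id`` column then ``LSx_repy`` columns.

    Returns a DataFrame indexed by gene_id with a (stage, replicate)
    MultiIndex on the columns. Values are raw FPKM; no log transform is
    applied here. Negative or missing cells raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing column gene_id")
    df = df.set_index("gene_id")
    cols = []
    for c in df.columns:
        m = _EXPR_COL_RE.match(c)
        if not m:
            raise FormatError(f"{path}: column {c!r} is not of the form LSx_repy")
        cols.append((m.group(1), int(m.group(2))))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["stage", "replicate"])
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)]
        raise ValidationError(f"missing FPKM value(s) for gene(s): "
                              f"{', '.join(map(str, bad[:5]))}")
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)]
        raise ValidationError(f"negative FPKM for gene(s): "
                              f"{', '.join(map(str, bad[:5]))}")
    return df


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    out = expression.copy()
    out.columns = [f"{s}_rep{r}" for s, r in out.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SampleDesign:
    """One WGBS library: haplotype-resolved stage/replicate sample."""

    stage: str
    replicate: int
    haplotype: str | None = None
    path: str | None = None


def check_design(samples: list[SampleDesign], min_replicates: int = 2) -> None:
    """Validate uniqueness of (haplotype, stage, replicate) and replication."""
    keys = [(s.haplotype, s.stage, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (haplotype, stage, replicate) in design")
    per_stage: dict[tuple, int] = {}
    for s in samples:
        per_stage[(s.haplotype, s.stage)] = per_stage.get((s.haplotype, s.stage), 0) + 1
    low = [k for k, n in per_stage.items() if n < min_replicates]
    if low:
        raise ValidationError(f"stages with fewer than {min_replicates} replicates: {low}")
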