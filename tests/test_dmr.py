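"""DMR-calling thresholds, merging, annotation and symmetry."""

import numpy as np
import pandas as pd
import pytest

from hapmeth.dmr import (DMC_DELTA, DifferentialMethylation, DMRParams,
                         annotate_dmrs, call_dmcs, compare_sets,
                         dmg_expression_contrast, feature_kind_counts,
                         fold_change, retain_and_merge, score_windows,
                         select_dm_windows)
from tests.conftest import make_calls


def window_row(q, l1, l2, start=0, context="CG", chrom="c"):
    return {"chrom": chrom, "start": start, "end": start + 200,
            "context": context, "mc1": 0, "cov1": 1, "mc2": 0, "cov2": 1,
            "n_cyt1": 1, "n_cyt2": 1, "level1": l1, "level2": l2,
            "p_value": q, "q_value": q,
            "fold_change": fold_change(l1, l2),
            "direction": "hyper" if l2 > l1 else "hypo"}


def test_select_fdr_boundary_is_strict():
    w = pd.DataFrame([window_row(0.05, 0.1, 0.9),
                      window_row(0.049999, 0.1, 0.9, start=400)])
    kept = select_dm_windows(w)
    assert kept["start"].tolist() == [400]  # q = 0.05 exactly is rejected


def test_select_fc_boundary_inclusive():
    # levels 0.30 vs 0.46 -> (0.47/0.31) = 1.516 >= 1.5: kept
    # a fold change of exactly 1.5 is accepted (>=, not >)
    # identical levels: excluded; FC 1.29: excluded
    rows = [window_row(1e-4, 0.30, 0.46, start=0),
            window_row(1e-4, 0.20, 0.30, start=400),
            window_row(1e-4, 0.3, 0.3, start=800),
            window_row(1e-4, 0.30, 0.40, start=1200)]
    rows[1]["fold_change"] = 1.5  # boundary value, exact
    w = pd.DataFrame(rows)
    assert w.iloc[0]["fold_change"] == pytest.approx(0.47 / 0.31)
    kept = select_dm_windows(w)
    assert kept["start"].tolist() == [0, 400]
    assert (kept["direction"] == "hyper").all()


def candidate(start, end, context="CG", direction="hyper", chrom="c"):
    return {"chrom": chrom, "start": start, "end": end, "context": context,
            "direction": direction}


def pooled_sites(rows):
    return make_calls(rows)


def test_dmc_delta_thresholds_per_context():
    """Per-cytosine |delta| gates: 0.39 CG rejected, 0.40 CG accepted,
    0.12 CHH accepted, delta 0 never a DMC."""
    cand = pd.DataFrame([candidate(0, 200), candidate(0, 200, context="CHH")])
    p1 = pooled_sites([("c", 10, "+", "CG", 0, 100),
                       ("c", 20, "+", "CG", 0, 100),
                       ("c", 30, "+", "CHH", 0, 100),
                       ("c", 40, "+", "CG", 50, 100)])
    p2 = pooled_sites([("c", 10, "+", "CG", 39, 100),   # delta 0.39
                       ("c", 20, "+", "CG", 40, 100),   # delta 0.40
                       ("c", 30, "+", "CHH", 12, 100),  # delta 0.12
                       ("c", 40, "+", "CG", 50, 100)])  # delta 0
    sites = call_dmcs(cand, p1, p2).set_index("pos")
    assert not sites.loc[10, "is_dmc"]
    assert sites.loc[20, "is_dmc"]
    assert sites.loc[30, "is_dmc"]
    assert not sites.loc[40, "is_dmc"]


def test_dmc_fc_gate():
    """A large delta at high base levels can fail the FC >= 2 gate."""
    cand = pd.DataFrame([candidate(0, 200)])
    p1 = pooled_sites([("c", 10, "+", "CG", 55, 100)])
    p2 = pooled_sites([("c", 10, "+", "CG", 100, 100)])  # 0.55 -> 1.0
    sites = call_dmcs(cand, p1, p2)
    assert sites.iloc[0]["delta"] == pytest.approx(0.45)
    assert not sites.iloc[0]["is_dmc"]  # FC = 1.01/0.56 < 2


def dmc_sites(positions, context="CG", chrom="c"):
    rows = [{"chrom": chrom, "pos": p, "strand": "+", "context": context,
             "is_dmc": True} for p in positions]
    return pd.DataFrame(rows)


def test_retention_requires_seven_dmcs():
    cand = pd.DataFrame([candidate(0, 200)])
    assert retain_and_merge(cand, dmc_sites(range(6))).empty
    kept = retain_and_merge(cand, dmc_sites(range(7)))
    assert len(kept) == 1 and kept.iloc[0]["n_dmcs"] == 7


def test_merge_gap_boundary():
    sites = dmc_sites(list(range(0, 140, 20)) + list(range(300, 440, 20))
                      + list(range(1000, 1140, 20)))
    cand = pd.DataFrame([candidate(0, 200), candidate(300, 500),  # gap 100
                         candidate(1000, 1200)])                  # gap 500
    out = retain_and_merge(cand, sites)
    assert len(out) == 2
    assert out.iloc[0][["start", "end"]].tolist() == [0, 500]  # merged
    # gap 101: stays separate
    cand2 = pd.DataFrame([candidate(0, 200), candidate(301, 501)])
    sites2 = dmc_sites(list(range(0, 140, 20)) + list(range(310, 450, 20)))
    assert len(retain_and_merge(cand2, sites2)) == 2


def test_merge_never_bridges_direction_or_context():
    sites = pd.concat([dmc_sites(range(0, 140, 20)),
                       dmc_sites(range(250, 390, 20))], ignore_index=True)
    cand = pd.DataFrame([candidate(0, 200, direction="hyper"),
                         candidate(250, 450, direction="hypo")])
    out = retain_and_merge(cand, sites)
    assert len(out) == 2


def test_merge_idempotent():
    sites = dmc_sites(list(range(0, 140, 20)) + list(range(260, 400, 20)))
    cand = pd.DataFrame([candidate(0, 200), candidate(150, 350),
                         candidate(260, 460)])
    once = retain_and_merge(cand, sites)
    again = retain_and_merge(
        once.rename(columns={})[["chrom", "start", "end", "context",
                                 "direction"]], sites)
    pd.testing.assert_frame_equal(
        once[["chrom", "start", "end", "context", "direction", "n_dmcs"]],
        again[["chrom", "start", "end", "context", "direction", "n_dmcs"]])


def test_overlapping_windows_count_dmcs_once():
    # two overlapping windows share DMCs; the run must count distinct sites
    sites = dmc_sites([10, 30, 50, 70, 90, 110, 130])
    cand = pd.DataFrame([candidate(0, 200), candidate(50, 250)])
    out = retain_and_merge(cand, sites)
    assert len(out) == 1 and out.iloc[0]["n_dmcs"] == 7


FEATS = pd.DataFrame(
    [("c", 2000, 4000, "+", "promoter2kb", "g1", "HM", False),
     ("c", 4000, 6000, "+", "gene_body", "g1", "HM", False),
     ("c", 8000, 8500, "+", "TE", "TE1", "HM", False),
     ("c", 6000, 10000, ".", "intergenic", None, "HM", False)],
    columns=["chrom", "start", "end", "strand", "kind", "gene_id",
             "haplotype", "truncated"])


def test_annotation_multilabel():
    dmrs = pd.DataFrame([
        {"chrom": "c", "start": 2500, "end": 2700, "context": "CG",
         "direction": "hyper", "n_dmcs": 8, "n_windows": 2},   # promoter only
        {"chrom": "c", "start": 3900, "end": 4100, "context": "CG",
         "direction": "hyper", "n_dmcs": 8, "n_windows": 2},   # promoter+body
        {"chrom": "c", "start": 8100, "end": 8300, "context": "CHH",
         "direction": "hypo", "n_dmcs": 9, "n_windows": 2}])   # TE+intergenic
    ann = annotate_dmrs(dmrs, FEATS)
    assert ann.iloc[0]["kinds"] == "promoter2kb"
    assert ann.iloc[0]["dmp_genes"] == "g1" and ann.iloc[0]["dmg_genes"] == ""
    assert ann.iloc[1]["kinds"] == "gene_body,promoter2kb"
    assert ann.iloc[1]["dmg_genes"] == "g1"
    assert ann.iloc[2]["kinds"] == "TE,intergenic"
    counts = feature_kind_counts(ann)
    assert counts.set_index(["context", "direction", "kind"])["n"].loc[
        ("CG", "hyper", "promoter2kb")] == 2


def test_compare_sets():
    out = compare_sets({"a", "b", "c"}, {"b", "c", "d"})
    assert out["intersection"] == 2 and out["union"] == 4
    assert compare_sets(set(), {"x"})["intersection"] == 0
    same = compare_sets({"a", "b"}, {"a", "b"})
    assert same["intersection"] == same["n1"] == 2


def expression_table(genes, values):
    cols = pd.MultiIndex.from_product([["LS1"], [1, 2, 3]],
                                      names=["stage", "replicate"])
    return pd.DataFrame(np.array(values), index=pd.Index(genes, name="gene_id"),
                        columns=cols)


def test_dmg_expression_contrast():
    expr = expression_table(
        ["h1", "h2", "h3", "l1", "l2", "l3"],
        [[1, 1, 1]] * 3 + [[31, 31, 31]] * 3)
    out = dmg_expression_contrast(["h1", "h2", "h3"], ["l1", "l2", "l3"], expr)
    assert out["testable"] and out["hyper_mean"] < out["hypo_mean"]
    assert out["p_value"] < 0.01  # one-tailed: hyper < hypo
    sym = dmg_expression_contrast(["h1", "h2"], ["h1", "h2"], expr)
    assert sym["p_value"] == pytest.approx(0.5)  # identical groups
    small = dmg_expression_contrast(["h1"], ["l1", "l2"], expr)
    assert not small["testable"] and np.isnan(small["p_value"])


def simulate_two_groups(seed, n_sites=300, effect_from=100, effect_to=220):
    """Tiny direct two-group dataset with a planted block difference."""
    rng = np.random.default_rng(seed)
    pos = np.arange(n_sites) * 4
    ctx = np.full(n_sites, "CG")
    cov = rng.integers(20, 40, size=(2, 3, n_sites))
    level = np.full(n_sites, 0.2)
    g1 = [make_calls(list(zip(["c"] * n_sites, pos, ["+"] * n_sites, ctx,
                              rng.binomial(cov[0, r], level), cov[0, r])))
          for r in range(3)]
    level2 = level.copy()
    level2[(pos >= effect_from * 4) & (pos < effect_to * 4)] = 0.8
    g2 = [make_calls(list(zip(["c"] * n_sites, pos, ["+"] * n_sites, ctx,
                              rng.binomial(cov[1, r], level2), cov[1, r])))
          for r in range(3)]
    return g1, g2


def test_group_swap_symmetry():
    """Swapping groups swaps hyper<->hypo and changes nothing else."""
    g1, g2 = simulate_two_groups(4)
    lengths = {"c": 1200}
    fwd = DifferentialMethylation(g1, g2, lengths, contexts=("CG",)).fit()
    rev = DifferentialMethylation(g2, g1, lengths, contexts=("CG",)).fit()
    assert len(fwd.dmrs) >= 1
    np.testing.assert_allclose(fwd.windows["p_value"], rev.windows["p_value"])
    flip = {"hyper": "hypo", "hypo": "hyper"}
    pd.testing.assert_frame_equal(
        fwd.dmrs.assign(direction=fwd.dmrs["direction"].map(flip)),
        rev.dmrs)


def test_chunked_replicates_identical():
    g1, g2 = simulate_two_groups(9)
    lengths = {"c": 1200}
    whole = DifferentialMethylation(g1, g2, lengths, contexts=("CG",)).fit()
    split = DifferentialMethylation(
        [df.iloc[:150] for df in g1] + [df.iloc[150:] for df in g1],
        [df.iloc[:150] for df in g2] + [df.iloc[150:] for df in g2],
        lengths, contexts=("CG",)).fit()
    pd.testing.assert_frame_equal(whole.dmrs, split.dmrs)
    pd.testing.assert_frame_equal(whole.windows, split.windows)


def test_params_validation_and_summary():
    with pytest.raises(ValueError):
        DMRParams(fdr=1.5).validate()
    with pytest.raises(ValueError):
        DMRParams(width=200, step=60).validate()
    g1, g2 = simulate_two_groups(4)
    res = DifferentialMethylation(g1, g2, {"c": 1200}, contexts=("CG",)).fit()
    s = res.summary()
    assert "CG" in s and "hyper" in s
    assert DMC_DELTA == {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
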