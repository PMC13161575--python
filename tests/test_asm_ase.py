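"""ASM/ASE calling, consistency classification and association."""

import numpy as np
import pandas as pd
import pytest

from hapmeth.asm import (AlleleSpecificExpression, AlleleSpecificMethylation,
                         allele_meth_expression_profile, asm_ase_association,
                         asm_ase_overlap, consistency_classify, count_bias)
from tests.conftest import make_calls

STAGES5 = ("LS1", "LS2", "LS3", "LS4", "LS5")


@pytest.mark.parametrize("statuses,expected", [
    (["a-biased"] * 5, "consistent a-biased"),
    (["b-biased"] * 5, "consistent b-biased"),
    (["a-biased"] * 4 + ["none"], "inconsistent"),
    (["a-biased"] * 3 + ["b-biased"] * 2, "inconsistent"),
    (["none"] * 5, "none"),
    (["untestable"] * 5, "none"),
])
def test_consistency_classification(statuses, expected):
    assert consistency_classify(statuses, 5) == expected


def test_consistency_is_stage_order_invariant():
    statuses = ["a-biased", "b-biased", "a-biased", "a-biased", "a-biased"]
    rng = np.random.default_rng(0)
    base = consistency_classify(statuses, 5)
    for _ in range(5):
        rng.shuffle(statuses)
        assert consistency_classify(statuses, 5) == base


def test_count_bias_tally():
    rec = pd.DataFrame({
        "stage": ["LS1"] * 5 + ["LS2"],
        "context": ["CG"] * 6,
        "region": ["gene_body"] * 6,
        "status": ["a-biased", "a-biased", "a-biased", "b-biased", "b-biased",
                   "a-biased"]})
    assert count_bias(rec, stage="LS1") == (3, 2)
    assert count_bias(rec) == (4, 2)
    assert count_bias(rec.iloc[:0]) == (0, 0)


# ---------------------------------------------------------------------------
# ASM on constructed haplotype data
# ---------------------------------------------------------------------------

def hap_samples(level_a, level_b, stages=STAGES5, n_sites=120, cov=30,
                length=6000):
    """Fully separated allele levels over a 2-kb gene body on each haplotype."""
    pos = np.linspace(2050, 3950, n_sites).astype(int)
    samples = {}
    for hap, level in (("HM", level_a), ("HC", level_b)):
        chrom = f"{hap}_chr1"
        for stage in stages:
            for rep in (1, 2, 3):
                mc = np.full(n_sites, int(round(cov * level)))
                samples[(hap, stage, rep)] = make_calls(list(zip(
                    [chrom] * n_sites, pos, ["+"] * n_sites, ["CG"] * n_sites,
                    mc, [cov] * n_sites)))
    features = pd.DataFrame(
        [("HM_chr1", 2000, 4000, "+", "gene_body", "gM1", "HM", False),
         ("HC_chr1", 2000, 4000, "+", "gene_body", "gC1", "HC", False)],
        columns=["chrom", "start", "end", "strand", "kind", "gene_id",
                 "haplotype", "truncated"])
    pairs = pd.DataFrame({"pair_id": ["gM1|gC1"], "a": ["gM1"], "b": ["gC1"]})
    lengths = {"HM_chr1": length, "HC_chr1": length}
    cmap = [("chr1", "HM_chr1", "HC_chr1")]
    return samples, pairs, features, cmap, lengths


def test_asm_extreme_separation_called_b_biased():
    """Allele b fully methylated, a unmethylated: every stage b-biased and
    the pair classifies as consistent b-biased."""
    args = hap_samples(0.0, 1.0)
    fit = AlleleSpecificMethylation(*args, regions=("gene_body",),
                                    contexts=("CG",)).fit()
    rec = fit.records
    assert (rec["status"] == "b-biased").all() and len(rec) == 5
    cons = fit.consistency()
    assert cons.iloc[0]["classification"] == "consistent b-biased"
    assert fit.counts(context="CG") == (0, 5)


def test_asm_identical_alleles_is_none():
    args = hap_samples(0.5, 0.5)
    fit = AlleleSpecificMethylation(*args, regions=("gene_body",),
                                    contexts=("CG",)).fit()
    assert (fit.records["status"] == "none").all()


def test_asm_uncovered_region_untestable():
    samples, pairs, features, cmap, lengths = hap_samples(0.0, 1.0)
    empty = {k: v.iloc[:0] for k, v in samples.items()}
    fit = AlleleSpecificMethylation(empty, pairs, features, cmap, lengths,
                                    regions=("gene_body",),
                                    contexts=("CG",)).fit()
    assert (fit.records["status"] == "untestable").all()


def test_asm_label_swap_symmetry():
    """Relabelling the haplotypes swaps a-biased and b-biased exactly."""
    samples, pairs, features, cmap, lengths = hap_samples(1.0, 0.0)
    fwd = AlleleSpecificMethylation(samples, pairs, features, cmap, lengths,
                                    regions=("gene_body",),
                                    contexts=("CG",)).fit()
    rename = {"HM_chr1": "HC_chr1", "HC_chr1": "HM_chr1"}
    swapped_samples = {}
    for (hap, stage, rep), calls in samples.items():
        c = calls.copy()
        c["chrom"] = c["chrom"].map(rename)
        swapped_samples[({"HM": "HC", "HC": "HM"}[hap], stage, rep)] = c
    sw_features = features.copy()
    sw_features["chrom"] = sw_features["chrom"].map(rename)
    sw_features["haplotype"] = sw_features["haplotype"].map(
        {"HM": "HC", "HC": "HM"})
    sw_pairs = pairs.rename(columns={"a": "b", "b": "a"})
    rev = AlleleSpecificMethylation(swapped_samples, sw_pairs, sw_features,
                                    cmap, lengths, regions=("gene_body",),
                                    contexts=("CG",)).fit()
    flip = {"a-biased": "b-biased", "b-biased": "a-biased",
            "none": "none", "untestable": "untestable"}
    assert rev.records["status"].tolist() == \
        fwd.records["status"].map(flip).tolist()
    np.testing.assert_allclose(rev.records["delta"], -fwd.records["delta"])


# ---------------------------------------------------------------------------
# ASE
# ---------------------------------------------------------------------------

def expr_table(rows, stages=("LS1",)):
    cols = pd.MultiIndex.from_product([stages, [1, 2, 3]],
                                      names=["stage", "replicate"])
    return pd.DataFrame(rows, index=pd.Index(
        [f"g{i}" for i in range(len(rows))], name="gene_id"), columns=cols)


def pairs_for(n):
    return pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(n)],
        "a": [f"g{2 * i}" for i in range(n)],
        "b": [f"g{2 * i + 1}" for i in range(n)]})


def test_ase_directions_and_ratio_gate():
    # pair 0: equal -> balanced; pair 1: a = 8x b -> a-biased;
    # pair 2: ratio 1.5, tiny noise -> balanced despite significance
    expr = expr_table([
        [10, 10.01, 9.99], [10, 10.01, 9.99],
        [80, 80.5, 79.5], [10, 10.05, 9.95],
        [15, 15.01, 14.99], [10, 10.01, 9.99]])
    fit = AlleleSpecificExpression(expr, pairs_for(3)).fit()
    rec = fit.records.set_index("pair_id")
    assert rec.loc["p0", "direction"] == "balanced"
    assert rec.loc["p1", "direction"] == "a-biased"
    assert rec.loc["p2", "direction"] == "balanced"
    assert rec.loc["p2", "q_value"] < 0.05  # significant but gated by ratio


def test_ase_consistency_and_sets():
    stages = ("LS1", "LS2")
    a_hi = [[80, 81, 79], [10, 10, 10.1]]
    expr = expr_table([a_hi[0] * 1 + a_hi[0], a_hi[1] + a_hi[1]],
                      stages=stages)
    fit = AlleleSpecificExpression(expr, pairs_for(1)).fit()
    cons = fit.consistency()
    assert cons.iloc[0]["classification"] == "consistent a-biased"
    assert fit.biased_pairs("a-biased", stage="LS1") == {"p0"}


def test_ase_single_replicate_untestable():
    cols = pd.MultiIndex.from_product([["LS1"], [1]],
                                      names=["stage", "replicate"])
    expr = pd.DataFrame([[10.0], [20.0]],
                        index=pd.Index(["g0", "g1"], name="gene_id"),
                        columns=cols)
    fit = AlleleSpecificExpression(expr, pairs_for(1)).fit()
    assert fit.records.iloc[0]["direction"] == "untestable"


# ---------------------------------------------------------------------------
# Association and profiles
# ---------------------------------------------------------------------------

def level_matrix(deltas, stage="LS1", context="CG", region="promoter2kb"):
    rows, idx = [], []
    for i, d in enumerate(deltas):
        idx += [(f"p{i}", "a", f"g{2 * i}"), (f"p{i}", "b", f"g{2 * i + 1}")]
        rows += [{(stage, context, region): 0.5 + d / 2},
                 {(stage, context, region): 0.5 - d / 2}]
    m = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        idx, names=["pair_id", "allele", "gene_id"]))
    m.columns = pd.MultiIndex.from_tuples(m.columns,
                                          names=["stage", "context", "region"])
    return m


def ase_records(directions, stage="LS1"):
    return pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(len(directions))],
        "stage": stage, "direction": directions,
        "mean_a": 1.0, "mean_b": 1.0})


def test_association_sign_pattern():
    # b-biased ASE genes carry positive (a - b) methylation differences
    matrix = level_matrix([0.4, 0.5, 0.45, -0.4, -0.5, -0.45])
    rec = ase_records(["b-biased"] * 3 + ["a-biased"] * 3)
    out = asm_ase_association(matrix, rec, stage="LS1").set_index("ase_group")
    assert out.loc["b-biased", "mean_delta"] > 0
    assert out.loc["b-biased", "p_value"] < 0.05
    assert out.loc["a-biased", "mean_delta"] < 0
    assert out.loc["a-biased", "p_value"] < 0.05


def test_association_degenerate_all_zero():
    matrix = level_matrix([0.0, 0.0, 0.0])
    out = asm_ase_association(matrix, ase_records(["b-biased"] * 3),
                              stage="LS1").set_index("ase_group")
    assert out.loc["b-biased", "mean_delta"] == 0.0
    assert out.loc["b-biased", "p_value"] == 0.5


def test_association_small_group_flagged():
    matrix = level_matrix([0.4])
    out = asm_ase_association(matrix, ase_records(["b-biased"]),
                              stage="LS1").set_index("ase_group")
    assert not out.loc["b-biased", "testable"]


@pytest.mark.parametrize("asm,ase,frac", [
    (set("abcdefghij"), set("abc"), 0.3),
    (set("ab"), set("cd"), 0.0),
    (set("ab"), set("ab"), 1.0),
])
def test_asm_ase_overlap(asm, ase, frac):
    assert asm_ase_overlap(asm, ase)["fraction"] == pytest.approx(frac)


def test_allele_meth_expression_profile_anticorrelated():
    stages = ("LS1", "LS2", "LS3")
    idx = pd.MultiIndex.from_tuples([("p0", "a", "g0"), ("p0", "b", "g1")],
                                    names=["pair_id", "allele", "gene_id"])
    cols = pd.MultiIndex.from_tuples(
        [(s, "CG", "promoter2kb") for s in stages],
        names=["stage", "context", "region"])
    matrix = pd.DataFrame([[0.2, 0.5, 0.8], [0.3, 0.3, 0.3]],
                          index=idx, columns=cols)
    rec = pd.DataFrame({
        "pair_id": "p0", "stage": stages,
        "mean_a": [30.0, 20.0, 10.0], "mean_b": [5.0, 5.0, 5.0],
        "direction": "balanced"})
    prof = allele_meth_expression_profile("p0", matrix, rec)
    a = prof[prof["allele"] == "a"]
    assert a["spearman_rho"].iloc[0] == pytest.approx(-1.0)
    b = prof[prof["allele"] == "b"]
    assert np.isnan(b["spearman_rho"].iloc[0])  # constant level: undefined
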