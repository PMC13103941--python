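"""Pseudobulk aggregation, expression and composition tests, Fisher exact
and BH adjustment, each against an independent oracle where one exists."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from oscellkit import pseudobulk
from oscellkit.config import SimConfig
from oscellkit import synthetic


def _random_fixture(rng, n_cells=200, n_genes=30):
    counts = sp.csr_matrix(rng.poisson(2.0, (n_cells, n_genes)))
    barcodes = [f"bc{i}" for i in range(n_cells)]
    genes = [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame({
        "sample": rng.choice(["s1", "s2", "s3"], n_cells),
        "group": "A",
        "celltype": rng.choice(["T", "B"], n_cells),
    }, index=barcodes)
    meta["group"] = meta["sample"].map({"s1": "A", "s2": "A", "s3": "B"})
    return counts, barcodes, genes, meta


def test_aggregate_matches_nested_loop_oracle(rng):
    counts, barcodes, genes, meta = _random_fixture(rng)
    pb = pseudobulk.aggregate_pseudobulk(counts, barcodes, genes, meta, "T")
    dense = counts.toarray()
    for s in pb.counts.columns:
        expected = np.zeros(len(genes), dtype=int)
        for i, bc in enumerate(barcodes):
            if meta.loc[bc, "sample"] == s and meta.loc[bc, "celltype"] == "T":
                expected += dense[i]
        np.testing.assert_array_equal(pb.counts[s].to_numpy(), expected)
    # conservation
    sel = (meta["celltype"] == "T").to_numpy()
    assert pb.counts.to_numpy().sum() == dense[sel].sum()


def test_aggregate_single_cell_per_sample(rng):
    counts = sp.csr_matrix(rng.poisson(3.0, (2, 10)))
    meta = pd.DataFrame({"sample": ["s1", "s2"], "group": ["A", "B"],
                         "celltype": ["T", "T"]}, index=["b0", "b1"])
    pb = pseudobulk.aggregate_pseudobulk(
        counts, ["b0", "b1"], [f"g{i}" for i in range(10)], meta, "T")
    np.testing.assert_array_equal(pb.counts["s1"], counts.toarray()[0])


def test_aggregate_unknown_celltype(rng):
    counts, barcodes, genes, meta = _random_fixture(rng)
    with pytest.raises(ValueError, match="unknown cell type"):
        pseudobulk.aggregate_pseudobulk(counts, barcodes, genes, meta, "X")


def test_de_identical_groups_zero_fold_change(rng):
    counts = pd.DataFrame(rng.poisson(20.0, (50, 4)),
                          index=[f"g{i}" for i in range(50)],
                          columns=["a1", "a2", "b1", "b2"])
    counts["b1"], counts["b2"] = counts["a1"], counts["a2"]
    pb = pseudobulk.PseudobulkMatrix(
        counts, pd.Series(["A", "A", "B", "B"], index=counts.columns), "T")
    res = pseudobulk.pseudobulk_de(pb, "A", "B")
    np.testing.assert_allclose(res["log2fc"], 0, atol=1e-12)


def test_de_recovers_planted_genes():
    cfg = SimConfig(seed=21, n_genes=300, cells_per_sample=300,
                    frac_low_complexity=0.0, frac_high_mito=0.0)
    sim = synthetic.simulate_counts(cfg)
    pb = pseudobulk.aggregate_pseudobulk(
        sim.counts, sim.barcodes, list(sim.features["gene_id"]),
        sim.metadata, "Malignant")
    res = pseudobulk.pseudobulk_de(pb, "TKO", "DKO").set_index("gene")
    planted = sim.truth.de_gene_ids
    hits = res.loc[list(planted)]
    recall = (hits["fdr"] < 0.05).mean()
    assert recall >= 0.8
    signs = np.sign(hits["log2fc"])
    truth_signs = pd.Series(planted)
    assert (signs == truth_signs.loc[hits.index]).mean() >= 0.9


def test_de_null_calibration():
    cfg = SimConfig(seed=22, n_genes=2000, cells_per_sample=300,
                    de_log2fc=0.0, frac_low_complexity=0.0,
                    frac_high_mito=0.0)
    sim = synthetic.simulate_counts(cfg)
    pb = pseudobulk.aggregate_pseudobulk(
        sim.counts, sim.barcodes, list(sim.features["gene_id"]),
        sim.metadata, "Malignant")
    res = pseudobulk.pseudobulk_de(pb, "TKO", "DKO")
    expressed = res[pb.counts.sum(axis=1).to_numpy() > 20]
    rate = (expressed["p"] < 0.05).mean()
    assert 0.02 <= rate <= 0.08


def test_de_requires_replicates(rng):
    counts = pd.DataFrame(rng.poisson(5.0, (10, 3)),
                          index=[f"g{i}" for i in range(10)],
                          columns=["a1", "a2", "b1"])
    pb = pseudobulk.PseudobulkMatrix(
        counts, pd.Series(["A", "A", "B"], index=counts.columns), "T")
    with pytest.raises(ValueError, match=">= 2 samples"):
        pseudobulk.pseudobulk_de(pb, "A", "B")


def test_asin_sqrt_hand_value():
    assert np.isclose(pseudobulk.asin_sqrt(0.25), 0.5236, atol=1e-4)
    assert pseudobulk.asin_sqrt(0.0) == 0.0
    assert np.isclose(pseudobulk.asin_sqrt(1.0), np.pi / 2)


def _meta_from_counts(counts_by_sample, groups):
    rows = []
    for sample, units in counts_by_sample.items():
        for unit, k in units.items():
            for i in range(k):
                rows.append((f"{sample}:{unit}{i}", sample, groups[sample], unit))
    return pd.DataFrame(rows, columns=["barcode", "sample", "group",
                                       "celltype"]).set_index("barcode")


def test_proportion_test_identical_composition_p1():
    meta = _meta_from_counts(
        {s: {"T": 30, "B": 10} for s in ["a1", "a2", "b1", "b2"]},
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    res, props = pseudobulk.proportion_test(meta)
    assert (res["p"] == 1.0).all()
    np.testing.assert_allclose(props.sum(axis=1), 1.0)


def test_proportion_test_scale_invariance():
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    base = {"a1": {"T": 30, "B": 10}, "a2": {"T": 25, "B": 15},
            "b1": {"T": 10, "B": 30}, "b2": {"T": 12, "B": 28}}
    scaled = {s: {u: 5 * k for u, k in units.items()}
              for s, units in base.items()}
    r1, _ = pseudobulk.proportion_test(_meta_from_counts(base, groups))
    r2, _ = pseudobulk.proportion_test(_meta_from_counts(scaled, groups))
    pd.testing.assert_frame_equal(r1, r2)


def test_proportion_test_absent_unit_still_tested():
    meta = _meta_from_counts(
        {"a1": {"T": 20, "B": 20}, "a2": {"T": 22, "B": 18},
         "b1": {"T": 40}, "b2": {"T": 40}},
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    res, _ = pseudobulk.proportion_test(meta)
    row = res[res["unit"] == "B"].iloc[0]
    assert {row["group_a"], row["group_b"]} == {"A", "B"}
    assert row["p"] < 1.0


def _fisher_oracle(a, b, c, d):
    """Full enumeration over tables with the observed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def prob(k):
        return (math.comb(r1, k) * math.comb(n - r1, c1 - k)
                / math.comb(n, c1))
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    p_obs = prob(a)
    return sum(prob(k) for k in support if prob(k) <= p_obs * (1 + 1e-7))


def test_fisher_symmetric_table():
    odds, p = pseudobulk.fisher_exact_2x2([[5, 5], [5, 5]])
    assert np.isclose(p, 1.0, atol=1e-12) and np.isclose(odds, 1.0)


@pytest.mark.parametrize("table", [[[3, 7], [9, 1]], [[0, 10], [10, 0]],
                                   [[2, 3], [4, 5]], [[8, 2], [1, 9]]])
def test_fisher_matches_enumeration(table):
    (a, b), (c, d) = table
    _, p = pseudobulk.fisher_exact_2x2(table)
    assert np.isclose(p, _fisher_oracle(a, b, c, d), atol=1e-12)


def test_fisher_zero_margin_convention():
    with pytest.warns(UserWarning, match="degenerate margin"):
        _, p = pseudobulk.fisher_exact_2x2([[0, 0], [3, 4]])
    assert p == 1.0


@given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_fisher_agrees_with_scipy(vals):
    from scipy.stats import fisher_exact as scipy_fisher
    a, b, c, d = vals
    if a + b + c + d == 0:
        return
    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    _, p = pseudobulk.fisher_exact_2x2(table)
    assert np.isclose(p, scipy_fisher(table).pvalue, atol=1e-9)


def test_bh_hand_case_and_monotonicity():
    np.testing.assert_allclose(
        pseudobulk.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert pseudobulk.bh_adjust([0.3])[0] == 0.3
    p = np.sort(np.random.default_rng(1).random(50))
    adj = pseudobulk.bh_adjust(p)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj >= p).all() and (adj <= 1.0).all()
    with pytest.raises(ValueError):
        pseudobulk.bh_adjust([0.5, 1.2])
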