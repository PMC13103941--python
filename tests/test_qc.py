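"""Barcode QC: regression diagnostics against brute-force oracles, cutoff
boundary semantics, MAD hand calculations, and per-sample independence."""

import numpy as np
import pandas as pd
import pytest

from oscellkit import qc
from oscellkit.config import QCParams


def _table(n_umi, n_gene, mito=None, hb=None):
    n = len(n_umi)
    return pd.DataFrame({
        "n_umi": np.asarray(n_umi),
        "n_gene": np.asarray(n_gene),
        "pct_mito": np.zeros(n) if mito is None else np.asarray(mito, float),
        "pct_hemoglobin": np.zeros(n) if hb is None else np.asarray(hb, float),
    }, index=[f"bc{i}" for i in range(n)])


def _loo_cooks(x, y):
    """Leave-one-out Cook's distance oracle: refit without i, measure the
    scaled shift of all fitted values."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    fitted = X @ beta
    mse = np.sum((y - fitted) ** 2) / (n - 2)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        shift = X @ beta - X @ beta_i
        out[i] = np.sum(shift**2) / (2 * mse)
    return out


def test_exact_power_law_gives_zero_residuals():
    n_umi = np.array([k**5 for k in range(2, 22)])
    n_gene = np.array([k**4 for k in range(2, 22)])  # n_gene = n_umi ** 0.8
    fit = qc.fit_complexity_regression(_table(n_umi, n_gene))
    np.testing.assert_allclose(fit.table["linear_residual"], 0, atol=1e-9)
    np.testing.assert_allclose(fit.table["loess_residual"], 0, atol=1e-9)
    np.testing.assert_allclose(fit.table["cooks_distance"], 0, atol=1e-9)


def test_cooks_distance_matches_leave_one_out_refit(rng):
    for _ in range(20):
        n = int(rng.integers(10, 30))
        x = rng.normal(7, 1, n)
        y = 0.8 * x + rng.normal(0, 0.3, n)
        tbl = _table(np.exp(x), np.maximum(np.exp(y), 1))
        fit = qc.fit_complexity_regression(tbl)
        oracle = _loo_cooks(np.log(tbl["n_umi"].to_numpy(float)),
                            np.log(tbl["n_gene"].to_numpy(float)))
        np.testing.assert_allclose(fit.table["cooks_distance"], oracle,
                                   atol=1e-8)


def test_leverage_at_mean_is_one_over_n():
    # symmetric x-design plus one barcode exactly at the mean
    x = np.array([6.0, 6.5, 7.5, 8.0, 6.2, 7.8, 6.9, 7.1, 5.0, 9.0, 7.0])
    assert np.isclose(x[-1], x.mean())
    tbl = _table(np.exp(x), np.maximum(np.exp(0.8 * x), 1))
    fit = qc.fit_complexity_regression(tbl)
    assert np.isclose(fit.table["leverage"].iloc[-1], 1 / len(x))
    # leverages sum to the number of linear parameters
    assert np.isclose(fit.table["leverage"].sum(), 2.0, atol=1e-8)


def test_fit_refuses_tiny_or_degenerate_input():
    with pytest.raises(ValueError):
        qc.fit_complexity_regression(_table([10] * 5, [5] * 5))
    with pytest.raises(ValueError):
        qc.fit_complexity_regression(_table([100] * 12, [50] * 12))


def test_low_complexity_requires_conjunction():
    idx = [f"bc{i}" for i in range(3)]
    table = pd.DataFrame({
        "linear_residual": [0.0, -5.0, -5.0],
        "loess_residual": [-5.0, -0.1, -5.0],
        "leverage": [0.1, 0.1, 0.1],
        "cooks_distance": [0.0, 2.0, 2.0],  # threshold is 4/3 at n = 3
    }, index=idx)
    fit = qc.ComplexityFit(table, 1.0, 0.0, 1.0, 0.75, 2)
    flags = qc.flag_low_complexity(fit)["low_complexity"]
    assert not flags.iloc[0]  # deep residual, zero influence
    assert not flags.iloc[1]  # influence without deep residual
    assert flags.iloc[2]
    # printed threshold: 1,000 cells -> 4 / 1000
    big = qc.ComplexityFit(pd.concat([table] * 334, ignore_index=True)[:1000],
                           1.0, 0.0, 1.0, 0.75, 2)
    assert big.n == 1000
    assert qc.flag_low_complexity(big, cooks_multiplier=4.0) is not None
    assert np.isclose(4.0 / big.n, 0.004)


@pytest.mark.parametrize(
    "row,expected_flags",
    [
        ((1000, 500, 1.0, 1.0), {"fail_numi_fixed"}),  # boundary not > 1000
        ((1001, 201, 24.9, 24.9), set()),
        ((5000, 300, 25.0, 1.0), {"fail_mito_fixed"}),
        ((5000, 200, 1.0, 1.0), {"fail_gene_fixed"}),
        ((5000, 300, 1.0, 25.0), {"fail_hb_fixed"}),
    ],
)
def test_fixed_cutoffs_are_strict(row, expected_flags):
    tbl = _table([row[0]], [row[1]], [row[2]], [row[3]])
    flags = qc.apply_fixed_cutoffs(tbl).iloc[0]
    assert {k for k, v in flags.items() if v} == expected_flags


def test_mad_cutoff_hand_calculation():
    tbl = _table([2000] * 5, [500] * 5, mito=[1, 2, 3, 4, 100])
    with pytest.warns(UserWarning, match="MAD is zero"):
        flags, thresholds = qc.apply_mad_cutoffs(tbl)  # n_umi MAD degenerates
    assert np.isclose(thresholds["pct_mito_upper"], 3 + 2.5 * 1.4826 * 1.0)
    assert np.isclose(thresholds["pct_mito_upper"], 6.7065)
    assert list(flags["fail_mito_mad"]) == [False] * 4 + [True]


def test_mad_degenerate_numi():
    tbl = _table([2000] * 9 + [100], [500] * 10, mito=list(range(10)))
    with pytest.warns(UserWarning, match="MAD is zero"):
        flags, thresholds = qc.apply_mad_cutoffs(tbl)
    assert thresholds["n_umi_lower"] == 2000
    assert flags["fail_numi_mad"].sum() == 1
    assert flags["fail_numi_mad"].iloc[-1]


def test_identical_barcodes_nothing_fails_mad():
    tbl = _table([2000] * 6, [500] * 6, mito=[5] * 6)
    with pytest.warns(UserWarning):
        flags, _ = qc.apply_mad_cutoffs(tbl)
    assert not flags.any().any()


def test_run_qc_equals_brute_force_union(small_sim):
    sample = small_sim.metadata["sample"].iloc[0]
    mask = (small_sim.metadata["sample"] == sample).to_numpy()
    tbl = small_sim.qc[mask]
    params = QCParams()
    res = qc.run_qc(tbl, params)
    fit = qc.fit_complexity_regression(tbl, params.span, params.degree)
    lc = qc.flag_low_complexity(fit, params.loess_cut, params.cooks_multiplier)
    fixed = qc.apply_fixed_cutoffs(tbl)
    mad, _ = qc.apply_mad_cutoffs(tbl, params.mad_k, params.mad_scale)
    expected_fail = (lc["low_complexity"] | fixed.any(axis=1)
                     | mad.any(axis=1))
    assert (res.decisions["pass"] == ~expected_fail).all()
    assert res.counts["pass"] + int(expected_fail.sum()) == len(tbl)


def test_per_sample_runs_do_not_leak(small_sim):
    meta = small_sim.metadata
    two = list(pd.unique(meta["sample"]))[:2]
    mask = meta["sample"].isin(two).to_numpy()
    tbl = small_sim.qc[mask]
    combined = qc.run_qc_per_sample(tbl, meta.loc[mask, "sample"])
    for s in two:
        sub = (meta.loc[mask, "sample"] == s).to_numpy()
        solo = qc.run_qc(tbl[sub])
        pd.testing.assert_frame_equal(
            combined.decisions.loc[tbl.index[sub]], solo.decisions)


def test_flagging_monotone_in_n_gene():
    """Decreasing a barcode's gene count (holding UMIs fixed) never rescues
    it from the low-complexity flag."""
    from oscellkit.config import SimConfig
    from oscellkit import synthetic

    sim = synthetic.simulate_counts(
        SimConfig(seed=23, cells_per_sample=1500, groups=[("S", 1)]))
    tbl = sim.qc.copy()
    fit = qc.fit_complexity_regression(tbl)
    flagged = qc.flag_low_complexity(fit)["low_complexity"]
    target = flagged.idxmax() if flagged.any() else None
    assert target is not None
    tbl.loc[target, "n_gene"] = max(1, tbl.loc[target, "n_gene"] // 2)
    refit = qc.fit_complexity_regression(tbl)
    assert qc.flag_low_complexity(refit)["low_complexity"].loc[target]
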