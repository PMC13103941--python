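"""CNV burden, PCA, centroid-distance test and the DiffAmps procedures,
including the exact-Wilcoxon significance floor of small replicate designs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from oscellkit import cnv
from oscellkit.config import SimConfig
from oscellkit import synthetic


def _states_df(values, cells=None, genes=None):
    values = np.asarray(values, float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=cells, columns=genes)


def test_burden_single_row_printed_rules():
    df = _states_df([[0, 0.5, 1, 1.5, 2, 3]])
    row = cnv.cnv_burden(df).iloc[0]
    assert row["n_cnv_genes"] == 5
    assert row["n_extreme"] == 3  # the 0, the 2 and the 3
    assert row["n_extreme_amp"] == 2 and row["n_extreme_del"] == 1


def test_burden_neutral_cell_all_zero():
    row = cnv.cnv_burden(_states_df([[1.0] * 8])).iloc[0]
    assert (row == 0).all()


def test_burden_matches_nested_loop_oracle(rng):
    values = rng.choice(cnv.ALPHABET, (100, 50))
    table = cnv.cnv_burden(_states_df(values))
    for i in range(100):
        n_cnv = sum(1 for v in values[i] if v != 1.0)
        n_amp = sum(1 for v in values[i] if v >= 2.0)
        n_del = sum(1 for v in values[i] if v == 0.0)
        assert table.iloc[i]["n_cnv_genes"] == n_cnv
        assert table.iloc[i]["n_extreme"] == n_amp + n_del
    assert (table["n_extreme"] <= table["n_cnv_genes"]).all()


def test_burden_rejects_bad_alphabet():
    with pytest.raises(ValueError, match="alphabet"):
        cnv.cnv_burden(_states_df([[1.0, 2.5]]))


def test_pca_separates_planted_populations(rng):
    values = np.ones((60, 100))
    noise = rng.choice([0.5, 1.0, 1.5], (60, 100), p=[0.05, 0.9, 0.05])
    values = noise
    values[:30, :50] = rng.choice([2.0, 3.0], (30, 50), p=[0.8, 0.2])
    emb = cnv.cnv_pca(_states_df(values), n_components=3)
    labels = [0] * 30 + [1] * 30
    score = silhouette_score(emb.coords[["PC1"]], labels)
    assert score > 0.5


def test_pca_constant_matrix_rejected():
    with pytest.raises(ValueError):
        cnv.cnv_pca(_states_df(np.ones((10, 5))))


def test_pca_variance_identity(rng):
    values = rng.choice(cnv.ALPHABET, (15, 6))
    df = _states_df(values)
    emb = cnv.cnv_pca(df, n_features=6, n_components=6)
    selected = df[emb.features].to_numpy()
    total_var = selected.var(axis=0, ddof=1).sum()
    assert np.isclose(emb.variance_explained.sum(), total_var, rtol=1e-9)
    # components orthogonal, variance non-increasing
    gram = emb.coords.to_numpy().T @ emb.coords.to_numpy()
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
    assert (np.diff(emb.variance_explained) <= 1e-12).all()


def _embedding(coords, cells):
    return pd.DataFrame(coords, index=cells,
                        columns=[f"PC{i+1}" for i in range(coords.shape[1])])


def test_centroid_identical_replicates_zero_distance(rng):
    coords = np.tile(rng.normal(size=(1, 3)), (30, 1))
    cells = [f"c{i}" for i in range(30)]
    samples = pd.Series(np.repeat(["s1", "s2", "s3"], 10), index=cells)
    groups = pd.Series("A", index=cells)
    res = cnv.centroid_distance_test(_embedding(coords, cells), samples, groups)
    np.testing.assert_allclose(res.distances["distance"], 0, atol=1e-12)


def test_centroid_two_replicates_symmetric(rng):
    coords = np.vstack([rng.normal(size=3)[None].repeat(5, 0),
                        rng.normal(size=3)[None].repeat(5, 0)])
    cells = [f"c{i}" for i in range(10)]
    samples = pd.Series(np.repeat(["s1", "s2"], 5), index=cells)
    groups = pd.Series("A", index=cells)
    res = cnv.centroid_distance_test(_embedding(coords, cells), samples, groups)
    d = res.distances["distance"].to_numpy()
    assert np.isclose(d[0], d[1])


def test_centroid_excludes_single_replicate_group(rng):
    coords = rng.normal(size=(30, 2))
    cells = [f"c{i}" for i in range(30)]
    samples = pd.Series(np.repeat(["s1", "s2", "s3"], 10), index=cells)
    groups = pd.Series(np.repeat(["A", "A", "B"], 10), index=cells)
    with pytest.warns(UserWarning, match="excluded"):
        res = cnv.centroid_distance_test(_embedding(coords, cells),
                                         samples, groups)
    assert res.tests.empty


def test_exact_wilcoxon_minimum_p_small_designs():
    p33 = cnv.exact_wilcoxon_rank_sum([[4, 5, 6]], [[1, 2, 3]])[0]
    assert np.isclose(p33, 2 / 20)
    p43 = cnv.exact_wilcoxon_rank_sum([[4, 5, 6, 7]], [[1, 2, 3]])[0]
    assert np.isclose(p43, 2 / 35)
    tied = cnv.exact_wilcoxon_rank_sum([[1, 1, 1]], [[1, 1, 1]])[0]
    assert tied == 1.0


def test_exact_wilcoxon_matches_scipy_without_ties(rng):
    from scipy.stats import mannwhitneyu
    for _ in range(20):
        a = rng.normal(size=(1, 5))
        b = rng.normal(size=(1, 6))
        ours = cnv.exact_wilcoxon_rank_sum(a, b)[0]
        ref = mannwhitneyu(a[0], b[0], alternative="two-sided",
                           method="exact").pvalue
        assert np.isclose(ours, ref, atol=1e-12)


def test_diffamps_mean_identical_samples_p1(small_cnv):
    states, meta = small_cnv.states, small_cnv.metadata
    res, mean_states = cnv.diffamps_mean(
        states, meta["sample"], meta["group"], "TKO", "DKO")
    constant = mean_states.index[mean_states.nunique(axis=1) == 1]
    assert (res.set_index("gene").loc[constant, "p"] == 1.0).all()
    # per-sample summaries stay in the state range
    assert mean_states.to_numpy().min() >= 0.0
    assert mean_states.to_numpy().max() <= 3.0


def test_diffamps_count_proportions_match_oracle(rng):
    values = rng.choice(cnv.ALPHABET, (60, 10))
    cells = [f"c{i}" for i in range(60)]
    df = _states_df(values, cells=cells)
    samples = pd.Series(np.repeat(["s1", "s2", "s3", "s4"], 15), index=cells)
    props = cnv.extreme_proportions(df, samples, mode="amp")
    for s, cell_block in [("s1", range(0, 15)), ("s3", range(30, 45))]:
        for j in range(10):
            expected = np.mean([values[i, j] >= 2.0 for i in cell_block])
            assert np.isclose(props.loc[f"g{j}", s], expected)
    props_del = cnv.extreme_proportions(df, samples, mode="del")
    assert np.isclose(props_del.loc["g0", "s1"],
                      np.mean(values[:15, 0] == 0.0))


def test_diffamps_count_all_quiet_gene_p1():
    values = np.ones((40, 3))
    cells = [f"c{i}" for i in range(40)]
    df = _states_df(values, cells=cells)
    samples = pd.Series(np.repeat(["a1", "a2", "b1", "b2"], 10), index=cells)
    groups = pd.Series(np.repeat(["A", "A", "B", "B"], 10), index=cells)
    res, _ = cnv.diffamps_count(df, samples, groups, "A", "B")
    assert (res["p"] == 1.0).all()


def test_diffamps_rejects_underreplicated_design():
    values = np.ones((20, 3))
    cells = [f"c{i}" for i in range(20)]
    df = _states_df(values, cells=cells)
    samples = pd.Series(np.repeat(["a1", "b1"], 10), index=cells)
    groups = pd.Series(np.repeat(["A", "B"], 10), index=cells)
    with pytest.raises(ValueError):
        cnv.diffamps_count(df, samples, groups, "A", "B")
    with pytest.raises(ValueError):
        cnv.diffamps_mean(df, samples, groups, "A", "B")


def test_select_candidates_set_semantics():
    diff = pd.DataFrame({"gene": ["g1", "g2", "g3", "g4"],
                         "p": [0.01, 0.05, 0.5, 0.02]})
    de = pd.DataFrame({"gene": ["g1", "g2", "g3"],
                       "fdr": [0.01, 0.2, 0.001],
                       "direction": [1, 1, -1]})
    assert cnv.select_candidates(diff, de) == ["g1"]
    assert cnv.select_candidates(diff, de.iloc[0:0]) == []
    # brute-force intersection on a random fixture
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(50)]
    diff = pd.DataFrame({"gene": genes, "p": rng.random(50)})
    de = pd.DataFrame({"gene": genes, "fdr": rng.random(50),
                       "direction": rng.choice([-1, 1], 50)})
    expected = sorted(
        set(diff[diff.p < 0.1].gene)
        & set(de[(de.fdr < 0.05) & (de.direction > 0)].gene))
    assert cnv.select_candidates(diff, de) == expected


def test_diffamps_recovers_planted_amplifications(small_cnv):
    states, meta = small_cnv.states, small_cnv.metadata
    res, _ = cnv.diffamps_count(states, meta["sample"], meta["group"],
                                "TKO", "DKO", mode="amp")
    planted = next(iter(small_cnv.truth.amplified_gene_ids.values()))
    hit = res.set_index("gene").loc[sorted(planted), "p"] < 0.1
    assert hit.mean() >= 0.9
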