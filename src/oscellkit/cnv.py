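"""Analyses on 6-state HMM copy-number matrices.

The input is a cells x genes matrix of inferred copy-number states in
{0, 0.5, 1, 1.5, 2, 3} (1 = copy-neutral, 0 = deep two-copy deletion,
>= 2 = high-level amplification), as produced by a 6-state HMM CNV caller,
with per-cell sample/group annotations.  The module provides:

* per-cell CNV burden counts,
* PCA of CNV profiles on the most variable genes,
* a replicate-to-group centroid-distance heterogeneity test,
* two replicate-aware differential-amplification procedures —
  DiffAmps_mean (per-sample mean states, exact Wilcoxon rank-sum) and
  DiffAmps_count (per-sample extreme-state proportions, asin-sqrt transform,
  pooled two-sample t-test),
* candidate selection intersecting DiffAmps hits with up-regulated DE genes.

With 3-4 replicates per group the exact Wilcoxon p floor matters: the
smallest attainable two-sided p is 2/C(6,3) = 0.1 for a 3-vs-3 design and
2/C(7,3) = 2/35 for 4-vs-3, which bounds what any gene can achieve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .pseudobulk import asin_sqrt, _t_rows

ALPHABET = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0])


def _validate_states(values: np.ndarray) -> None:
    uniq = np.unique(values)
    if not np.isin(uniq, ALPHABET).all():
        bad = sorted(set(uniq) - set(ALPHABET))
        raise ValueError(f"states outside the 6-level alphabet: {bad}")


def cnv_burden(states: pd.DataFrame) -> pd.DataFrame:
    """Per-cell burden: genes with state != 1, and extreme counts
    (state 0 deletions, state >= 2 amplifications)."""
    values = states.to_numpy(float)
    _validate_states(values)
    n_cnv = (values != 1.0).sum(axis=1)
    n_amp = (values >= 2.0).sum(axis=1)
    n_del = (values == 0.0).sum(axis=1)
    return pd.DataFrame(
        {
            "n_cnv_genes": n_cnv,
            "n_extreme": n_amp + n_del,
            "n_extreme_amp": n_amp,
            "n_extreme_del": n_del,
        },
        index=states.index,
    )


@dataclass
class CNVEmbedding:
    coords: pd.DataFrame  # cells x components
    variance_explained: np.ndarray
    features: list[str]


def cnv_pca(
    states: pd.DataFrame, n_features: int = 1000, n_components: int = 10
) -> CNVEmbedding:
    """PCA of CNV profiles on the top-variance genes.

    The ``n_features`` genes of highest (plain) variance across cells are
    selected (all non-constant genes if fewer), centered per gene, and
    projected onto the leading principal components via SVD.
    """
    values = states.to_numpy(float)
    _validate_states(values)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    var = values.var(axis=0)
    nonconstant = np.where(var > 0)[0]
    if nonconstant.size < 2:
        raise ValueError("need at least 2 non-constant genes")
    top = nonconstant[np.argsort(var[nonconstant], kind="mergesort")[::-1]]
    top = np.sort(top[:n_features])
    x = values[:, top] - values[:, top].mean(axis=0)
    k = max(1, min(n_components, x.shape[0] - 1, x.shape[1]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / (x.shape[0] - 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    return CNVEmbedding(
        pd.DataFrame(coords, index=states.index, columns=cols),
        explained,
        [states.columns[i] for i in top],
    )


@dataclass
class CentroidDistanceResult:
    distances: pd.DataFrame  # sample, group, distance
    tests: pd.DataFrame  # group_a, group_b, stat, p


def centroid_distance_test(
    emb: CNVEmbedding | pd.DataFrame,
    samples: pd.Series,
    groups: pd.Series,
    group_pairs: list[tuple[str, str]] | None = None,
) -> CentroidDistanceResult:
    """Replicate-to-group centroid distances, compared between groups.

    Replicate centroid = mean PC coordinates of that replicate's cells;
    group centroid = mean of its replicate centroids (replicates weighted
    equally, not cells); distance = Euclidean norm.  Each group pair is
    compared with a two-sample Welch t-test on the distance sets.
    """
    coords = emb.coords if isinstance(emb, CNVEmbedding) else emb
    samples = samples.loc[coords.index]
    groups = groups.loc[coords.index]
    rep_centroids = coords.groupby(samples).mean()
    rep_group = groups.groupby(samples).first().loc[rep_centroids.index]
    group_centroids = rep_centroids.groupby(rep_group).mean()
    diffs = rep_centroids - group_centroids.loc[rep_group].to_numpy()
    dist = np.sqrt((diffs**2).sum(axis=1))
    distances = pd.DataFrame(
        {"sample": rep_centroids.index, "group": rep_group.to_numpy(),
         "distance": dist.to_numpy()}).reset_index(drop=True)

    sizes = distances.groupby("group").size()
    testable = [g for g in sizes.index if sizes[g] >= 2]
    for g in sizes.index:
        if g not in testable:
            warnings.warn(f"group {g!r} has < 2 replicates; excluded from testing")
    if group_pairs is None:
        order = [g for g in pd.unique(rep_group) if g in testable]
        group_pairs = list(itertools.combinations(order, 2))
    rows = []
    for ga, gb in group_pairs:
        if ga not in testable or gb not in testable:
            continue
        da = distances.loc[distances["group"] == ga, "distance"].to_numpy()
        db = distances.loc[distances["group"] == gb, "distance"].to_numpy()
        stat, p = _t_rows(da[None, :], db[None, :])
        rows.append({"group_a": ga, "group_b": gb,
                     "stat": float(stat[0]), "p": float(p[0])})
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "stat", "p"])
    return CentroidDistanceResult(distances, tests)


_ENUM_LIMIT = 200_000


def exact_wilcoxon_rank_sum(
    a: np.ndarray, b: np.ndarray, exact: bool | None = None
) -> np.ndarray:
    """Row-wise two-sided Wilcoxon rank-sum p-values.

    For small designs (min group size <= 10 and C(n, n_a) combinations below
    an enumeration cap) the exact conditional distribution of the midrank sum
    is enumerated and p = min(1, 2 * min(tail probabilities)); ties are
    handled by midranks.  Larger designs fall back to the normal
    approximation with tie correction.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    n_a, n_b = a.shape[1], b.shape[1]
    n = n_a + n_b
    if exact is None:
        exact = min(n_a, n_b) <= 10 and comb(n, n_a) <= _ENUM_LIMIT
    if not exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", axis=1)
        return np.asarray(res.pvalue, float)
    combined = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(combined, axis=1)  # midranks
    combos = np.array(list(itertools.combinations(range(n), n_a)))
    w_all = ranks[:, combos].sum(axis=2)  # genes x combinations
    w_obs = ranks[:, :n_a].sum(axis=1)
    tol = 1e-9
    less = (w_all <= w_obs[:, None] + tol).mean(axis=1)
    greater = (w_all >= w_obs[:, None] - tol).mean(axis=1)
    return np.minimum(1.0, 2.0 * np.minimum(less, greater))


def _group_columns(
    samples: pd.Series, groups: pd.Series, group: str
) -> list[str]:
    sample_groups = groups.groupby(samples).first()
    return list(sample_groups.index[sample_groups == group])


def diffamps_mean(
    states: pd.DataFrame,
    samples: pd.Series,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    exact: bool | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DiffAmps_mean: per-sample mean CNV state per gene, compared between
    groups with the (exact) Wilcoxon rank-sum test.

    Returns (per-gene results, the gene x sample mean-state matrix).
    """
    values = states.to_numpy(float)
    _validate_states(values)
    samples = samples.loc[states.index]
    mean_states = states.groupby(samples.to_numpy()).mean().T  # genes x samples
    a_cols = _group_columns(samples, groups.loc[states.index], group_a)
    b_cols = _group_columns(samples, groups.loc[states.index], group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    p = exact_wilcoxon_rank_sum(
        mean_states[a_cols].to_numpy(), mean_states[b_cols].to_numpy(),
        exact=exact)
    res = pd.DataFrame({
        "gene": mean_states.index,
        "method": "mean",
        "group_a": group_a,
        "group_b": group_b,
        "mean_a": mean_states[a_cols].mean(axis=1).to_numpy(),
        "mean_b": mean_states[b_cols].mean(axis=1).to_numpy(),
        "p": p,
    })
    return res, mean_states


def extreme_proportions(
    states: pd.DataFrame, samples: pd.Series, mode: str = "amp"
) -> pd.DataFrame:
    """Per-gene, per-sample proportion of cells with an extreme state
    (state >= 2 for ``amp``, state == 0 for ``del``)."""
    values = states.to_numpy(float)
    _validate_states(values)
    if mode == "amp":
        extreme = values >= 2.0
    elif mode == "del":
        extreme = values == 0.0
    else:
        raise ValueError("mode must be 'amp' or 'del'")
    flags = pd.DataFrame(extreme, index=states.index, columns=states.columns)
    return flags.groupby(samples.loc[states.index].to_numpy()).mean().T


def diffamps_count(
    states: pd.DataFrame,
    samples: pd.Series,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    mode: str = "amp",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DiffAmps_count: per-sample extreme-state proportions per gene,
    asin-sqrt transformed and compared between groups with a pooled
    two-sample t-test (the compositional-analysis analogy: a cell either
    carries the extreme CNV or it does not; the transform stabilizes the
    variance, so the pooled test holds its level at 3-4 replicates).

    Returns (per-gene results, the gene x sample proportion matrix).
    """
    props = extreme_proportions(states, samples, mode=mode)
    a_cols = _group_columns(samples.loc[states.index],
                            groups.loc[states.index], group_a)
    b_cols = _group_columns(samples.loc[states.index],
                            groups.loc[states.index], group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    trans_a = asin_sqrt(props[a_cols].to_numpy())
    trans_b = asin_sqrt(props[b_cols].to_numpy())
    stat, p = _t_rows(trans_a, trans_b, equal_var=True)
    res = pd.DataFrame({
        "gene": props.index,
        "method": f"count_{mode}",
        "group_a": group_a,
        "group_b": group_b,
        "prop_a": props[a_cols].mean(axis=1).to_numpy(),
        "prop_b": props[b_cols].mean(axis=1).to_numpy(),
        "stat": stat,
        "p": p,
    })
    return res, props


def select_candidates(
    diffamps: pd.DataFrame,
    de: pd.DataFrame,
    alpha: float = 0.1,
    de_fdr: float = 0.05,
) -> list[str]:
    """Genes with DiffAmps p < alpha that the matching DE contrast also calls
    significantly over-expressed (fdr < 0.05, positive direction)."""
    if de.empty:
        return []
    hits = set(diffamps.loc[diffamps["p"] < alpha, "gene"])
    up = set(de.loc[(de["fdr"] < de_fdr) & (de["direction"] > 0), "gene"])
    return sorted(hits & up)
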