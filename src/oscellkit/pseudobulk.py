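"""Replicate-aware pseudobulk and compositional statistics.

Single-cell counts are summed per sample (pseudobulk) so every statistical
comparison has biological replicates as its unit, not cells.  Expression is
compared with a Welch t-test on log2(CPM+1); cell-type composition with the
propeller-style test (per-sample proportions, arcsine-square-root transform,
two-sample t-test per unit, BH across units); small categorical designs with
the Fisher exact test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame  # genes x samples, integer UMI sums
    sample_groups: pd.Series  # sample -> group
    celltype: str


def aggregate_pseudobulk(
    counts,
    barcodes: list[str],
    genes: list[str],
    metadata: pd.DataFrame,
    celltype: str,
) -> PseudobulkMatrix:
    """Sum raw UMIs of one cell type per sample for each gene (exact integer
    sums; samples with zero cells of the type are omitted with a warning)."""
    if celltype not in set(metadata["celltype"]):
        raise ValueError(f"unknown cell type {celltype!r}")
    counts = sp.csr_matrix(counts)
    meta = metadata.loc[list(barcodes)]
    keep = (meta["celltype"] == celltype).to_numpy()
    samples_all = pd.unique(meta["sample"])
    cols, kept_samples, groups = [], [], []
    for sample in samples_all:
        mask = keep & (meta["sample"] == sample).to_numpy()
        if not mask.any():
            warnings.warn(f"sample {sample!r} has no {celltype!r} cells; omitted")
            continue
        cols.append(np.asarray(counts[mask].sum(axis=0)).ravel())
        kept_samples.append(sample)
        groups.append(meta.loc[mask, "group"].iloc[0])
    pb = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=list(genes),
        columns=kept_samples)
    return PseudobulkMatrix(pb, pd.Series(groups, index=kept_samples), celltype)


def _t_rows(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test (Welch by default, pooled on request) with
    the degenerate-variance convention: both groups constant -> p = 1 when
    means are equal, p = 0 otherwise."""
    with warnings.catch_warnings():
        # constant rows are handled by the convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    stat = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    eq = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(var0 & eq, 1.0, p)
    p = np.where(var0 & ~eq, 0.0, p)
    stat = np.where(var0, 0.0, stat)
    return stat, p


def pseudobulk_de(
    pb: PseudobulkMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group pseudobulk expression test.

    Per gene: log2 fold change of mean CPM (pseudocount 1) and a Welch t-test
    on log2(CPM+1) across replicate samples, BH-adjusted.  Externally produced
    DE tables with the same columns (gene, log2fc, p, fdr, direction) are
    accepted anywhere this table is consumed.
    """
    groups = pb.sample_groups
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    counts = pb.counts
    cpm = counts / counts.sum(axis=0) * 1e6
    log_cpm = np.log2(cpm + 1.0)
    lfc = np.log2((cpm[a_cols].mean(axis=1) + pseudocount)
                  / (cpm[b_cols].mean(axis=1) + pseudocount))
    stat, p = _t_rows(log_cpm[a_cols].to_numpy(), log_cpm[b_cols].to_numpy())
    out = pd.DataFrame({
        "gene": counts.index,
        "log2fc": lfc.to_numpy(),
        "stat": stat,
        "p": p,
        "fdr": bh_adjust(p),
    })
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out


def asin_sqrt(p) -> np.ndarray:
    """Variance-stabilizing arcsine-square-root transform of proportions."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must be in [0, 1]")
    return np.arcsin(np.sqrt(p))


def sample_proportions(
    metadata: pd.DataFrame, unit_col: str = "celltype"
) -> pd.DataFrame:
    """Per-sample proportions of each unit (rows = samples, columns = units;
    units absent from a sample get proportion 0)."""
    tab = pd.crosstab(metadata["sample"], metadata[unit_col])
    return tab.div(tab.sum(axis=1), axis=0)


def proportion_test(
    metadata: pd.DataFrame,
    unit_col: str = "celltype",
    group_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Propeller-style compositional test.

    Per-sample unit proportions are asin(sqrt(p))-transformed; each group
    pair is compared per unit with a pooled-variance two-sample t-test (the
    transform stabilizes the sampling variance, making the pooled test
    exact-level under the null at 3-4 replicates), with BH adjustment across
    units within the pair.  A unit absent from every sample of one group is
    still tested (proportion 0); both-groups-constant with equal means gives
    p = 1.  Returns (results, per-sample proportion table).
    """
    props = sample_proportions(metadata, unit_col)
    sample_groups = metadata.groupby("sample")["group"].first()
    if group_pairs is None:
        levels = list(pd.unique(metadata["group"]))
        group_pairs = list(itertools.combinations(levels, 2))
    trans = pd.DataFrame(asin_sqrt(props.to_numpy()),
                         index=props.index, columns=props.columns)
    rows = []
    for ga, gb in group_pairs:
        a_samples = sample_groups.index[sample_groups == ga]
        b_samples = sample_groups.index[sample_groups == gb]
        if len(a_samples) < 2 or len(b_samples) < 2:
            raise ValueError(f"groups {ga!r}/{gb!r} need >= 2 samples each")
        a = trans.loc[a_samples].to_numpy().T  # units x samples
        b = trans.loc[b_samples].to_numpy().T
        stat, p = _t_rows(a, b, equal_var=True)
        tbl = pd.DataFrame({
            "unit": props.columns,
            "group_a": ga,
            "group_b": gb,
            "prop_a": props.loc[a_samples].mean(axis=0).to_numpy(),
            "prop_b": props.loc[b_samples].mean(axis=0).to_numpy(),
            "trans_mean_a": a.mean(axis=1),
            "trans_mean_b": b.mean(axis=1),
            "stat": stat,
            "p": p,
            "fdr": bh_adjust(p),
        })
        rows.append(tbl)
    return pd.concat(rows, ignore_index=True), props


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    p sums the hypergeometric probabilities (margins fixed) of every table at
    most as probable as the observed one; the reported odds ratio is the
    cross-product ratio ad/(bc).  A zero margin yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer entries")
    (a, b), (c, d) = t
    n = int(t.sum())
    if n == 0:
        raise ValueError("table has no observations")
    r1, c1 = a + b, a + c
    with np.errstate(divide="ignore", invalid="ignore"):
        if b * c == 0:
            odds = np.inf if a * d > 0 else np.nan
        else:
            odds = (a * d) / (b * c)
    if min(r1, c1, n - r1, n - c1) == 0:
        warnings.warn("degenerate margin; p = 1 by convention")
        return float(odds), 1.0
    k_min = max(0, r1 + c1 - n)
    support = np.arange(k_min, min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return float(odds), min(p, 1.0)
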