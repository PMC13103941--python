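"""Marker statistics and signature (module) scoring.

``find_markers`` ranks cluster markers by a specificity-weighted fold change
(marker score = (pct.1 - pct.2) * avg_log2FC); ``module_score`` implements
the expression-bin-matched control-gene scoring scheme used by Seurat's
AddModuleScore; ``cell_cycle_phase`` and ``classify_responders`` are the
score-based cell classifiers built on top of it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .pseudobulk import bh_adjust
from .synthetic import GeneSet


def log_normalize(counts, barcodes, genes, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    Returns a dense genes x cells DataFrame (the ExpressionMatrix layout).
    """
    import scipy.sparse as sp

    counts = sp.csr_matrix(counts)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals = np.maximum(totals, 1.0)
    norm = counts.multiply(scale / totals[:, None]).tocsr()
    expr = np.log1p(norm.toarray()).T
    return pd.DataFrame(expr, index=list(genes), columns=list(barcodes))


def marker_score(pct1: float, pct2: float, avg_log2fc: float) -> float:
    """Specificity-weighted marker priority: (pct.1 - pct.2) * avg_log2FC."""
    if not (0.0 <= pct1 <= 1.0 and 0.0 <= pct2 <= 1.0):
        raise ValueError("expressing-cell fractions must be in [0, 1]")
    return (pct1 - pct2) * avg_log2fc


def find_markers(
    expr: pd.DataFrame,
    clusters: pd.Series,
    pseudocount: float = 1.0,
    min_cells: int = 3,
    only_pos: bool = True,
) -> pd.DataFrame:
    """Per-cluster one-vs-rest marker table.

    For each gene and cluster: pct.1/pct.2 are expressing-cell fractions
    (normalized expression > 0) inside/outside the cluster; avg_log2FC is
    log2((m1 + pc) / (m2 + pc)) on de-logged (expm1) means; p-values come
    from the Wilcoxon rank-sum normal approximation with tie correction, BH
    adjusted per cluster; only positive-fold-change rows are kept when
    ``only_pos``.
    """
    clusters = clusters.loc[expr.columns]
    levels = [c for c in pd.unique(clusters)]
    if len(levels) < 2:
        raise ValueError("need at least 2 clusters")
    values = expr.to_numpy(float)
    delogged = np.expm1(values)
    expressing = values > 0
    rows = []
    for level in levels:
        in_mask = (clusters == level).to_numpy()
        if in_mask.sum() < min_cells:
            warnings.warn(f"cluster {level!r} has fewer than {min_cells} cells; skipped")
            continue
        out_mask = ~in_mask
        pct1 = expressing[:, in_mask].mean(axis=1)
        pct2 = expressing[:, out_mask].mean(axis=1)
        m1 = delogged[:, in_mask].mean(axis=1)
        m2 = delogged[:, out_mask].mean(axis=1)
        lfc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
        res = stats.mannwhitneyu(
            values[:, in_mask], values[:, out_mask],
            alternative="two-sided", method="asymptotic", axis=1)
        padj = bh_adjust(res.pvalue)
        tbl = pd.DataFrame({
            "gene": expr.index,
            "cluster": level,
            "pct1": pct1,
            "pct2": pct2,
            "avg_log2fc": lfc,
            "p": res.pvalue,
            "p_adj": padj,
        })
        rows.append(tbl)
    out = pd.concat(rows, ignore_index=True)
    out["marker_score"] = (out["pct1"] - out["pct2"]) * out["avg_log2fc"]
    if only_pos:
        out = out[out["avg_log2fc"] > 0].reset_index(drop=True)
    return out


def module_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Expression-bin-matched signature score per cell.

    Genes are ranked by mean expression across cells and split into
    ``n_bins`` near-equal bins (stable order breaks ties).  For each member
    gene, ``n_ctrl`` control genes are drawn uniformly from its bin (without
    replacement when the bin is large enough, with replacement otherwise).
    score(cell) = mean member expression - mean control expression.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    members = [g for g in gene_set.genes if g in expr.index]
    dropped = set(gene_set.genes) - set(members)
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) of {gene_set.name!r} absent from the matrix")
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} empty after harmonization")
    if rng is None:
        rng = np.random.default_rng([101, int(seed)])

    avg = expr.mean(axis=1).to_numpy()
    order = np.argsort(avg, kind="mergesort")
    bin_of = np.empty(len(expr), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    pos = {g: i for i, g in enumerate(expr.index)}
    values = expr.to_numpy(float)

    ctrl_rows: list[np.ndarray] = []
    for g in members:
        b = bin_of[pos[g]]
        bin_genes = np.where(bin_of == b)[0]
        replace = bin_genes.size < n_ctrl
        ctrl_rows.append(rng.choice(bin_genes, size=n_ctrl, replace=replace))
    member_idx = np.array([pos[g] for g in members])
    ctrl_idx = np.concatenate(ctrl_rows)
    # anchor on one member row so a constant matrix scores exactly zero
    ref = values[member_idx[0]]
    score = ((values[member_idx] - ref).mean(axis=0)
             - (values[ctrl_idx] - ref).mean(axis=0))
    out = pd.Series(score, index=expr.columns, name=gene_set.name)
    out.attrs["provenance"] = {
        "gene_set": gene_set.name, "n_members": len(members),
        "n_bins": n_bins, "n_ctrl": n_ctrl, "seed": int(seed)}
    return out


def cell_cycle_phase(s_score: pd.Series, g2m_score: pd.Series) -> pd.Series:
    """Assign G1/S/G2M from the two phase scores.

    S when the S score leads and is positive; G2M when the G2M score is at
    least as large and positive; otherwise G1 (both scores non-positive).
    """
    if not s_score.index.equals(g2m_score.index):
        raise ValueError("S and G2M scores must cover the same cells")
    s = s_score.to_numpy(float)
    g2m = g2m_score.to_numpy(float)
    phase = np.where((s > g2m) & (s > 0), "S",
                     np.where((g2m >= s) & (g2m > 0), "G2M", "G1"))
    return pd.Series(phase, index=s_score.index, name="phase")


def classify_responders(scores: pd.Series) -> pd.Series:
    """High iff score strictly above the pooled median (computed once over
    all malignant cells of all samples, never per sample)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 cells")
    median = float(scores.median())
    return (scores > median).rename("responder_high")
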