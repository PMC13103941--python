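"""Pathologic-subtype calling and cross-species marker scoring.

A tumor's pathologic subtype (osteoblastic / chondroblastic / fibroblastic)
is called as the most frequent transferred reference-atlas label among its
malignant cells.  Cross-species fidelity is assessed by translating murine
cell-type marker sets through one-to-one orthologs, module-scoring them on
the target (human) cells, averaging per target cell type, and hierarchically
clustering the correlation structure of the resulting score matrix.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .signatures import module_score
from .synthetic import GeneSet

_SUFFIX = re.compile(r"\s+\d+$")


def simplify_atlas_labels(labels) -> pd.Series:
    """Merge numbered atlas clusters into their cell type by stripping a
    trailing space-plus-integer suffix ("Fibroblastic 3" -> "Fibroblastic")."""
    s = pd.Series(labels)
    return s.map(lambda v: _SUFFIX.sub("", str(v)))


def call_subtype(
    transfer: pd.DataFrame,
    malignant_cells,
    samples: pd.Series,
    label_col: str = "predicted",
) -> pd.DataFrame:
    """Per-sample subtype call: argmax of transferred-label proportions over
    malignant cells; exact ties break lexicographically with a tie flag."""
    malignant_cells = [c for c in malignant_cells]
    labels = transfer.loc[malignant_cells, label_col]
    cell_samples = samples.loc[malignant_cells]
    rows = []
    for sample in pd.unique(samples):
        mask = cell_samples == sample
        if not mask.any():
            warnings.warn(f"sample {sample!r} has no malignant cells; skipped")
            continue
        counts = labels[mask.to_numpy()].value_counts()
        props = (counts / counts.sum()).sort_index()
        top = props.max()
        winners = sorted(props.index[props == top])
        row = {"sample": sample, "called_subtype": winners[0],
               "proportion": float(top), "tie": len(winners) > 1}
        for label, p in props.items():
            row[f"prop_{label}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def filter_orthologs(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only one-to-one pairs: a source kept iff it maps to a single
    target that no other source maps to (bijective on retained pairs)."""
    t = table[["source", "target"]].drop_duplicates()
    src_counts = t["source"].value_counts()
    tgt_counts = t["target"].value_counts()
    keep = t["source"].map(src_counts).eq(1) & t["target"].map(tgt_counts).eq(1)
    return t[keep].reset_index(drop=True)


def translate_gene_set(gene_set: GeneSet, orthologs: pd.DataFrame) -> GeneSet | None:
    """Map a source gene set through (already filtered) one-to-one orthologs;
    None when no member survives."""
    mapping = dict(zip(orthologs["source"], orthologs["target"]))
    translated = tuple(mapping[g] for g in gene_set.genes if g in mapping)
    if not translated:
        return None
    return GeneSet(gene_set.name, translated, gene_set.description)


def crossspecies_score_matrix(
    marker_sets: dict[str, GeneSet],
    target_expr: pd.DataFrame,
    target_labels: pd.Series,
    orthologs: pd.DataFrame,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    cell_filter=None,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Score source marker sets on target cells and summarize per cell type.

    Each source set is translated through one-to-one orthologs, scored per
    target cell with the module score, and averaged within each target cell
    type, giving a source-set x target-type matrix.  Pearson correlation
    between the source-set rows is hierarchically clustered (average linkage
    on the 1 - r distance); constant rows are excluded with a warning.

    Returns (score matrix, row correlation matrix, clustered row order).
    """
    filtered = filter_orthologs(orthologs)
    if cell_filter is not None:
        cells = [c for c in target_expr.columns if cell_filter(c)]
        target_expr = target_expr[cells]
    target_labels = target_labels.loc[target_expr.columns]
    if target_labels.nunique() < 2:
        raise ValueError("need at least 2 target cell types")

    rows = {}
    for name, gene_set in marker_sets.items():
        translated = translate_gene_set(gene_set, filtered)
        if translated is None:
            warnings.warn(f"marker set {name!r} emptied by ortholog filtering")
            continue
        present = [g for g in translated.genes if g in target_expr.index]
        if not present:
            warnings.warn(f"marker set {name!r} has no genes in the target matrix")
            continue
        scores = module_score(target_expr, GeneSet(name, tuple(present)),
                              n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        rows[name] = scores.groupby(target_labels).mean()
    if not rows:
        raise ValueError("no marker set survived ortholog filtering")
    score_matrix = pd.DataFrame(rows).T  # sets x target types

    variable = score_matrix.index[score_matrix.std(axis=1) > 0]
    dropped = set(score_matrix.index) - set(variable)
    if dropped:
        warnings.warn(
            f"constant score rows excluded from correlation: {sorted(dropped)}")
    corr = score_matrix.loc[variable].T.corr()
    if len(corr) >= 2:
        dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
        order_idx = leaves_list(linkage(dist, method=linkage_method))
        order = [corr.index[i] for i in order_idx]
    else:
        order = list(corr.index)
    return score_matrix, corr, order
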