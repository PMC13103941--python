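"""Proteomics preprocessing and differential abundance.

The chain mirrors standard label-free proteomics practice: log2 transform,
per-sample mean centering, downshifted-normal imputation of missing values
(draws from Normal(mean - shift_sd * SD, (width_frac * SD)^2) per sample,
reflecting that missingness concentrates in low-abundance proteins), an
advisory PCA outlier screen, and per-protein Welch t-tests with BH control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudobulk import _t_rows, bh_adjust


@dataclass
class ProcessedProteins:
    values: pd.DataFrame  # proteins x samples, log2, centered, complete after imputation
    mask: pd.DataFrame  # True where the raw matrix was missing


def normalize_log2(raw: pd.DataFrame) -> ProcessedProteins:
    """log2-transform intensities and center each sample at its observed mean.

    Missing entries stay missing; the returned mask marks exactly the cells
    that were missing in the input.
    """
    if (raw <= 0).any().any():
        raise ValueError("intensities must be positive where present")
    mask = raw.isna()
    log2 = np.log2(raw)
    centered = log2 - log2.mean(axis=0, skipna=True)
    return ProcessedProteins(centered, mask)


def impute_downshift(
    processed: ProcessedProteins,
    shift_sd: float = 2.0,
    width_frac: float = 0.3,
    seed: int = 0,
    per_sample: bool = True,
) -> ProcessedProteins:
    """Downshifted-normal imputation of missing values.

    Each missing cell of sample s is drawn from
    Normal(mu_s - shift_sd * sigma_s, (width_frac * sigma_s)^2), where mu_s
    and sigma_s are the sample's observed mean and SD (global mode pools all
    samples).  Observed cells are never altered; the draw is deterministic
    under a fixed seed.
    """
    values = processed.values.copy()
    mask = processed.mask
    rng = np.random.default_rng([211, int(seed)])
    if per_sample:
        for col in values.columns:
            observed = values[col][~mask[col]]
            if observed.empty:
                raise ValueError(f"sample {col!r} is entirely missing")
            mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
            if sigma <= 0:
                raise ValueError(f"sample {col!r} has zero observed spread")
            n_missing = int(mask[col].sum())
            if n_missing:
                draws = rng.normal(mu - shift_sd * sigma,
                                   width_frac * sigma, n_missing)
                values.loc[mask[col], col] = draws
    else:
        observed = values.to_numpy()[~mask.to_numpy()]
        mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
        flat = values.to_numpy()
        m = mask.to_numpy()
        flat[m] = rng.normal(mu - shift_sd * sigma, width_frac * sigma,
                             int(m.sum()))
        values = pd.DataFrame(flat, index=values.index, columns=values.columns)
    return ProcessedProteins(values, mask.copy())


def pca_outlier_screen(
    processed: ProcessedProteins, n_components: int = 2, ratio: float = 3.0
) -> pd.DataFrame:
    """Advisory PCA screen for aberrant samples.

    Samples are projected on the leading components of the processed matrix;
    a sample is flagged when its distance from the remaining samples'
    centroid exceeds ``ratio`` times those samples' own mean distance from
    that centroid.  Removal stays the caller's decision.
    """
    values = processed.values
    if values.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    if values.shape[1] < 3:
        raise ValueError("PCA screen needs at least 3 samples")
    x = values.to_numpy().T  # samples x proteins
    x = x - x.mean(axis=0)
    k = min(n_components, x.shape[0] - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    rows = []
    for i in range(coords.shape[0]):
        others = np.delete(coords, i, axis=0)
        centroid = others.mean(axis=0)
        d_i = float(np.linalg.norm(coords[i] - centroid))
        d_others = float(np.mean(np.linalg.norm(others - centroid, axis=1)))
        flagged = d_others > 0 and d_i > ratio * d_others
        rows.append({"sample": values.columns[i],
                     **{f"PC{j + 1}": coords[i, j] for j in range(k)},
                     "distance": d_i, "reference_distance": d_others,
                     "outlier": bool(flagged)})
    return pd.DataFrame(rows)


def protein_de(
    processed: ProcessedProteins,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-protein Welch t-test between two sample groups on processed
    (log2, centered, imputed) values, with BH adjustment."""
    values = processed.values
    if values.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    a_cols = [s for s in values.columns if groups.get(s) == group_a]
    b_cols = [s for s in values.columns if groups.get(s) == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    a = values[a_cols].to_numpy()
    b = values[b_cols].to_numpy()
    stat, p = _t_rows(a, b)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame({
        "protein": values.index,
        "log2fc": lfc,
        "stat": stat,
        "p": p,
        "fdr": bh_adjust(p),
    })
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out
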