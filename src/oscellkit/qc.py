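"""Per-sample barcode quality control.

Three filters, applied jointly to one sample's BarcodeQC table:

1. *Two-step regression low-complexity filter.*  Ordinary least squares and a
   LOESS curve are both fit with log(nUMI) as predictor and log(nGene) as
   response.  A barcode is a low-complexity outlier (an erythrocyte-like
   droplet dominated by a handful of hemoglobin transcripts) when its LOESS
   residual falls below ``loess_cut`` (default -4, natural-log units) AND its
   linear-model Cook's distance exceeds ``cooks_multiplier / n`` (default
   4/Ncells) — a conjunction of "far below the trend" and "influential".
2. *Fixed cutoffs*, strict: keep requires nUMI > 1000, nGene > 200,
   %mito < 25 and %hemoglobin < 25.
3. *MAD-adaptive cutoffs*: %mito above median + k*MAD, or nUMI below
   median - k*MAD (k = 2.5, MAD scaled by 1.4826 for normal consistency).

A barcode passes iff no filter flags it.  Filters see the original table (no
sequential re-fitting after removals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCParams

FLAG_COLUMNS = [
    "low_complexity",
    "fail_numi_fixed",
    "fail_gene_fixed",
    "fail_mito_fixed",
    "fail_hb_fixed",
    "fail_mito_mad",
    "fail_numi_mad",
]


@dataclass
class ComplexityFit:
    """Per-barcode diagnostics of the complexity regressions."""

    table: pd.DataFrame  # linear_residual, loess_residual, leverage, cooks_distance
    slope: float
    intercept: float
    mse: float
    span: float
    degree: int

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class QCResult:
    decisions: pd.DataFrame  # one bool column per flag + 'pass'
    thresholds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    max_exact: int = 2000,
    n_grid: int = 401,
) -> np.ndarray:
    """Classical LOESS: tricube-weighted local polynomial of the k nearest
    neighbors, k = ceil(span * n).  Fitted values are computed at every point
    for small n and on an x-quantile grid (linear interpolation) for large n.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]

    if n <= max_exact:
        targets = xs
    else:
        qs = np.linspace(0.0, 1.0, min(n_grid, n))
        targets = np.unique(np.quantile(xs, qs))

    fitted_t = np.empty(targets.size)
    for i, x0 in enumerate(targets):
        # k nearest neighbors form a contiguous window in sorted order
        lo = np.searchsorted(xs, x0)
        lo = min(max(lo - k // 2, 0), n - k)
        hi = lo + k
        while lo > 0 and x0 - xs[lo - 1] < xs[hi - 1] - x0:
            lo -= 1
            hi -= 1
        while hi < n and xs[hi] - x0 < x0 - xs[lo]:
            lo += 1
            hi += 1
        xi, yi = xs[lo:hi], ys[lo:hi]
        d = np.abs(xi - x0)
        dmax = d.max()
        if dmax == 0:
            fitted_t[i] = yi.mean()
            continue
        w = (1.0 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        V = np.vander(xi - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], yi * sw, rcond=None)
        fitted_t[i] = coef[0]

    if targets.size == n and np.array_equal(targets, xs):
        fitted_sorted = fitted_t
    else:
        fitted_sorted = np.interp(xs, targets, fitted_t)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def fit_complexity_regression(
    barcodes: pd.DataFrame, span: float = 0.75, degree: int = 2
) -> ComplexityFit:
    """OLS + LOESS of log(nGene) on log(nUMI), with OLS influence measures.

    Cook's distance uses the hat-matrix formula
    D_i = e_i^2 * h_ii / (p * MSE * (1 - h_ii)^2) with p = 2 parameters.
    """
    if len(barcodes) < 10:
        raise ValueError("complexity regression needs at least 10 barcodes")
    if (barcodes["n_umi"] < 1).any() or (barcodes["n_gene"] < 1).any():
        raise ValueError("n_umi and n_gene must be >= 1 for all fitted barcodes")
    x = np.log(barcodes["n_umi"].to_numpy(float))
    y = np.log(barcodes["n_gene"].to_numpy(float))
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0 or np.allclose(x, x[0]):
        raise ValueError("zero variance of log(n_umi); cannot fit")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    leverage = 1.0 / n + (x - x.mean()) ** 2 / sxx
    mse = float(np.sum(resid**2) / (n - 2))
    denom = 2.0 * mse * (1.0 - leverage) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        cooks = np.where(denom > 0, resid**2 * leverage / denom, np.inf)
    # an (essentially) perfect fit has no influential points: Cook's D is a
    # 0/0 ratio there, resolved to 0 rather than round-off noise
    tss = float(np.sum((y - y.mean()) ** 2))
    if mse * (n - 2) <= 1e-12 * max(tss, np.finfo(float).tiny):
        cooks = np.zeros(n)

    loess_resid = y - loess_fit(x, y, span=span, degree=degree)
    table = pd.DataFrame(
        {
            "linear_residual": resid,
            "loess_residual": loess_resid,
            "leverage": leverage,
            "cooks_distance": cooks,
        },
        index=barcodes.index,
    )
    return ComplexityFit(table, slope, intercept, mse, span, degree)


def flag_low_complexity(
    fit: ComplexityFit, loess_cut: float = -4.0, cooks_multiplier: float = 4.0
) -> pd.DataFrame:
    """Flag barcodes with LOESS residual < cut AND Cook's D > multiplier/n."""
    threshold = cooks_multiplier / fit.n
    flag = (fit.table["loess_residual"] < loess_cut) & (
        fit.table["cooks_distance"] > threshold
    )
    return pd.DataFrame({"low_complexity": flag})


def apply_fixed_cutoffs(
    barcodes: pd.DataFrame,
    min_umi: float = 1000.0,
    min_genes: float = 200.0,
    max_pct_mito: float = 25.0,
    max_pct_hemoglobin: float = 25.0,
) -> pd.DataFrame:
    """Strict fixed cutoffs: keep requires nUMI > 1000, nGene > 200,
    %mito < 25, %hemoglobin < 25; a barcode exactly at a boundary fails."""
    if barcodes.empty:
        raise ValueError("empty BarcodeQC table")
    return pd.DataFrame(
        {
            "fail_numi_fixed": ~(barcodes["n_umi"] > min_umi),
            "fail_gene_fixed": ~(barcodes["n_gene"] > min_genes),
            "fail_mito_fixed": ~(barcodes["pct_mito"] < max_pct_mito),
            "fail_hb_fixed": ~(barcodes["pct_hemoglobin"] < max_pct_hemoglobin),
        }
    )


def _mad(x: np.ndarray, scale: float) -> float:
    med = np.median(x)
    return scale * float(np.median(np.abs(x - med)))


def apply_mad_cutoffs(
    barcodes: pd.DataFrame, k: float = 2.5, mad_scale: float = 1.4826
) -> tuple[pd.DataFrame, dict]:
    """Adaptive cutoffs: %mito above median + k*MAD, nUMI below median - k*MAD.

    With MAD = 0 the threshold degenerates to the median (warned, still
    applied); values strictly beyond the median are then flagged.
    """
    if len(barcodes) < 3:
        raise ValueError("MAD cutoffs need at least 3 barcodes")
    mito = barcodes["pct_mito"].to_numpy(float)
    numi = barcodes["n_umi"].to_numpy(float)
    mito_mad = _mad(mito, mad_scale)
    numi_mad = _mad(numi, mad_scale)
    if mito_mad == 0 or numi_mad == 0:
        warnings.warn("MAD is zero; threshold degenerates to the median")
    upper_mito = float(np.median(mito) + k * mito_mad)
    lower_numi = float(np.median(numi) - k * numi_mad)
    flags = pd.DataFrame(
        {
            "fail_mito_mad": pd.Series(mito > upper_mito, index=barcodes.index),
            "fail_numi_mad": pd.Series(numi < lower_numi, index=barcodes.index),
        }
    )
    thresholds = {"pct_mito_upper": upper_mito, "n_umi_lower": lower_numi}
    return flags, thresholds


def run_qc(barcodes: pd.DataFrame, params: QCParams | None = None) -> QCResult:
    """All three filters on one sample's table; pass iff no flag is set."""
    params = params or QCParams()
    fit = fit_complexity_regression(barcodes, span=params.span,
                                    degree=params.degree)
    lc = flag_low_complexity(fit, params.loess_cut, params.cooks_multiplier)
    fixed = apply_fixed_cutoffs(
        barcodes, params.min_umi, params.min_genes,
        params.max_pct_mito, params.max_pct_hemoglobin)
    mad, thresholds = apply_mad_cutoffs(barcodes, params.mad_k, params.mad_scale)
    decisions = pd.concat([lc, fixed, mad], axis=1)[FLAG_COLUMNS]
    decisions["pass"] = ~decisions[FLAG_COLUMNS].any(axis=1)
    thresholds = dict(thresholds)
    thresholds["cooks_distance"] = params.cooks_multiplier / fit.n
    thresholds["loess_cut"] = params.loess_cut
    counts = {c: int(decisions[c].sum()) for c in FLAG_COLUMNS}
    counts["pass"] = int(decisions["pass"].sum())
    counts["total"] = int(len(decisions))
    return QCResult(decisions, thresholds, counts)


def run_qc_per_sample(
    barcodes: pd.DataFrame, samples: pd.Series, params: QCParams | None = None
) -> QCResult:
    """Apply ``run_qc`` independently to each sample's barcodes."""
    parts, thresholds, counts = [], {}, {}
    for sample, idx in samples.groupby(samples).groups.items():
        res = run_qc(barcodes.loc[idx], params)
        parts.append(res.decisions)
        thresholds[str(sample)] = res.thresholds
        counts[str(sample)] = res.counts
    decisions = pd.concat(parts).loc[barcodes.index]
    return QCResult(decisions, thresholds, counts)
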