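"""Recovery and calibration studies on synthetic data.

Each function sets up one planted-truth study (the study conditions mirror
the 4 TKO / 3 DKOAA / 3 DKO replicate design), runs the corresponding
analysis end to end, and returns the measured quantity — a sensitivity, a
false-positive rate, a rejection rate under the null, or an oracle
discrepancy.  These are the quantities the repository's acceptance checks
and the reproduction script report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cnv, proteomics, pseudobulk, qc, signatures, survival, synthetic
from .config import SimConfig
from .synthetic import GeneSet


def _child_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


# --- barcode QC --------------------------------------------------------------

def qc_recovery(seed: int = 0, n_barcodes: int = 10_000) -> dict:
    """Two-step regression filter and MAD mito filter on the default
    synthetic sample (5% planted RBC-like, 5% planted high-mito)."""
    cfg = SimConfig(seed=_child_seed(seed, 1), groups=[("S", 1)],
                    cells_per_sample=n_barcodes)
    sim = synthetic.simulate_counts(cfg)
    result = qc.run_qc(sim.qc)
    truth = sim.truth.bad_barcode_flags
    lc_flag = result.decisions["low_complexity"]
    planted_lc = (truth == "low_complexity").to_numpy()
    planted_hm = (truth == "high_mito").to_numpy()
    return {
        "sensitivity": float(lc_flag[planted_lc].mean()),
        "fpr": float(lc_flag[~planted_lc].mean()),
        "mad_mito_recall": float(
            result.decisions["fail_mito_mad"][planted_hm].mean()),
        "n": n_barcodes,
    }


def cooks_oracle_discrepancy(seed: int = 0, n_datasets: int = 100) -> dict:
    """Max |hat-matrix Cook's D - leave-one-out refit Cook's D| over random
    small regressions."""
    rng = np.random.default_rng(_child_seed(seed, 2))
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(10, 40))
        x = rng.normal(7.0, 1.0, n)
        y = 0.8 * x + rng.normal(0.0, 0.3, n)
        table = pd.DataFrame({
            "n_umi": np.exp(x), "n_gene": np.maximum(np.exp(y), 1.0),
            "pct_mito": 0.0, "pct_hemoglobin": 0.0})
        fit = qc.fit_complexity_regression(table)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        mse = np.sum((y - X @ beta) ** 2) / (n - 2)
        loo = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            loo[i] = np.sum((X @ beta - X @ beta_i) ** 2) / (2 * mse)
        worst = max(worst, float(
            np.abs(fit.table["cooks_distance"].to_numpy() - loo).max()))
    return {"max_abs_diff": worst, "n": n_datasets}


# --- exact small-sample tests ------------------------------------------------

def wilcoxon_minimum_p() -> dict:
    """Smallest attainable two-sided exact p for the study's group sizes."""
    p33 = float(cnv.exact_wilcoxon_rank_sum([[4, 5, 6]], [[1, 2, 3]])[0])
    p43 = float(cnv.exact_wilcoxon_rank_sum([[4, 5, 6, 7]], [[1, 2, 3]])[0])
    return {"min_p_3v3": p33, "min_p_4v3": p43}


def fisher_enumeration_sweep(max_total: int = 40) -> dict:
    """Exhaustive comparison of the Fisher p against full hypergeometric
    enumeration for every 2x2 table with positive margins and N <= max_total.
    Returns the largest absolute discrepancy and the number of tables."""
    from math import comb

    worst, count = 0.0, 0
    for n in range(1, max_total + 1):
        for r1 in range(1, n):
            for c1 in range(1, n):
                k_min = max(0, r1 + c1 - n)
                k_max = min(r1, c1)
                denom = comb(n, c1)
                probs = np.array([
                    comb(r1, k) * comb(n - r1, c1 - k) / denom
                    for k in range(k_min, k_max + 1)])
                for a in range(k_min, k_max + 1):
                    b, c = r1 - a, c1 - a
                    d = n - r1 - c
                    p_oracle = probs[probs <= probs[a - k_min] * (1 + 1e-7)].sum()
                    _, p = pseudobulk.fisher_exact_2x2([[a, b], [c, d]])
                    worst = max(worst, abs(p - float(p_oracle)))
                    count += 1
    return {"max_abs_diff": worst, "n": count}


# --- DiffAmps ----------------------------------------------------------------

def _diffamps_config(seed: int, null: bool) -> SimConfig:
    if null:
        amp = {"TKO": 0.3, "DKO": 0.3}
        disp = 0.05
    else:
        amp = {"TKO": 0.5, "DKO": 0.05}
        disp = 0.02
    return SimConfig(seed=seed, groups=[("TKO", 4), ("DKO", 3)],
                     cells_per_sample=300, n_cnv_genes=60,
                     n_amplified_genes=10, amp_cell_fraction=amp,
                     replicate_dispersion=disp)


def diffamps_count_power(seed: int = 0, n_sims: int = 200) -> dict:
    """Fraction of planted amplified genes (amp fraction 0.5 vs 0.05, 4v3
    samples, 300 cells each) detected at p < 0.1 by DiffAmps_count."""
    hits = tot = 0
    for k in range(n_sims):
        sim = synthetic.simulate_cnv_states(
            _diffamps_config(_child_seed(seed, 100 + k), null=False))
        res, _ = cnv.diffamps_count(
            sim.states, sim.metadata["sample"], sim.metadata["group"],
            "TKO", "DKO", mode="amp")
        planted = next(iter(sim.truth.amplified_gene_ids.values()))
        mask = res["gene"].isin(planted)
        hits += int((res.loc[mask, "p"] < 0.1).sum())
        tot += int(mask.sum())
    return {"power": hits / tot, "n": tot}


def diffamps_count_null_rate(seed: int = 0, n_sims: int = 200) -> dict:
    """p < 0.1 rate of DiffAmps_count when both groups share the planted
    amplification fraction (0.3) and replicate dispersion."""
    hits = tot = 0
    for k in range(n_sims):
        sim = synthetic.simulate_cnv_states(
            _diffamps_config(_child_seed(seed, 300 + k), null=True))
        res, _ = cnv.diffamps_count(
            sim.states, sim.metadata["sample"], sim.metadata["group"],
            "TKO", "DKO", mode="amp")
        planted = next(iter(sim.truth.amplified_gene_ids.values()))
        mask = res["gene"].isin(planted)
        hits += int((res.loc[mask, "p"] < 0.1).sum())
        tot += int(mask.sum())
    return {"rate": hits / tot, "n": tot}


# --- centroid-distance heterogeneity test ------------------------------------

def _centroid_config(seed: int, dispersion_a: float) -> SimConfig:
    return SimConfig(seed=seed, groups=[("TKO", 4), ("DKO", 3)],
                     cells_per_sample=300, n_cnv_genes=100,
                     n_amplified_genes=10,
                     amp_cell_fraction={"TKO": 0.3, "DKO": 0.3},
                     replicate_dispersion={"TKO": dispersion_a, "DKO": 0.02})


def _centroid_p(cfg: SimConfig) -> float:
    sim = synthetic.simulate_cnv_states(cfg)
    emb = cnv.cnv_pca(sim.states, n_components=10)
    res = cnv.centroid_distance_test(
        emb, sim.metadata["sample"], sim.metadata["group"],
        group_pairs=[("TKO", "DKO")])
    return float(res.tests["p"].iloc[0])


def centroid_test_power(seed: int = 0, n_sims: int = 200) -> dict:
    """Detection rate (p < 0.05) of 3x planted replicate dispersion."""
    det = sum(_centroid_p(_centroid_config(_child_seed(seed, 500 + k), 0.06))
              < 0.05 for k in range(n_sims))
    return {"power": det / n_sims, "n": n_sims}


def centroid_test_null_rate(seed: int = 0, n_sims: int = 200) -> dict:
    """Rejection rate (p < 0.05) under equal replicate dispersion."""
    rej = sum(_centroid_p(_centroid_config(_child_seed(seed, 700 + k), 0.02))
              < 0.05 for k in range(n_sims))
    return {"rate": rej / n_sims, "n": n_sims}


# --- compositional test ------------------------------------------------------

def _composition_config(seed: int, null: bool) -> SimConfig:
    if null:
        comp = {"Malignant": (0.5, 0.5), "Osteoclast": (0.15, 0.15),
                "Fibroblast": (0.30, 0.30), "Macrophage": (0.05, 0.05)}
    else:
        comp = {"Malignant": (0.5, 0.5), "Osteoclast": (0.30, 0.03),
                "Fibroblast": (0.15, 0.42), "Macrophage": (0.05, 0.05)}
    return SimConfig(seed=seed, groups=[("TKO", 4), ("DKO", 3)],
                     cells_per_sample=500, composition_shift=comp)


def composition_power(seed: int = 0, n_sims: int = 200) -> dict:
    """Detection rate (fdr < 0.05) of the planted 30% vs 3% subtype shift."""
    det = 0
    for k in range(n_sims):
        meta = synthetic.simulate_composition_metadata(
            _composition_config(_child_seed(seed, 900 + k), null=False))
        res, _ = pseudobulk.proportion_test(meta,
                                            group_pairs=[("TKO", "DKO")])
        det += res.loc[res["unit"] == "Osteoclast", "fdr"].iloc[0] < 0.05
    return {"power": det / n_sims, "n": n_sims}


def composition_null_rate(seed: int = 0, n_sims: int = 200) -> dict:
    """p < 0.05 rate for one designated cell type under equal composition."""
    rej = 0
    for k in range(n_sims):
        meta = synthetic.simulate_composition_metadata(
            _composition_config(_child_seed(seed, 1100 + k), null=True))
        res, _ = pseudobulk.proportion_test(meta,
                                            group_pairs=[("TKO", "DKO")])
        rej += res.loc[res["unit"] == "Osteoclast", "p"].iloc[0] < 0.05
    return {"rate": rej / n_sims, "n": n_sims}


# --- module score ------------------------------------------------------------

def module_score_null(seed: int = 0, n_genes: int = 2000,
                      n_cells: int = 10_000) -> dict:
    """Mean module score of a random 50-gene set on a structure-free
    log-normalized matrix (should vanish)."""
    expr = synthetic.null_expression_matrix(n_genes, n_cells,
                                            seed=_child_seed(seed, 3))
    rng = np.random.default_rng(_child_seed(seed, 4))
    members = tuple(expr.index[np.sort(rng.choice(n_genes, 50, replace=False))])
    score = signatures.module_score(expr, GeneSet("random50", members),
                                    seed=_child_seed(seed, 5))
    return {"mean_score": float(score.mean()), "n": n_cells}


# --- survival ----------------------------------------------------------------

def logrank_power(seed: int = 0, n_sims: int = 200) -> dict:
    """Power of the log-rank test on median-dichotomized cohorts simulated
    with hazard ratio 3 per unit signature score (n = 200 patients)."""
    det = 0
    for k in range(n_sims):
        cfg = SimConfig(seed=_child_seed(seed, 1300 + k),
                        survival_n_patients=200,
                        survival_effect=float(np.log(3.0)))
        cohort = synthetic.simulate_survival_cohort(cfg)
        strata = survival.stratify_by_score(cohort.truth.hazard_score)
        _, p = survival.logrank_test(
            cohort.clinical["time"], cohort.clinical["event"],
            strata.to_numpy())
        det += p < 0.05
    return {"power": det / n_sims, "n": n_sims}


# --- proteomics --------------------------------------------------------------

def imputation_offset(seed: int = 0, n_missing: int = 10_000) -> dict:
    """Empirical offset of imputed values from the observed sample mean, in
    observed-SD units (target: -shift_sd = -2), plus the mask-exactness and
    the standard error of the check."""
    rng = np.random.default_rng(_child_seed(seed, 6))
    n = 2 * n_missing
    raw = pd.DataFrame(
        np.power(2.0, rng.normal(20.0, 1.0, (n, 2))),
        index=[f"p{i}" for i in range(n)], columns=["s0", "s1"])
    raw.iloc[:n_missing, 0] = np.nan
    processed = proteomics.normalize_log2(raw)
    observed = processed.values["s0"][~processed.mask["s0"]]
    mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
    imputed = proteomics.impute_downshift(processed, shift_sd=2.0,
                                          width_frac=0.3,
                                          seed=_child_seed(seed, 7))
    drawn = imputed.values["s0"][processed.mask["s0"]]
    untouched = bool(
        (imputed.values["s1"] == processed.values["s1"]).all()
        and (imputed.values["s0"][~processed.mask["s0"]] == observed).all())
    se_units = 3.0 * 0.3 / np.sqrt(n_missing)
    return {
        "offset_sd_units": float((drawn.mean() - mu) / sigma),
        "tolerance_sd_units": float(se_units),
        "observed_untouched": untouched,
        "n": n_missing,
    }
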