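"""Synthetic inputs with planted ground truth.

Every generator emulates one class of input the analysis modules consume:

* ``simulate_counts`` — a 10x-style sparse UMI matrix over grouped replicate
  samples, with planted RBC-like (low-complexity) and high-mitochondria
  barcodes, planted differentially expressed genes in the first group's
  malignant cells, and planted cell-type compositional shifts.
* ``simulate_cnv_states`` — a 6-state HMM copy-number matrix (states
  {0, 0.5, 1, 1.5, 2, 3}) with planted gene-level amplifications and
  between-replicate heterogeneity.
* ``simulate_survival_cohort`` — a bulk-expression cohort whose event hazard
  is log-linear in a per-patient signature score.
* ``simulate_proteomics`` — protein intensities with missing-not-at-random
  entries (low-abundance proteins drop out preferentially).

All randomness flows from ``SimConfig.seed`` through named child streams, so
adding one generator never perturbs another's output and regeneration with
the same config is bit-for-bit reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.special import expit

from .config import SimConfig

SUBTYPES = ("Chondroblastic", "Fibroblastic", "Osteoblastic")

# fixed child-stream ids: a generator's stream never depends on which other
# generators were called
_STREAMS = {
    "counts": 11,
    "cnv": 23,
    "survival": 37,
    "proteomics": 41,
    "labels": 53,
    "xspecies": 67,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class GeneSet:
    """A named gene set (one GMT line)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        # deduplicate preserving order
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g))
        self.genes = tuple(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class SyntheticTruth:
    """Planted ground truth used by recovery-based tests."""

    bad_barcode_flags: pd.Series | None = None  # barcode -> low_complexity/high_mito/none
    amplified_gene_ids: dict[str, set] = field(default_factory=dict)  # group -> genes
    de_gene_ids: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    true_subtype: dict[str, str] = field(default_factory=dict)  # sample -> subtype
    true_cell_subtype: pd.Series | None = None  # cell -> cell type
    hazard_score: pd.Series | None = None  # patient -> score


@dataclass
class SimulatedCounts:
    counts: sp.csr_matrix  # cells x genes
    barcodes: list[str]
    features: pd.DataFrame  # gene_id, gene_name
    qc: pd.DataFrame  # BarcodeQC table
    metadata: pd.DataFrame  # barcode, sample, group, celltype
    truth: SyntheticTruth


@dataclass
class SimulatedCNV:
    states: pd.DataFrame  # cells x genes, values in the 6-state alphabet
    metadata: pd.DataFrame  # cell, sample, group, celltype
    truth: SyntheticTruth


@dataclass
class SurvivalCohort:
    clinical: pd.DataFrame  # patient, time, event
    expression: pd.DataFrame  # genes x patients, non-negative log-scale
    signature: GeneSet
    truth: SyntheticTruth


@dataclass
class SimulatedProteomics:
    raw: pd.DataFrame  # proteins x samples, linear scale, NaN = missing
    mask: pd.DataFrame  # True where missing
    groups: pd.Series  # sample -> group
    truth_log2: pd.DataFrame  # pre-masking log2 abundances
    de_protein_ids: dict[str, int]


def gene_names(config: SimConfig) -> list[str]:
    """Gene ids: 13 mt- genes, Hb[ab] hemoglobins, then generic symbols."""
    mito = [f"mt-Gene{i + 1}" for i in range(config.n_mito_genes)]
    hb_pool = ["Hba-a1", "Hba-a2", "Hbb-bs", "Hbb-bt", "Hba-x", "Hbb-y",
               "Hbb-bh1", "Hbb-bh2", "Hba-ps3", "Hbb-ps4"]
    hb = hb_pool[: config.n_hemoglobin_genes]
    n_body = config.n_genes - len(mito) - len(hb)
    if n_body < 20:
        raise ValueError("n_genes too small for the mito/hemoglobin layout")
    body = [f"Gene{i + 1:05d}" for i in range(n_body)]
    return mito + hb + body


def simulate_counts(config: SimConfig) -> SimulatedCounts:
    """Generate the UMI count matrix, its BarcodeQC table, and the truth.

    Good barcodes draw total UMIs from a log-normal (median ~3,000 at the
    defaults) and spread them over a power-law expression profile, giving the
    approximately log-linear genes~UMIs relation the QC regression assumes.
    Planted low-complexity barcodes are RBC-like: all but a Poisson(1) handful
    of UMIs fall on the hemoglobin genes.  Planted high-mito barcodes draw
    their mitochondrial fraction from Uniform(0.25, 0.75), far above any
    plausible MAD cutoff.  Differential expression (config.n_de_genes at
    +/- config.de_log2fc) is planted in the first group's malignant cells.
    """
    config.validate()
    rng = child_rng(config.seed, "counts")
    genes = gene_names(config)
    n_genes = len(genes)
    n_mito = config.n_mito_genes
    n_hb = config.n_hemoglobin_genes
    mito_idx = np.arange(n_mito)
    hb_idx = np.arange(n_mito, n_mito + n_hb)
    body_idx = np.arange(n_mito + n_hb, n_genes)

    # power-law expression profile over non-mito, non-hemoglobin genes
    ranks = np.arange(1, body_idx.size + 1, dtype=float)
    base_profile = ranks ** -config.profile_exponent
    base_profile /= base_profile.sum()
    mito_profile = np.arange(1, n_mito + 1, dtype=float) ** -0.5
    mito_profile /= mito_profile.sum()
    hb_profile = np.full(n_hb, 1.0 / n_hb)

    # planted DE genes: a fixed block of well-expressed body genes, half up,
    # half down; the block starts at body gene 20 so the CNV simulator can
    # plant its amplifications on the same (up-regulated) gene ids
    half = config.n_de_genes // 2
    if 20 + config.n_de_genes > body_idx.size:
        raise ValueError("n_de_genes too large for the gene space")
    de_sel = body_idx[20:20 + config.n_de_genes]
    de_dir = {int(g): (1 if i < half else -1) for i, g in enumerate(de_sel)}
    de_profile = base_profile.copy()
    for g, d in de_dir.items():
        de_profile[g - body_idx[0]] *= 2.0 ** (d * config.de_log2fc)
    de_profile /= de_profile.sum()

    celltypes = sorted(config.composition_shift)
    comp = np.array([config.composition_shift[c] for c in celltypes])  # unit x group

    first_group = config.group_names[0]
    subtype_cycle = {}
    for gi, (g, n_rep) in enumerate(config.groups):
        for ri in range(n_rep):
            subtype_cycle[f"{g}_{ri + 1}"] = SUBTYPES[(gi + ri) % len(SUBTYPES)]

    blocks, barcodes, meta_rows = [], [], []
    flags_all = []
    n = config.cells_per_sample
    for gi, (group, n_rep) in enumerate(config.groups):
        props = comp[:, gi]
        for ri in range(n_rep):
            sample = f"{group}_{ri + 1}"
            flag = rng.choice(
                3, size=n,
                p=[config.frac_low_complexity, config.frac_high_mito,
                   1.0 - config.frac_low_complexity - config.frac_high_mito])
            celltype = rng.choice(len(celltypes), size=n, p=props)
            totals = np.maximum(
                np.rint(rng.lognormal(config.umi_meanlog, config.umi_sdlog, n)), 1
            ).astype(np.int64)
            # RBC-like droplets are transcript-rich (hemoglobin dominates the
            # cytoplasm), so their totals sit higher and tighter
            n_lc = int((flag == 0).sum())
            totals[flag == 0] = np.maximum(
                np.rint(rng.lognormal(config.umi_meanlog + 0.5,
                                      0.4, n_lc)), 1).astype(np.int64)
            mito_frac = rng.beta(2.0, 48.0, size=n)
            mito_frac[flag == 1] = rng.uniform(0.25, 0.75, size=int((flag == 1).sum()))
            mito_frac[flag == 0] = 0.0  # RBC-like barcodes carry no mito signal
            mito_total = rng.binomial(totals, mito_frac)
            body_total = totals - mito_total

            counts = np.zeros((n, n_genes), dtype=np.int64)
            if n_mito:
                counts[:, mito_idx] = rng.multinomial(mito_total, mito_profile)

            is_lc = flag == 0
            is_de = (~is_lc) & (group == first_group) & (
                np.array(celltypes)[celltype] == "Malignant")
            is_base = (~is_lc) & (~is_de)
            if is_base.any():
                counts[np.ix_(is_base, body_idx)] = rng.multinomial(
                    body_total[is_base], base_profile)
            if is_de.any():
                counts[np.ix_(is_de, body_idx)] = rng.multinomial(
                    body_total[is_de], de_profile)
            if is_lc.any():
                stray = np.minimum(rng.poisson(0.5, int(is_lc.sum())),
                                   body_total[is_lc]).astype(np.int64)
                hb_total = body_total[is_lc] - stray
                counts[np.ix_(is_lc, hb_idx)] = rng.multinomial(hb_total, hb_profile)
                counts[np.ix_(is_lc, body_idx)] += rng.multinomial(stray, base_profile)

            blocks.append(sp.csr_matrix(counts))
            bc = [f"{sample}:BC{j + 1:05d}" for j in range(n)]
            barcodes.extend(bc)
            flags_all.extend(
                np.array(["low_complexity", "high_mito", "none"])[flag])
            meta_rows.append(pd.DataFrame({
                "barcode": bc,
                "sample": sample,
                "group": group,
                "celltype": np.array(celltypes)[celltype],
            }))

    counts = sp.vstack(blocks, format="csr")
    metadata = pd.concat(meta_rows, ignore_index=True).set_index("barcode")
    features = pd.DataFrame({"gene_id": genes, "gene_name": genes})
    qc = qc_table(counts, barcodes, genes)
    truth = SyntheticTruth(
        bad_barcode_flags=pd.Series(flags_all, index=barcodes, name="flag"),
        de_gene_ids={genes[g]: d for g, d in de_dir.items()},
        true_subtype=subtype_cycle,
        true_cell_subtype=metadata["celltype"].copy(),
    )
    return SimulatedCounts(counts, barcodes, features, qc, metadata, truth)


def qc_table(
    counts: sp.spmatrix,
    barcodes: list[str],
    genes: list[str],
    mito_prefix: str = "mt-",
    hemoglobin_regex: str = "^Hb[ab]",
) -> pd.DataFrame:
    """Build the per-barcode QC table (UMIs, genes, %mito, %hemoglobin)."""
    counts = sp.csr_matrix(counts)
    genes_arr = np.asarray(genes, dtype=object)
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in genes_arr])
    hb_re = re.compile(hemoglobin_regex)
    hb_mask = np.array([bool(hb_re.match(str(g))) for g in genes_arr])
    n_umi = np.asarray(counts.sum(axis=1)).ravel()
    n_gene = counts.getnnz(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = 100.0 * np.asarray(
            counts[:, mito_mask].sum(axis=1)).ravel() / np.maximum(n_umi, 1)
        pct_hb = 100.0 * np.asarray(
            counts[:, hb_mask].sum(axis=1)).ravel() / np.maximum(n_umi, 1)
    return pd.DataFrame(
        {"n_umi": n_umi.astype(np.int64), "n_gene": n_gene.astype(np.int64),
         "pct_mito": pct_mito, "pct_hemoglobin": pct_hb},
        index=pd.Index(barcodes, name="barcode"),
    )


CNV_STATES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)


def simulate_cnv_states(config: SimConfig) -> SimulatedCNV:
    """Generate a 6-state CNV matrix with planted amplifications.

    Background genes are copy-neutral (state 1) in >=95% of cells with
    symmetric mild noise (0.5 / 1.5) and a small extreme rate split between
    state 0 and state >=2.  For each planted gene, a per-group fraction of
    cells carries state >=2.  Replicate heterogeneity: each replicate's
    per-gene amplification probability is perturbed by
    Normal(0, replicate_dispersion[group]).  Per-gene state counts within a
    sample are assigned deterministically as round(p * n_cells) cells, so with
    zero dispersion all replicate mean-state profiles are exactly identical.
    """
    config.validate()
    rng = child_rng(config.seed, "cnv")
    n_genes = config.n_cnv_genes
    # CNV genes share the expression gene namespace (the leading body genes),
    # so planted amplifications coincide with planted up-regulated DE genes
    # and the candidate-intersection step has something to find
    all_names = gene_names(config)
    body_names = all_names[config.n_mito_genes + config.n_hemoglobin_genes:]
    if n_genes <= len(body_names):
        genes = body_names[:n_genes]
    else:
        genes = [f"CnvGene{i + 1:04d}" for i in range(n_genes)]
    start = max(0, min(20, n_genes - config.n_amplified_genes))
    planted = np.arange(start, start + config.n_amplified_genes)
    n = config.cells_per_sample

    frames, meta_rows = [], []
    for gi, (group, n_rep) in enumerate(config.groups):
        base_amp = np.full(n_genes, config.cnv_background_extreme)
        base_amp[planted] = config.amp_cell_fraction[group]
        disp = config.replicate_dispersion[group]
        for ri in range(n_rep):
            sample = f"{group}_{ri + 1}"
            p_amp = base_amp + (rng.normal(0.0, disp, n_genes) if disp > 0
                                else 0.0)
            p_amp = np.clip(p_amp, 0.0, 1.0)
            k_amp = np.rint(p_amp * n).astype(int)
            k_del = np.rint(np.full(n_genes, config.cnv_background_extreme) * n
                            ).astype(int)
            k_mild = np.rint(np.full(n_genes, config.cnv_background_mild) * n
                             ).astype(int)
            # cap so state assignments never overlap
            k_del = np.minimum(k_del, n - k_amp)
            k_05 = np.minimum(k_mild, n - k_amp - k_del)
            k_15 = np.minimum(k_mild, n - k_amp - k_del - k_05)

            order = np.argsort(rng.random((n, n_genes)), axis=0)
            pos = np.empty_like(order)
            np.put_along_axis(pos, order, np.arange(n)[:, None], axis=0)
            states = np.ones((n, n_genes))
            k2 = np.ceil(0.8 * k_amp).astype(int)  # amp cells: 80% state 2, rest 3
            states[pos < k2] = 2.0
            states[(pos >= k2) & (pos < k_amp)] = 3.0
            b = k_amp
            states[(pos >= b) & (pos < b + k_del)] = 0.0
            b = b + k_del
            states[(pos >= b) & (pos < b + k_05)] = 0.5
            b = b + k_05
            states[(pos >= b) & (pos < b + k_15)] = 1.5

            cells = [f"{sample}:C{j + 1:04d}" for j in range(n)]
            frames.append(pd.DataFrame(states, index=cells, columns=genes))
            meta_rows.append(pd.DataFrame({
                "cell": cells, "sample": sample, "group": group,
                "celltype": "Malignant"}))

    states = pd.concat(frames)
    states.index.name = "cell"
    metadata = pd.concat(meta_rows, ignore_index=True).set_index("cell")
    planted_names = {genes[i] for i in planted}
    truth = SyntheticTruth(
        amplified_gene_ids={g: set(planted_names) for g in config.group_names})
    return SimulatedCNV(states, metadata, truth)


def simulate_survival_cohort(
    config: SimConfig,
    signature: GeneSet | None = None,
    censor_horizon: float | None = None,
) -> SurvivalCohort:
    """Cohort whose event hazard is exp(log baseline + effect * score).

    Each patient carries a latent standard-normal score; signature genes'
    (log-scale, non-negative) expression is shifted by that score so the
    module-score procedure can recover it.  Event times are exponential with
    the stated log-hazard; censoring is an independent exponential (plus an
    optional administrative horizon).
    """
    config.validate()
    if not np.isfinite(config.survival_effect):
        raise ValueError("survival_effect must be finite")
    rng = child_rng(config.seed, "survival")
    n_pat = config.survival_n_patients
    n_genes = config.survival_n_genes
    genes = [f"BulkGene{i + 1:04d}" for i in range(n_genes)]
    if signature is None:
        members = rng.choice(n_genes, size=config.signature_size, replace=False)
        signature = GeneSet("planted_signature",
                            tuple(genes[i] for i in np.sort(members)))
    member_set = set(signature.genes)

    patients = [f"P{i + 1:04d}" for i in range(n_pat)]
    score = rng.normal(0.0, 1.0, n_pat)
    base = rng.uniform(0.5, 3.0, n_genes)
    base[[g in member_set for g in genes]] += 2.0  # headroom: no floor clipping
    expr = base[:, None] + rng.normal(0.0, 0.3, (n_genes, n_pat))
    member_rows = np.array([g in member_set for g in genes])
    expr[member_rows] += score[None, :]
    expr = np.maximum(expr, 0.0)

    lam = config.survival_baseline_hazard * np.exp(config.survival_effect * score)
    t_event = rng.exponential(1.0 / lam)
    t_cens = (rng.exponential(1.0 / config.survival_censor_rate, n_pat)
              if config.survival_censor_rate > 0 else np.full(n_pat, np.inf))
    if censor_horizon is not None:
        t_cens = np.minimum(t_cens, float(censor_horizon))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if np.any(time <= 0):
        raise AssertionError("non-positive survival time generated")

    clinical = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(patients, name="patient"))
    expression = pd.DataFrame(expr, index=genes, columns=patients)
    truth = SyntheticTruth(hazard_score=pd.Series(score, index=patients))
    return SurvivalCohort(clinical, expression, signature, truth)


def simulate_proteomics(config: SimConfig) -> SimulatedProteomics:
    """Protein intensities with missing-not-at-random dropout.

    True per-protein log2 abundances are normal; the dropout probability is a
    decreasing logistic function of abundance whose intercept is solved so the
    overall missing rate matches ``proteomics_missing_rate``.
    """
    config.validate()
    rng = child_rng(config.seed, "proteomics")
    n_prot = config.n_proteins
    proteins = [f"Prot{i + 1:05d}" for i in range(n_prot)]
    samples = config.sample_names
    groups = pd.Series(config.sample_groups, name="group").loc[samples]

    mu = rng.normal(22.0, 2.5, n_prot)
    x = mu[:, None] + rng.normal(0.0, config.protein_noise_sd,
                                 (n_prot, len(samples)))
    n_de = min(config.n_de_proteins, n_prot)
    half = n_de // 2
    de_dir = {proteins[i]: (1 if i < half else -1) for i in range(n_de)}
    first = [s for s in samples if groups[s] == config.group_names[0]]
    first_cols = [samples.index(s) for s in first]
    for i in range(n_de):
        x[i, first_cols] += (1 if i < half else -1) * config.protein_shift

    rate = config.proteomics_missing_rate
    if rate > 0:
        z = (x - x.mean()) / x.std()
        def mean_rate(a: float) -> float:
            return float(expit(a - 2.0 * z).mean()) - rate
        a = brentq(mean_rate, -50.0, 50.0)
        mask = rng.random(x.shape) < expit(a - 2.0 * z)
        # a fully missing sample breaks normalization; regenerate such columns
        for j in np.where(mask.all(axis=0))[0]:  # pragma: no cover
            mask[rng.integers(n_prot), j] = False
    else:
        mask = np.zeros(x.shape, dtype=bool)

    truth_log2 = pd.DataFrame(x, index=proteins, columns=samples)
    raw = np.power(2.0, x)
    raw[mask] = np.nan
    raw_df = pd.DataFrame(raw, index=proteins, columns=samples)
    mask_df = pd.DataFrame(mask, index=proteins, columns=samples)
    return SimulatedProteomics(raw_df, mask_df, groups, truth_log2, de_dir)


def simulate_label_transfer(
    config: SimConfig,
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    concentration: float = 8.0,
) -> pd.DataFrame:
    """Transferred-label table for malignant cells.

    Per-cell label scores are Dirichlet draws concentrated on the sample's
    true pathologic subtype; the predicted label is the argmax, so per-sample
    majorities recover the planted subtype.
    """
    rng = child_rng(config.seed, "labels")
    malignant = metadata.index[metadata["celltype"] == "Malignant"]
    labels = list(SUBTYPES)
    rows = []
    for cell in malignant:
        sample = metadata.at[cell, "sample"]
        alpha = np.ones(len(labels))
        alpha[labels.index(truth.true_subtype[sample])] += concentration
        scores = rng.dirichlet(alpha)
        rows.append(scores)
    scores = pd.DataFrame(rows, index=malignant, columns=labels)
    out = pd.DataFrame({"predicted": scores.idxmax(axis=1)})
    return pd.concat([out, scores], axis=1)


def simulate_ortholog_table(
    source_genes: list[str],
    n_ambiguous: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse->human ortholog pairs: mostly one-to-one (upper-cased symbol),
    with a few planted one-to-many and many-to-one ambiguities."""
    rng = child_rng(seed, "xspecies")
    rows = [(g, g.upper()) for g in source_genes]
    if source_genes:
        amb = rng.choice(len(source_genes), size=min(n_ambiguous, len(source_genes)),
                         replace=False)
        for i in amb[: len(amb) // 2 + 1]:
            rows.append((source_genes[i], source_genes[i].upper() + "-ALT"))
        for i in amb[len(amb) // 2 + 1:]:
            rows.append((source_genes[i] + "l1", source_genes[i].upper()))
    return pd.DataFrame(rows, columns=["source", "target"])


def simulate_crossspecies(
    config: SimConfig,
    n_types: int = 4,
    markers_per_type: int = 20,
    cells_per_type: int = 60,
    signal: float = 2.0,
):
    """Planted cross-species correspondence: marker sets per source cell type,
    an ortholog table, and a target expression matrix in which each target
    type over-expresses the orthologs of exactly one source set.

    Returns ``(marker_sets, orthologs, target_expr, target_labels, matching)``
    where ``matching`` maps source set name -> matched target type.
    """
    rng = child_rng(config.seed, "xspecies")
    n_genes = n_types * markers_per_type + 200
    source_genes = [f"Ms{i + 1:04d}" for i in range(n_genes)]
    marker_sets = {}
    for t in range(n_types):
        name = f"mouse_type_{t + 1}"
        members = source_genes[t * markers_per_type:(t + 1) * markers_per_type]
        marker_sets[name] = GeneSet(name, tuple(members))
    orthologs = simulate_ortholog_table(source_genes, n_ambiguous=8,
                                        seed=config.seed)

    target_genes = [g.upper() for g in source_genes]
    base = rng.uniform(0.5, 2.0, len(target_genes))
    cols, labels = [], []
    matching = {}
    for t in range(n_types):
        tname = f"human_type_{t + 1}"
        matching[f"mouse_type_{t + 1}"] = tname
        block = base[:, None] + rng.normal(0.0, 0.3,
                                           (len(target_genes), cells_per_type))
        block[t * markers_per_type:(t + 1) * markers_per_type] += signal
        cols.append(block)
        labels.extend([tname] * cells_per_type)
    expr = np.maximum(np.concatenate(cols, axis=1), 0.0)
    cells = [f"hcell{i + 1:05d}" for i in range(expr.shape[1])]
    target_expr = pd.DataFrame(expr, index=target_genes, columns=cells)
    target_labels = pd.Series(labels, index=cells, name="celltype")
    return marker_sets, orthologs, target_expr, target_labels, matching


def simulate_composition_metadata(config: SimConfig) -> pd.DataFrame:
    """Cell metadata only (sample, group, celltype), drawn from the same
    per-group composition model as ``simulate_counts`` — the light-weight
    input for compositional power/calibration studies that do not need a
    count matrix."""
    config.validate()
    rng = child_rng(config.seed, "counts")
    celltypes = sorted(config.composition_shift)
    comp = np.array([config.composition_shift[c] for c in celltypes])
    rows = []
    n = config.cells_per_sample
    for gi, (group, n_rep) in enumerate(config.groups):
        for ri in range(n_rep):
            sample = f"{group}_{ri + 1}"
            celltype = rng.choice(len(celltypes), size=n, p=comp[:, gi])
            rows.append(pd.DataFrame({
                "barcode": [f"{sample}:BC{j + 1:05d}" for j in range(n)],
                "sample": sample, "group": group,
                "celltype": np.array(celltypes)[celltype]}))
    return pd.concat(rows, ignore_index=True).set_index("barcode")


def null_expression_matrix(
    n_genes: int = 2000, n_cells: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Null log-normalized matrix: per-gene exponential noise around a
    gene-specific mean, no cell structure.  Used for score calibration."""
    rng = np.random.default_rng([97, int(seed)])
    mu = rng.uniform(0.05, 2.0, n_genes)
    expr = rng.exponential(mu[:, None], (n_genes, n_cells))
    genes = [f"NullGene{i + 1:05d}" for i in range(n_genes)]
    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    return pd.DataFrame(expr, index=genes, columns=cells)
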