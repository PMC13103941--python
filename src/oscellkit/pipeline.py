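"""End-to-end pipeline: simulate -> QC -> scores/markers -> pseudobulk /
composition -> CNV -> subtype -> cross-species -> survival -> proteomics.

Stages form a dependency graph over on-disk outputs: a stage re-runs when
forced, when any of its outputs is missing, or when an upstream stage ran;
otherwise its outputs are loaded from disk.  A manifest records the package
version, seed, per-stage parameter hashes and output checksums — reruns with
an identical configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from . import __version__, cnv, io, proteomics, pseudobulk, qc, signatures
from . import subtype as subtype_mod
from . import survival as survival_mod
from . import synthetic
from .config import PipelineConfig
from .synthetic import GeneSet


class Workspace:
    """Holds the configuration, output directory, and lazily loaded stage
    products (from memory when a stage just ran, from disk otherwise)."""

    def __init__(self, cfg: PipelineConfig, outdir: Path):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.cache: dict[str, object] = {}

    def path(self, rel: str) -> Path:
        return self.outdir / rel

    # --- simulate products -------------------------------------------------
    @property
    def counts(self):
        if "counts" not in self.cache:
            matrix, barcodes, features = io.read_mtx_triplet(self.path("sim"))
            self.cache["counts"] = (matrix, barcodes, features)
        return self.cache["counts"]

    @property
    def metadata(self) -> pd.DataFrame:
        if "metadata" not in self.cache:
            self.cache["metadata"] = io.read_table(self.path("sim/metadata.tsv"))
        return self.cache["metadata"]

    @property
    def cnv_states(self):
        if "cnv_states" not in self.cache:
            states = io.read_cnv_states(self.path("sim/cnv_states.tsv"))
            meta = io.read_table(self.path("sim/cnv_metadata.tsv"))
            self.cache["cnv_states"] = (states, meta)
        return self.cache["cnv_states"]

    @property
    def label_transfer(self) -> pd.DataFrame:
        if "label_transfer" not in self.cache:
            self.cache["label_transfer"] = io.read_table(
                self.path("sim/label_transfer.tsv"))
        return self.cache["label_transfer"]

    @property
    def gene_sets(self) -> dict[str, GeneSet]:
        if "gene_sets" not in self.cache:
            sets = io.read_gmt(self.path("sim/signatures.gmt"))
            self.cache["gene_sets"] = {s.name: s for s in sets}
        return self.cache["gene_sets"]

    @property
    def survival_inputs(self):
        if "survival_inputs" not in self.cache:
            clinical = io.read_table(self.path("sim/survival_clinical.tsv"))
            expr = io.read_table(self.path("sim/survival_expression.tsv"))
            self.cache["survival_inputs"] = (clinical, expr)
        return self.cache["survival_inputs"]

    @property
    def proteomics_raw(self):
        if "proteomics_raw" not in self.cache:
            raw = io.read_table(self.path("sim/proteomics_raw.tsv"))
            self.cache["proteomics_raw"] = raw
        return self.cache["proteomics_raw"]

    # --- downstream products ----------------------------------------------
    @property
    def qc_decisions(self) -> pd.DataFrame:
        if "qc_decisions" not in self.cache:
            self.cache["qc_decisions"] = io.read_table(
                self.path("qc/decisions.tsv"))
        return self.cache["qc_decisions"]

    @property
    def passing_metadata(self) -> pd.DataFrame:
        passing = self.qc_decisions.index[self.qc_decisions["pass"].astype(bool)]
        return self.metadata.loc[passing]

    @property
    def pseudobulk_matrix(self) -> pseudobulk.PseudobulkMatrix:
        if "pseudobulk_matrix" not in self.cache:
            pb = io.read_table(self.path("pseudobulk/pseudobulk.tsv"))
            groups = io.read_table(self.path("pseudobulk/sample_groups.tsv"))
            self.cache["pseudobulk_matrix"] = pseudobulk.PseudobulkMatrix(
                pb, groups["group"], "Malignant")
        return self.cache["pseudobulk_matrix"]

    def de_table(self, group_a: str, group_b: str) -> pd.DataFrame:
        return io.read_table(
            self.path(f"de/de_{group_a}_vs_{group_b}.tsv"), index_col=None)

    @property
    def expr(self) -> pd.DataFrame:
        """Log-normalized expression of QC-passing cells (not persisted)."""
        if "expr" not in self.cache:
            matrix, barcodes, features = self.counts
            passing = self.qc_decisions["pass"].astype(bool).to_numpy()
            expr = signatures.log_normalize(
                matrix[passing], [b for b, p in zip(barcodes, passing) if p],
                features["gene_id"])
            self.cache["expr"] = expr
        return self.cache["expr"]


def _pairs(cfg: PipelineConfig) -> list[tuple[str, str]]:
    return list(itertools.combinations(cfg.sim.group_names, 2))


# --- stage implementations ---------------------------------------------------

def _stage_simulate(ws: Workspace) -> None:
    cfg = ws.cfg
    sim = synthetic.simulate_counts(cfg.sim)
    out = ws.path("sim")
    io.write_mtx_triplet(out, sim.counts, sim.barcodes, sim.features)
    params = {"seed": cfg.sim.seed}
    io.write_table(sim.metadata, out / "metadata.tsv", "simulate", params)
    io.write_table(sim.qc, out / "barcode_qc.tsv", "simulate", params)
    io.write_table(sim.truth.bad_barcode_flags.to_frame(),
                   out / "truth_barcodes.tsv", "simulate", params)
    de = pd.DataFrame(sorted(sim.truth.de_gene_ids.items()),
                      columns=["gene", "direction"])
    io.write_table(de, out / "truth_de_genes.tsv", "simulate", params,
                   index=False)

    cnv_sim = synthetic.simulate_cnv_states(cfg.sim)
    io.write_table(cnv_sim.states, out / "cnv_states.tsv", "simulate", params)
    io.write_table(cnv_sim.metadata, out / "cnv_metadata.tsv", "simulate", params)
    amp = pd.DataFrame(
        sorted(next(iter(cnv_sim.truth.amplified_gene_ids.values()))),
        columns=["gene"])
    io.write_table(amp, out / "truth_amplified_genes.tsv", "simulate", params,
                   index=False)

    labels = synthetic.simulate_label_transfer(cfg.sim, sim.metadata, sim.truth)
    io.write_table(labels, out / "label_transfer.tsv", "simulate", params)

    cohort = synthetic.simulate_survival_cohort(cfg.sim)
    io.write_table(cohort.clinical, out / "survival_clinical.tsv", "simulate",
                   params)
    io.write_table(cohort.expression, out / "survival_expression.tsv",
                   "simulate", params)

    genes = [f for f in sim.features["gene_id"]]
    up = [g for g, d in sorted(sim.truth.de_gene_ids.items()) if d > 0]
    down = [g for g, d in sorted(sim.truth.de_gene_ids.items()) if d < 0]
    sets = [GeneSet("planted_de_up", tuple(up), "planted up-regulated genes"),
            GeneSet("planted_de_down", tuple(down), "planted down-regulated genes"),
            cohort.signature]
    del genes
    io.write_gmt(out / "signatures.gmt", sets)

    prot = synthetic.simulate_proteomics(cfg.sim)
    io.write_table(prot.raw, out / "proteomics_raw.tsv", "simulate", params)
    io.write_table(prot.mask, out / "proteomics_truth_mask.tsv", "simulate",
                   params)

    ws.cache["counts"] = (sim.counts, sim.barcodes, sim.features)
    ws.cache["metadata"] = sim.metadata
    ws.cache["cnv_states"] = (cnv_sim.states, cnv_sim.metadata)
    ws.cache["label_transfer"] = labels
    ws.cache["gene_sets"] = {s.name: s for s in sets}
    ws.cache["survival_inputs"] = (cohort.clinical, cohort.expression)
    ws.cache["proteomics_raw"] = prot.raw


def _stage_qc(ws: Workspace) -> None:
    matrix, barcodes, features = ws.counts
    table = synthetic.qc_table(
        matrix, barcodes, list(features["gene_id"]),
        mito_prefix=ws.cfg.qc.mito_prefix,
        hemoglobin_regex=ws.cfg.qc.hemoglobin_regex)
    result = qc.run_qc_per_sample(table, ws.metadata["sample"], ws.cfg.qc)
    params = dataclasses.asdict(ws.cfg.qc)
    io.write_table(result.decisions, ws.path("qc/decisions.tsv"), "qc", params)
    io.write_json({"thresholds": result.thresholds, "counts": result.counts},
                  ws.path("qc/thresholds.json"), "qc", params)
    ws.cache["qc_decisions"] = result.decisions


def _stage_markers(ws: Workspace) -> None:
    expr = ws.expr
    clusters = ws.passing_metadata["celltype"]
    table = signatures.find_markers(expr, clusters)
    io.write_table(table, ws.path("markers/markers.tsv"), "markers",
                   index=False)


def _stage_score(ws: Workspace) -> None:
    cfg = ws.cfg
    expr = ws.expr
    meta = ws.passing_metadata
    malignant = meta.index[meta["celltype"] == "Malignant"]
    gene_set = ws.gene_sets["planted_de_up"]
    scores = signatures.module_score(
        expr[malignant], gene_set, n_bins=cfg.score.n_bins,
        n_ctrl=cfg.score.n_ctrl, seed=cfg.seed)
    responders = signatures.classify_responders(scores)
    out = pd.DataFrame({"score": scores, "responder_high": responders})
    params = dataclasses.asdict(cfg.score)
    io.write_table(out, ws.path("score/scores.tsv"), "score", params)
    resp_meta = meta.loc[malignant, ["sample", "group"]].copy()
    resp_meta["responder"] = responders.map({True: "high", False: "low"})
    results, props = pseudobulk.proportion_test(resp_meta, unit_col="responder")
    io.write_table(results, ws.path("score/responder_composition.tsv"),
                   "score", params, index=False)
    io.write_table(props, ws.path("score/responder_proportions.tsv"),
                   "score", params)


def _stage_pseudobulk(ws: Workspace) -> None:
    matrix, barcodes, features = ws.counts
    decisions = ws.qc_decisions
    passing = decisions["pass"].astype(bool).to_numpy()
    kept_barcodes = [b for b, p in zip(barcodes, passing) if p]
    pb = pseudobulk.aggregate_pseudobulk(
        matrix[passing], kept_barcodes, list(features["gene_id"]),
        ws.metadata.loc[kept_barcodes], "Malignant")
    io.write_table(pb.counts, ws.path("pseudobulk/pseudobulk.tsv"), "pseudobulk")
    io.write_table(pb.sample_groups.to_frame("group"),
                   ws.path("pseudobulk/sample_groups.tsv"), "pseudobulk")
    ws.cache["pseudobulk_matrix"] = pb


def _stage_de(ws: Workspace) -> None:
    pb = ws.pseudobulk_matrix
    for ga, gb in _pairs(ws.cfg):
        table = pseudobulk.pseudobulk_de(pb, ga, gb)
        io.write_table(table, ws.path(f"de/de_{ga}_vs_{gb}.tsv"), "de",
                       {"group_a": ga, "group_b": gb}, index=False)


def _stage_composition(ws: Workspace) -> None:
    meta = ws.passing_metadata
    results, props = pseudobulk.proportion_test(meta, unit_col="celltype")
    io.write_table(results, ws.path("composition/composition.tsv"),
                   "composition", index=False)
    io.write_table(props, ws.path("composition/proportions.tsv"), "composition")


def _stage_cnv(ws: Workspace) -> None:
    cfg = ws.cfg
    states, meta = ws.cnv_states
    samples, groups = meta["sample"], meta["group"]
    params = dataclasses.asdict(cfg.cnv)

    burden = cnv.cnv_burden(states)
    io.write_table(burden, ws.path("cnv/burden.tsv"), "cnv", params)

    emb = cnv.cnv_pca(states, n_features=cfg.cnv.n_features,
                      n_components=cfg.cnv.n_components)
    io.write_table(emb.coords, ws.path("cnv/embedding.tsv"), "cnv", params)

    cdt = cnv.centroid_distance_test(emb, samples, groups)
    io.write_json(
        {"distances": cdt.distances.to_dict(orient="records"),
         "tests": cdt.tests.to_dict(orient="records")},
        ws.path("cnv/centroid_test.json"), "cnv", params)

    ga, gb = cfg.sim.group_names[0], cfg.sim.group_names[-1]
    dmean, _ = cnv.diffamps_mean(states, samples, groups, ga, gb,
                                 exact=cfg.cnv.exact)
    io.write_table(dmean, ws.path("cnv/diffamps_mean.tsv"), "cnv", params,
                   index=False)
    for mode in ("amp", "del"):
        dcount, _ = cnv.diffamps_count(states, samples, groups, ga, gb,
                                       mode=mode)
        io.write_table(dcount, ws.path(f"cnv/diffamps_count_{mode}.tsv"),
                       "cnv", params, index=False)

    de = ws.de_table(ga, gb)
    damp, _ = cnv.diffamps_count(states, samples, groups, ga, gb, mode="amp")
    candidates = cnv.select_candidates(damp, de, alpha=cfg.cnv.alpha)
    with open(ws.path("cnv/candidates.txt"), "w") as fh:
        fh.write("".join(f"{g}\n" for g in candidates))


def _stage_subtype(ws: Workspace) -> None:
    labels = ws.label_transfer
    meta = ws.metadata
    malignant = meta.index[meta["celltype"] == "Malignant"]
    calls = subtype_mod.call_subtype(labels, malignant, meta["sample"])
    io.write_table(calls, ws.path("subtype/subtype_calls.tsv"), "subtype",
                   index=False)


def _stage_xspecies(ws: Workspace) -> None:
    cfg = ws.cfg
    marker_sets, orthologs, target_expr, target_labels, matching = (
        synthetic.simulate_crossspecies(cfg.sim))
    score_matrix, corr, order = subtype_mod.crossspecies_score_matrix(
        marker_sets, target_expr, target_labels, orthologs,
        n_bins=cfg.score.n_bins, n_ctrl=cfg.score.n_ctrl, seed=cfg.seed)
    io.write_table(score_matrix, ws.path("xspecies/score_matrix.tsv"),
                   "xspecies")
    io.write_table(corr, ws.path("xspecies/correlation.tsv"), "xspecies")
    io.write_json({"row_order": order, "planted_matching": matching},
                  ws.path("xspecies/clustering.json"), "xspecies")


def _stage_survive(ws: Workspace) -> None:
    cfg = ws.cfg
    clinical, expr = ws.survival_inputs
    gene_set = ws.gene_sets["planted_signature"]
    scores = signatures.module_score(expr, gene_set, n_bins=cfg.score.n_bins,
                                     n_ctrl=cfg.score.n_ctrl, seed=cfg.seed)
    strata, result = survival_mod.km_by_score(scores, clinical)
    curves = pd.concat(
        [c.assign(group=g) for g, c in result.curves.items()],
        ignore_index=True)
    io.write_table(curves, ws.path("survive/km_curves.tsv"), "survive",
                   index=False)
    io.write_json({"chi2": result.chi2, "p": result.p,
                   "n_high": int((strata == "high").sum()),
                   "n_low": int((strata == "low").sum())},
                  ws.path("survive/logrank.json"), "survive")


def _stage_proteomics(ws: Workspace) -> None:
    cfg = ws.cfg
    raw = ws.proteomics_raw
    drop = [s for s in cfg.proteomics.drop_samples if s in raw.columns]
    raw = raw.drop(columns=drop)
    processed = proteomics.normalize_log2(raw)
    imputed = proteomics.impute_downshift(
        processed, shift_sd=cfg.proteomics.shift_sd,
        width_frac=cfg.proteomics.width_frac, seed=cfg.seed)
    params = dataclasses.asdict(cfg.proteomics)
    io.write_table(imputed.values, ws.path("proteomics/processed.tsv"),
                   "proteomics", params)
    io.write_table(imputed.mask, ws.path("proteomics/mask.tsv"), "proteomics",
                   params)
    screen = proteomics.pca_outlier_screen(imputed)
    io.write_table(screen, ws.path("proteomics/pca_screen.tsv"), "proteomics",
                   params, index=False)
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in raw.columns})
    ga, gb = cfg.sim.group_names[0], cfg.sim.group_names[-1]
    de = proteomics.protein_de(imputed, groups, ga, gb)
    io.write_table(de, ws.path("proteomics/protein_de.tsv"), "proteomics",
                   params, index=False)


@dataclass
class Stage:
    name: str
    deps: tuple[str, ...]
    outputs: Callable[[PipelineConfig], list[str]]
    run: Callable[[Workspace], None]


def _de_outputs(cfg: PipelineConfig) -> list[str]:
    return [f"de/de_{a}_vs_{b}.tsv" for a, b in _pairs(cfg)]


STAGES: list[Stage] = [
    Stage("simulate", (), lambda c: [
        "sim/matrix.mtx", "sim/barcodes.tsv", "sim/features.tsv",
        "sim/metadata.tsv", "sim/barcode_qc.tsv", "sim/truth_barcodes.tsv",
        "sim/truth_de_genes.tsv", "sim/cnv_states.tsv", "sim/cnv_metadata.tsv",
        "sim/truth_amplified_genes.tsv", "sim/label_transfer.tsv",
        "sim/survival_clinical.tsv", "sim/survival_expression.tsv",
        "sim/signatures.gmt", "sim/proteomics_raw.tsv",
        "sim/proteomics_truth_mask.tsv"], _stage_simulate),
    Stage("qc", ("simulate",), lambda c: [
        "qc/decisions.tsv", "qc/thresholds.json"], _stage_qc),
    Stage("markers", ("simulate", "qc"), lambda c: ["markers/markers.tsv"],
          _stage_markers),
    Stage("score", ("simulate", "qc"), lambda c: [
        "score/scores.tsv", "score/responder_composition.tsv",
        "score/responder_proportions.tsv"], _stage_score),
    Stage("pseudobulk", ("simulate", "qc"), lambda c: [
        "pseudobulk/pseudobulk.tsv", "pseudobulk/sample_groups.tsv"],
          _stage_pseudobulk),
    Stage("de", ("pseudobulk",), _de_outputs, _stage_de),
    Stage("composition", ("simulate", "qc"),
          lambda c: ["composition/composition.tsv",
                     "composition/proportions.tsv"], _stage_composition),
    Stage("cnv", ("simulate", "de"), lambda c: [
        "cnv/burden.tsv", "cnv/embedding.tsv", "cnv/centroid_test.json",
        "cnv/diffamps_mean.tsv", "cnv/diffamps_count_amp.tsv",
        "cnv/diffamps_count_del.tsv", "cnv/candidates.txt"], _stage_cnv),
    Stage("subtype", ("simulate",), lambda c: ["subtype/subtype_calls.tsv"],
          _stage_subtype),
    Stage("xspecies", (), lambda c: [
        "xspecies/score_matrix.tsv", "xspecies/correlation.tsv",
        "xspecies/clustering.json"], _stage_xspecies),
    Stage("survive", ("simulate",), lambda c: [
        "survive/km_curves.tsv", "survive/logrank.json"], _stage_survive),
    Stage("proteomics", ("simulate",), lambda c: [
        "proteomics/processed.tsv", "proteomics/mask.tsv",
        "proteomics/pca_screen.tsv", "proteomics/protein_de.tsv"],
          _stage_proteomics),
]


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    force: bool = False,
    stages: list[str] | None = None,
) -> dict:
    """Run (or resume) the pipeline; returns the provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ws = Workspace(cfg, outdir)
    selected = set(stages) if stages else {s.name for s in STAGES}
    unknown = selected - {s.name for s in STAGES}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ran: dict[str, bool] = {}
    manifest: dict = {
        "version": __version__, "seed": cfg.seed, "stages": {}}
    for stage in STAGES:
        if stage.name not in selected:
            ran[stage.name] = False
            continue
        outputs = [ws.path(rel) for rel in stage.outputs(cfg)]
        missing = [p for p in outputs if not p.exists()]
        needs_run = force or bool(missing) or any(
            ran.get(dep, False) for dep in stage.deps)
        if needs_run:
            stage.run(ws)
        ran[stage.name] = needs_run
        manifest["stages"][stage.name] = {
            "ran": needs_run,
            "outputs": io.hash_outputs(
                [str(p) for p in outputs if p.exists()], str(outdir)),
        }
    io.write_json(manifest, outdir / "manifest.json", "run",
                  {"seed": cfg.seed})
    return manifest
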