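"""Configuration objects for the simulator and the pipeline.

``SimConfig`` fixes the statistical structure of every synthetic input: the
grouped replicate design (default 4 TKO + 3 DKOAA + 3 DKO animals), barcode
contamination rates, planted CNV amplifications with between-replicate
heterogeneity, planted expression/compositional effects, the survival-hazard
link, and proteomics missingness.  ``PipelineConfig`` bundles a ``SimConfig``
with the per-stage analysis parameters so a whole run is reproducible from a
single YAML file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (("TKO", 4), ("DKOAA", 3), ("DKO", 3))

#: cell types used by the composition simulator; "Malignant" hosts the planted
#: expression effects, "Osteoclast" hosts the planted compositional shift.
DEFAULT_COMPOSITION: dict[str, tuple[float, ...]] = {
    "Malignant": (0.50, 0.50, 0.50),
    "Osteoclast": (0.30, 0.15, 0.03),
    "Fibroblast": (0.15, 0.30, 0.42),
    "Macrophage": (0.05, 0.05, 0.05),
}


def _as_dict(value, groups, default):
    """Normalize a scalar-or-mapping per-group parameter to a plain dict."""
    names = [g for g, _ in groups]
    if value is None:
        value = default
    if isinstance(value, Mapping):
        missing = set(names) - set(value)
        if missing:
            raise ValueError(f"per-group parameter missing groups: {sorted(missing)}")
        return {g: float(value[g]) for g in names}
    return {g: float(value) for g in names}


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic study.

    Fractions are in [0, 1]; per-group composition vectors must sum to 1.
    """

    seed: int = 0
    n_genes: int = 2000
    groups: Sequence[tuple[str, int]] = DEFAULT_GROUPS
    cells_per_sample: int = 300

    # barcode QC structure
    frac_low_complexity: float = 0.05
    frac_high_mito: float = 0.05
    umi_meanlog: float = 8.0
    umi_sdlog: float = 0.6
    profile_exponent: float = 1.2
    n_mito_genes: int = 13
    n_hemoglobin_genes: int = 4

    # CNV structure
    n_cnv_genes: int = 120
    n_amplified_genes: int = 10
    amp_cell_fraction: Mapping[str, float] | float | None = None
    replicate_dispersion: Mapping[str, float] | float | None = None
    cnv_background_mild: float = 0.02
    cnv_background_extreme: float = 0.0025

    # expression effects
    n_de_genes: int = 50
    de_log2fc: float = 2.0

    # composition: cell type -> per-group proportion vector
    composition_shift: Mapping[str, Sequence[float]] | None = None

    # survival
    survival_effect: float = 1.0986122886681098  # log(3) hazard per unit score
    survival_n_patients: int = 200
    survival_n_genes: int = 500
    survival_baseline_hazard: float = 0.1
    survival_censor_rate: float = 0.025
    signature_size: int = 50

    # proteomics
    n_proteins: int = 1500
    n_de_proteins: int = 100
    protein_shift: float = 3.0
    protein_noise_sd: float = 0.3
    proteomics_missing_rate: float = 0.2

    def __post_init__(self) -> None:
        self.groups = tuple((str(g), int(n)) for g, n in self.groups)
        self.amp_cell_fraction = _as_dict(
            self.amp_cell_fraction, self.groups,
            {g: (0.5 if i < len(self.groups) - 1 else 0.05)
             for i, (g, _) in enumerate(self.groups)},
        )
        self.replicate_dispersion = _as_dict(
            self.replicate_dispersion, self.groups, 0.02)
        if self.composition_shift is None:
            if len(self.groups) == 3:
                self.composition_shift = {
                    k: tuple(v) for k, v in DEFAULT_COMPOSITION.items()}
            else:
                p = 1.0 / 2
                self.composition_shift = {
                    "Malignant": tuple(p for _ in self.groups),
                    "Stroma": tuple(p for _ in self.groups),
                }
        else:
            self.composition_shift = {
                str(k): tuple(float(x) for x in v)
                for k, v in self.composition_shift.items()}
        self.validate()

    def validate(self) -> None:
        for name in ("frac_low_complexity", "frac_high_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.proteomics_missing_rate < 1.0:
            raise ValueError("proteomics_missing_rate must be in [0, 1)")
        if self.frac_low_complexity + self.frac_high_mito > 1.0:
            raise ValueError("contamination fractions exceed 1 in total")
        for c in (self.n_genes, self.cells_per_sample, self.n_cnv_genes,
                  self.n_proteins, self.survival_n_patients):
            if int(c) != c or c <= 0:
                raise ValueError("counts must be positive integers")
        for g, frac in self.amp_cell_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"amp_cell_fraction[{g}] outside [0, 1]")
        for g, d in self.replicate_dispersion.items():
            if d < 0:
                raise ValueError(f"replicate_dispersion[{g}] negative")
        n_groups = len(self.groups)
        for unit, vec in self.composition_shift.items():
            if len(vec) != n_groups:
                raise ValueError(
                    f"composition vector for {unit} has wrong length")
        import numpy as np
        colsums = np.sum([v for v in self.composition_shift.values()], axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("per-group composition proportions must sum to 1")
        if self.n_amplified_genes > self.n_cnv_genes:
            raise ValueError("more planted CNV genes than CNV genes")

    @property
    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g, n in self.groups for i in range(n)}


@dataclass
class QCParams:
    """Parameters of the per-sample barcode filter."""

    span: float = 0.75
    degree: int = 2
    loess_cut: float = -4.0
    cooks_multiplier: float = 4.0
    min_umi: float = 1000.0
    min_genes: float = 200.0
    max_pct_mito: float = 25.0
    max_pct_hemoglobin: float = 25.0
    mad_k: float = 2.5
    mad_scale: float = 1.4826
    mito_prefix: str = "mt-"
    hemoglobin_regex: str = "^Hb[ab]"


@dataclass
class ScoreParams:
    n_bins: int = 24
    n_ctrl: int = 100


@dataclass
class CNVParams:
    n_features: int = 1000
    n_components: int = 10
    alpha: float = 0.1
    exact: bool = True


@dataclass
class ProteomicsParams:
    shift_sd: float = 2.0
    width_frac: float = 0.3
    drop_samples: tuple[str, ...] = ()


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = None  # type: ignore[assignment]
    qc: QCParams = field(default_factory=QCParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    cnv: CNVParams = field(default_factory=CNVParams)
    proteomics: ProteomicsParams = field(default_factory=ProteomicsParams)

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)


_SECTION_TYPES = {
    "sim": SimConfig,
    "qc": QCParams,
    "score": ScoreParams,
    "cnv": CNVParams,
    "proteomics": ProteomicsParams,
}


def _build_section(cls, payload: Mapping) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML, rejecting unknown keys."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    known = {"seed"} | set(_SECTION_TYPES)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(payload.get("seed", 0))
    sections = {}
    for key, cls in _SECTION_TYPES.items():
        block = dict(payload.get(key, {}) or {})
        if key == "sim":
            block.setdefault("seed", seed)
        sections[key] = _build_section(cls, block)
    return PipelineConfig(seed=seed, **sections)


def config_to_yaml(cfg: PipelineConfig, path) -> None:
    payload = {"seed": cfg.seed}
    for key in _SECTION_TYPES:
        block = dataclasses.asdict(getattr(cfg, key))
        if key == "sim":
            block["groups"] = [list(g) for g in block["groups"]]
            block["composition_shift"] = {
                k: list(v) for k, v in block["composition_shift"].items()}
        if key == "proteomics":
            block["drop_samples"] = list(block["drop_samples"])
        payload[key] = block
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
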