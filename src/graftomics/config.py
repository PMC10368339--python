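"""Configuration objects for the simulator and the end-to-end pipeline.

``SimConfig`` is the *stated world* of the synthetic data: three biological
replicates per condition, lognormal pile-up noise around a planted fold of
at least 2x, Poisson read depth over cytosine sites, negative-binomial
RNA counts, and small planted fractions of affected genes/sites.  All
knobs are explicit so that every downstream caller can be scored against
the planted truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

MARKS = ("H3K4me3", "H3K27me3")
CONDITIONS = ("control", "grafted")
TIMEPOINTS = ("D0", "D3")


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omic experiment.

    Defaults mirror the experimental design being emulated: 3 biological
    replicates per condition, a planted chip effect comfortably above the
    2x classification threshold, ~20x sequencing depth per site, and
    planted expression folds at twice the 2x fold-change cut so that
    sampling noise does not straddle the threshold.
    """

    n_genes: int = 200
    gene_length_bp: int = 1000
    intergenic_bp: int = 500
    gc_fraction: float = 0.38          # tomato-like genomic GC
    n_replicates: int = 3
    # ChIP
    chip_effect_fold: float = 3.0      # planted fold for hyper genes (>= 2)
    chip_noise_cv: float = 0.2         # lognormal CV of replicate pile-ups
    chip_base_mean: float = 50.0       # mean pile-up of an unaffected gene
    chip_base_sigma: float = 0.5       # lognormal sigma of per-gene base level
    frac_hyper: float = 0.025          # fraction of genes planted hyper per mark
    frac_hypo: float = 0.005
    # methylome
    methylation_rate: float = 0.3      # per-cytosine prior P(methylated)
    dmp_rate: float = 0.002            # fraction of cytosine sites flipping state
    depth_mean: float = 20.0           # Poisson depth per site per replicate
    error_rate: float = 0.0            # per-read base miscall probability
    # expression
    deg_fold: float = 4.0              # planted expression fold for up genes
    frac_up: float = 0.05
    frac_down: float = 0.05
    count_base_mean: float = 500.0
    count_base_sigma: float = 1.0
    nb_dispersion: float = 0.1         # NB: var = m + a m^2 ; 0 -> Poisson
    # qPCR
    qpcr_ct_sd: float = 0.2
    qpcr_ref_ct: float = 15.0
    # cohorts: the drought-recovery experiment being emulated
    cohort_sizes: dict = field(
        default_factory=lambda: {"control": 30, "grafted": 16, "pre4d": 30, "pre7d": 30}
    )
    cohort_survival: dict = field(
        default_factory=lambda: {"control": 0.2, "grafted": 0.5625, "pre4d": 0.0, "pre7d": 0.0}
    )
    axillary_fraction: float = 0.23    # P(route = axillary | survivor)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if self.gene_length_bp < 100:
            raise ConfigError("gene_length_bp must be >= 100")
        if self.intergenic_bp < 0:
            raise ConfigError("intergenic_bp must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.chip_effect_fold < 2.0:
            raise ConfigError(
                "chip_effect_fold must be >= 2 so planted effects clear the 2x threshold"
            )
        if self.chip_noise_cv < 0:
            raise ConfigError("chip_noise_cv must be >= 0")
        for name in ("frac_hyper", "frac_hypo", "frac_up", "frac_down",
                     "methylation_rate", "dmp_rate", "error_rate", "axillary_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_hyper + self.frac_hypo > 1.0:
            raise ConfigError("frac_hyper + frac_hypo must not exceed 1")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigError("frac_up + frac_down must not exceed 1")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.deg_fold < 2.0:
            raise ConfigError("deg_fold must be >= 2 so planted DEGs clear the 2x threshold")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        for grp, p in self.cohort_survival.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"cohort survival probability for {grp!r} must lie in [0, 1]")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunConfig:
    """Thresholds and paths for the end-to-end pipeline.

    Threshold defaults are the printed analysis settings being reproduced:
    per-gene p < 0.001 for histone enrichment, |fold| >= 2 for both
    enrichment and expression, expression filter at RPKM > 10, one DMP to
    qualify a gene as differentially methylated, and p < 0.05 for term
    enrichment.
    """

    outdir: str = "graftomics_run"
    sim: SimConfig = field(default_factory=SimConfig)
    alpha: float = 0.001
    fold_cut: float = 2.0
    min_rpkm: float = 10.0
    dmg_k: int = 1
    enrichment_alpha: float = 0.05
    min_depth: int = 5
    min_fraction: float = 0.9
    flank_bp: int = 0
    pseudocount: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("alpha", "fold_cut", "min_rpkm", "enrichment_alpha", "min_fraction"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dmg_k < 1:
            raise ConfigError("dmg_k must be >= 1")
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if self.flank_bp < 0:
            raise ConfigError("flank_bp must be >= 0")

    @property
    def seed(self) -> int:
        return self.sim.seed

    def thresholds(self) -> dict:
        return {
            "alpha": self.alpha,
            "fold_cut": self.fold_cut,
            "min_rpkm": self.min_rpkm,
            "dmg_k": self.dmg_k,
            "enrichment_alpha": self.enrichment_alpha,
            "min_depth": self.min_depth,
            "min_fraction": self.min_fraction,
            "flank_bp": self.flank_bp,
            "pseudocount": self.pseudocount,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    sim_raw = raw.pop("sim", {}) or {}
    known_sim = {f.name for f in dataclasses.fields(SimConfig)}
    known_run = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    bad = (set(sim_raw) - known_sim) | (set(raw) - known_run)
    if bad:
        raise ConfigError(f"{path}: unknown configuration keys: {sorted(bad)}")
    try:
        sim = SimConfig(**sim_raw)
        return RunConfig(sim=sim, **raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
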