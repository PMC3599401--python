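"""Configuration objects for the synthetic study and the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic DMH study.

    The defaults emulate the cohort the analysis was designed for: 19
    right-sided colon tumors with paired normals, 11 BRAF-wildtype and 8
    BRAF-V600E-mutant, 11 CIMP-positive and 8 CIMP-negative, with the
    mutation and the methylator phenotype co-occurring in the 8 mutants.
    Effects are log2 tumor/normal units.
    """

    seed: int = 0

    # genome
    genome_length: int = 1_000_000          # bp, total across chromosomes
    n_chromosomes: int = 2
    cpg_island_density: float = 60.0        # islands per Mbp
    at_fraction: float = 0.50               # background AT content; sets MseI site density
    island_length_mean: int = 600           # bp

    # cohort
    n_wildtype: int = 11                    # BRAF wildtype tumors
    n_mutant: int = 8                       # BRAF V600E tumors
    n_cimp_pos: int = 11                    # CIMP-positive tumors (mutants first)

    # array design
    probe_length_min: int = 45
    probe_length_max: int = 60
    max_probes_per_fragment: int = 33
    decoy_fraction: float = 0.05            # boundary-spanning probes

    # planted effects
    n_tumor_dmr: int = 150                  # tumor-vs-normal regions
    n_group_dmr: int = 100                  # per group contrast (CIMP, BRAF)
    dmr_shared_fraction: float = 0.5        # CIMP/BRAF overlap, mirroring co-occurrence
    dmr_effect: float = 0.8                 # group-specific effect
    tumor_effect: float = 1.0               # tumor-vs-normal effect
    tumor_positive_fraction: float = 0.8    # hypermethylated share of tumor regions
    group_positive_fraction: float = 0.95   # hypermethylated share of group regions

    # measurement model
    noise_sd: float = 0.2                   # per-probe log2 noise
    dye_bias_sd: float = 0.1                # per-probe additive dye bias
    curvature_amp: float = 0.2              # amplitude of the cubic M~A trend
    a_mean: float = 10.0                    # lower edge of the log2 intensity distribution
    a_spread: float = 4.0                   # span of the (right-skewed) A distribution
    a_jitter: float = 0.0                   # optional per-array spread around the probe affinity

    # copy-number losses (concentrated in BRAF wildtypes)
    cn_loss_fraction: float = 0.7           # fraction of wildtype samples with losses
    cn_loss_log2: float = -0.26             # expected log2 shift over lost regions
    cn_loss_sd: float = 0.12                # per-region spread of the shift
    cn_loss_genome_fraction: tuple[float, float] = (0.05, 0.20)

    # chromatin tracks: odds ratio of track membership for planted group DMRs
    track_odds: dict[str, float] = field(
        default_factory=lambda: {
            "SUZ12": 3.0, "H3K27me3": 3.0, "CTCF": 0.5, "H3K4me3": 0.5,
        }
    )
    track_background_rate: float = 0.12     # membership rate for unplanted fragments

    # marker panel / bisulfite
    marker_ambiguous_fraction: float = 0.0
    bisulfite_genes: int = 2
    bisulfite_n_cpgs: int = 20
    bisulfite_delta: float = 25.0           # % methylation gain in mutant tumors
    bisulfite_nd_fraction: float = 0.05     # missing (not-detected) cells
    normal_meth_max: float = 8.0            # % methylation ceiling in normals

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_length < 100_000:
            raise ValueError("genome_length must be at least 100 kbp")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for name in ("noise_sd", "dye_bias_sd", "curvature_amp", "cn_loss_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cpg_island_density < 0:
            raise ValueError("cpg_island_density must be >= 0")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if not 0 <= self.cn_loss_fraction <= 1:
            raise ValueError("cn_loss_fraction must be in [0, 1]")
        if self.n_wildtype < 1 or self.n_mutant < 1:
            raise ValueError("need at least one sample per BRAF group")
        if not self.n_mutant <= self.n_cimp_pos <= self.n_samples:
            raise ValueError(
                "n_cimp_pos must cover all mutants and fit the cohort "
                f"(got {self.n_cimp_pos} for {self.n_samples} samples)"
            )

    @property
    def n_samples(self) -> int:
        return self.n_wildtype + self.n_mutant


#: Per-module tunables of the analysis itself, with the thresholds the
#: method prescribes: informative fragments of 150-3,000 bp, FDR <= 0.01,
#: >= 20 bp chromatin overlap, promoter window TSS -2,000/+500.
ANALYSIS_DEFAULTS: dict[str, Any] = {
    "loess_span": 0.3,
    "robustness_iters": 4,
    "min_fragment_length": 150,
    "max_fragment_length": 3000,
    "fdr_threshold": 0.01,
    "min_overlap_bp": 20,
    "promoter_upstream": 2000,
    "promoter_downstream": 500,
}

_PIPELINE_KEYS = {
    "seed", "output_dir", "simulate", "genome_fasta", "probe_table",
    "scan_table", "steps", "simulation", "analysis",
}
_STEP_NAMES = (
    "simulate", "digest", "normalize", "test", "annotate", "classify",
    "downstream", "report",
)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    output_dir: Path = Path("dmh_run")
    simulate: bool = True
    genome_fasta: Path | None = None
    probe_table: Path | None = None
    scan_table: Path | None = None
    steps: dict[str, bool] = field(
        default_factory=lambda: {name: True for name in _STEP_NAMES}
    )
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: dict[str, Any] = field(default_factory=lambda: dict(ANALYSIS_DEFAULTS))

    def validate(self) -> list[str]:
        """Return a list of problems; empty means valid."""
        errors = []
        if not self.simulate:
            for attr in ("genome_fasta", "probe_table", "scan_table"):
                if getattr(self, attr) is None:
                    errors.append(f"simulation disabled but {attr} not provided")
        unknown = set(self.steps) - set(_STEP_NAMES)
        if unknown:
            errors.append(f"unknown step toggles: {sorted(unknown)}")
        unknown = set(self.analysis) - set(ANALYSIS_DEFAULTS)
        if unknown:
            errors.append(f"unknown analysis keys: {sorted(unknown)}")
        if self.analysis.get("fdr_threshold", 0.01) is not None:
            fdr = self.analysis["fdr_threshold"]
            if not 0 < fdr <= 1:
                errors.append(f"fdr_threshold must be in (0, 1], got {fdr}")
        span = self.analysis.get("loess_span", 0.3)
        if not 0 < span <= 1:
            errors.append(f"loess_span must be in (0, 1], got {span}")
        try:
            self.simulation.validate()
        except ValueError as exc:
            errors.append(str(exc))
        return errors


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys are rejected; missing keys take defaults.  Raises
    ``ValueError`` listing every problem found.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    unknown = set(raw) - _PIPELINE_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_raw = raw.pop("simulation", {})
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim_raw) - sim_fields
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    if "cn_loss_genome_fraction" in sim_raw:
        sim_raw["cn_loss_genome_fraction"] = tuple(sim_raw["cn_loss_genome_fraction"])
    analysis = dict(ANALYSIS_DEFAULTS)
    analysis.update(raw.pop("analysis", {}))
    cfg = PipelineConfig(
        seed=raw.get("seed", 0),
        output_dir=Path(raw.get("output_dir", "dmh_run")),
        simulate=raw.get("simulate", True),
        genome_fasta=Path(raw["genome_fasta"]) if raw.get("genome_fasta") else None,
        probe_table=Path(raw["probe_table"]) if raw.get("probe_table") else None,
        scan_table=Path(raw["scan_table"]) if raw.get("scan_table") else None,
        steps={**{name: True for name in _STEP_NAMES}, **raw.get("steps", {})},
        simulation=SimulationConfig(seed=raw.get("seed", 0), **sim_raw)
        if "seed" not in sim_raw
        else SimulationConfig(**sim_raw),
        analysis=analysis,
    )
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid pipeline config:\n" + "\n".join(f"- {e}" for e in errors))
    return cfg
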