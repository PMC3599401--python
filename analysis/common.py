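"""Shared plumbing for the numbered analysis drivers.

Each driver operates on one run directory (default results/run) driven
by one seed, so the whole analysis is reproducible end to end.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from dmh.config import PipelineConfig, SimulationConfig

#: study conditions of the main analysis run: a 19-patient dye-swap
#: cohort (11 BRAF wildtype / 8 mutant, 11 CIMP-positive) on a 1 Mbp
#: two-chromosome genome, ~100 tumor and 80 per-group planted regions
STUDY = dict(genome_length=1_000_000, n_chromosomes=2,
             n_tumor_dmr=100, n_group_dmr=80)


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--dir", type=Path, default=Path("results/run"))
    return parser.parse_args()


def pipeline_config(seed: int, run_dir: Path) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed, output_dir=run_dir)
    cfg.simulation = SimulationConfig(seed=seed, **STUDY)
    return cfg
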