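"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dmh.config import SimulationConfig
from dmh import normalize, simulate


def informative_probe_map(study: simulate.SyntheticStudy) -> pd.DataFrame:
    """Probe -> fragment map restricted to informative fragments."""
    ids = {f.id for f in study.informative}
    pm = study.probes.rename(columns={"true_fragment_id": "fragment_id"})
    pm = pm[pm["fragment_id"].isin(ids)]
    return pm[["probe_id", "fragment_id"]]


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, genome_length=300_000, n_chromosomes=2,
        n_tumor_dmr=40, n_group_dmr=30,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> simulate.SyntheticStudy:
    return simulate.simulate_study(small_config)


@pytest.fixture(scope="session")
def noisefree_study() -> simulate.SyntheticStudy:
    cfg = SimulationConfig(
        seed=13, genome_length=300_000, n_chromosomes=2,
        n_tumor_dmr=40, n_group_dmr=30,
        noise_sd=0.0, cn_loss_fraction=0.0,
    )
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def normalized_small(small_study):
    """NormalizedMatrix of the small noisy study."""
    return normalize.normalize_experiment(
        small_study.scans, informative_probe_map(small_study)
    )
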