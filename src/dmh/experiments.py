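"""Benchmark experiments on synthetic studies.

These are the package's standing validation experiments: reproducing the
published chromatin-mark contingency tests from their printed tables,
measuring planted-region recovery and false discovery control of the
moderated-t pipeline on synthetic cohorts, checking null calibration,
and quantifying normalization recovery error.  Both the test suite and
the acceptance script drive these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffmeth, normalize, simulate
from .annotation import enrichment_chi_squared
from .config import SimulationConfig

#: Published 2x2 overlap tables (overlap count, set size) for selected
#: regions vs the remaining informative regions, with the P-value printed
#: alongside them.  These tables are inputs: the test recomputes P.
PUBLISHED_TABLES = {
    "tumor_h3k4me3": ((711, 1770, 13_835, 30_401), 0.000012),
    "cimp_ctcf": ((183, 749, 10_333, 31_422), 0.000001),
    "braf_ctcf": ((195, 758, 10_321, 31_413), 0.000035),
}


def published_chi_squared_pvalues() -> dict[str, float]:
    """Recompute the printed chi-squared P-values from their 2x2 tables."""
    return {
        name: enrichment_chi_squared(*counts)[1]
        for name, (counts, _) in PUBLISHED_TABLES.items()
    }


def _probe_map(study: simulate.SyntheticStudy) -> pd.DataFrame:
    ids = {f.id for f in study.informative}
    pm = study.probes.rename(columns={"true_fragment_id": "fragment_id"})
    return pm[pm["fragment_id"].isin(ids)][["probe_id", "fragment_id"]]


def recovery_config(seed: int) -> SimulationConfig:
    """Study conditions of the planted-recovery experiment.

    The cohort mirrors the published design (11 vs 8 samples, group
    effect 0.8 log2); copy-number losses are disabled because the
    experiment measures the testing machinery alone — the loss confound
    is exercised separately through the copy-number filter.
    """
    return SimulationConfig(
        seed=seed,
        genome_length=1_200_000,
        n_chromosomes=2,
        n_tumor_dmr=100,
        n_group_dmr=80,
        dmr_effect=0.8,
        cn_loss_fraction=0.0,
    )


@dataclass
class RecoveryResult:
    n_fragments: int
    n_selected: int
    sensitivity: float          # on planted group-effect fragments
    observed_fdr: float         # against the true group-mean difference
    positive_fraction: float    # sign of selected effects


def recovery_experiment(
    seed: int, contrast: str = "braf", fdr_threshold: float = 0.01
) -> RecoveryResult:
    """Simulate, normalize and test one cohort; score against the truth.

    Ground truth for a two-group contrast is the true between-group mean
    difference of the noiseless methylation matrix: regions planted for
    the *other* group contrast genuinely differ between these groups too
    (the phenotypes co-occur), so they are neither false positives nor
    counted for sensitivity.
    """
    cfg = recovery_config(seed)
    study = simulate.simulate_study(cfg)
    matrix = normalize.normalize_experiment(study.scans, _probe_map(study))
    samples = study.truth.samples
    res = diffmeth.run_contrast(matrix, samples, contrast, fdr_threshold)

    group_col = "braf" if contrast == "braf" else "cimp"
    group_val = "mutant" if contrast == "braf" else "positive"
    in_group = samples[group_col].eq(group_val).to_numpy()
    truth = study.true_m
    true_diff = (
        truth.loc[:, in_group].mean(axis=1) - truth.loc[:, ~in_group].mean(axis=1)
    )
    eff_col = f"{'braf' if contrast == 'braf' else 'cimp'}_effect"
    planted = study.truth.fragment_effects.set_index("fragment_id")[eff_col]

    res = res.set_index("fragment_id")
    sel = res.index[res["selected"]]
    planted_ids = planted.index[planted != 0]
    sensitivity = len(set(sel) & set(planted_ids)) / len(planted_ids)
    null_ids = set(true_diff.index[true_diff.abs() < 1e-9])
    n_false = len(set(sel) & null_ids)
    observed_fdr = n_false / max(1, len(sel))
    positive_fraction = float((res.loc[sel, "effect"] > 0).mean()) if len(sel) else np.nan
    return RecoveryResult(
        n_fragments=len(res),
        n_selected=int(len(sel)),
        sensitivity=float(sensitivity),
        observed_fdr=float(observed_fdr),
        positive_fraction=positive_fraction,
    )


def null_calibration(
    seeds: list[int],
    n_fragments: int = 2000,
    n_wildtype: int = 11,
    n_mutant: int = 8,
    noise_sd: float = 0.15,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Selected fraction per seed on matrices with no planted effects.

    Matrices of pure Gaussian noise at the fragment level stand in for a
    cohort without any differential methylation; the moderated pipeline
    should then select (on average) no more than the nominal fraction.
    """
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n_wildtype + n_mutant)],
            "braf": ["mutant"] * n_mutant + ["wildtype"] * n_wildtype,
            "cimp": ["positive"] * n_mutant + ["negative"] * n_wildtype,
        }
    )
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        y = rng.normal(0.0, noise_sd, (n_fragments, len(samples)))
        matrix = pd.DataFrame(y, index=[f"f{i}" for i in range(n_fragments)],
                              columns=samples["sample_id"])
        res = diffmeth.run_contrast(matrix, samples, "braf", fdr_threshold)
        rows.append({"seed": seed, "selected_fraction": res["selected"].mean()})
    return pd.DataFrame(rows)


def normalization_recovery(seed: int) -> dict[str, float]:
    """Recovery error of the preprocessing chain on noise-free scans.

    Returns the max absolute error of the full pipeline (LOESS +
    aquantile + dye swap + median) against the true matrix with dye bias
    and curvature planted, and of the dye-swap combination alone with
    curvature off (which must cancel the dye bias exactly).
    """
    cfg = SimulationConfig(
        seed=seed, genome_length=1_000_000, n_chromosomes=2,
        n_tumor_dmr=80, n_group_dmr=60, noise_sd=0.0, cn_loss_fraction=0.0,
    )
    study = simulate.simulate_study(cfg)
    matrix = normalize.normalize_experiment(study.scans, _probe_map(study))
    err = (matrix - study.true_m.loc[matrix.index]).abs()
    full_pipeline_max = float(err.stack().max())

    cfg_flat = SimulationConfig(
        seed=seed + 1, genome_length=300_000, n_chromosomes=1,
        n_tumor_dmr=30, n_group_dmr=20, noise_sd=0.0, curvature_amp=0.0,
        cn_loss_fraction=0.0,
    )
    study_flat = simulate.simulate_study(cfg_flat)
    matrix_flat = normalize.normalize_experiment(
        study_flat.scans, _probe_map(study_flat), loess=False, aquantile=False
    )
    err_flat = (matrix_flat - study_flat.true_m.loc[matrix_flat.index]).abs()
    dye_swap_max = float(err_flat.stack().max())
    return {
        "full_pipeline_max_error": full_pipeline_max,
        "dye_swap_max_error": dye_swap_max,
    }
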