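"""Synthetic DMH study generator.

Builds a complete, fully specified stand-in for a two-color CpG-island
methylation array study with known ground truth: a genome with CpG
islands and restriction sites, an oligonucleotide array designed against
the MseI fragments, a tumor/normal cohort with planted tumor-, CIMP- and
BRAF-specific methylation differences and copy-number losses, dye-swap
scan pairs with probe-level dye bias and intensity-dependent curvature,
chromatin-mark tracks correlated with the planted regions, a CIMP marker
panel, and per-CpG bisulfite tables.

Everything is driven by a single seed; identical configuration and seed
produce byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SimulationConfig
from .digestion import (
    Fragment,
    attach_probes,
    digest_genome,
    fragments_to_frame,
    map_probes,
    Probe,
    probes_to_frame,
    select_informative_fragments,
)

logger = logging.getLogger(__name__)

TRACK_NAMES = ("SUZ12", "H3K27me3", "CTCF", "H3K4me3")

CIMP1_MARKERS = ("BRAF_mut", "MLH1_meth", "TIMP3_meth", "MINT1_meth", "PRDM2_meth")
CIMP2_MARKERS = ("KRAS_mut", "MINT27_meth", "MINT2_meth", "MINT31_meth", "LRP2_meth")
NEGATIVE_MARKERS = (
    "TP53_mut", "MINT27_unmeth", "MINT2_unmeth", "MINT31_unmeth", "MINT1_unmeth",
)

# shape parameters of the right-skewed intensity distribution
A_BETA_SHAPE = (2.0, 5.0)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study.

    ``fragment_effects`` has one row per informative fragment with the
    planted per-contrast log2 effects; ``samples`` records group
    membership; ``cn_intervals`` lists per-sample copy-number losses;
    ``track_membership`` flags per-fragment chromatin-mark membership.
    """

    fragment_effects: pd.DataFrame
    samples: pd.DataFrame
    cn_intervals: pd.DataFrame
    track_membership: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    genome: dict[str, str]
    islands: pd.DataFrame
    fragments: list[Fragment]             # all fragments, pre-filter
    informative: list[Fragment]
    probes: pd.DataFrame
    true_m: pd.DataFrame                  # informative fragments x samples
    truth: SyntheticTruth
    scans: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    gene_sets: dict[str, set[str]]
    markers: pd.DataFrame
    bisulfite: dict[str, dict[str, pd.DataFrame]]


# ---------------------------------------------------------------------------
# genome

def _random_bases(rng: np.random.Generator, n: int, p_at: float) -> np.ndarray:
    probs = [p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a genome with CpG islands and MseI/HpaII/BstUI sites.

    The background composition (``at_fraction``) sets the TTAA density and
    thereby the MseI fragment-length distribution; islands are rewritten
    GC-rich with planted CCGG/CGCG motifs so they carry the
    methylation-sensitive sites the assay requires.  Coordinates are
    0-based half-open.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom_len = config.genome_length // config.n_chromosomes
    n_islands_total = round(config.cpg_island_density * config.genome_length / 1e6)
    if config.cpg_island_density > 0 and n_islands_total == 0:
        raise ValueError(
            "cpg_island_density of "
            f"{config.cpg_island_density} islands/Mbp yields zero islands on a "
            f"{config.genome_length} bp genome"
        )
    genome: dict[str, str] = {}
    island_rows = []
    per_chrom = np.full(config.n_chromosomes, n_islands_total // config.n_chromosomes)
    per_chrom[: n_islands_total % config.n_chromosomes] += 1
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        bases = _random_bases(rng, chrom_len, config.at_fraction)
        # non-overlapping island placement on a coarse grid
        n_isl = int(per_chrom[ci])
        if n_isl > 0:
            slot = chrom_len // n_isl
            for k in range(n_isl):
                length = int(
                    np.clip(rng.normal(config.island_length_mean, 150), 200, slot - 50)
                )
                start = int(slot * k + rng.integers(0, max(1, slot - length)))
                end = start + length
                island = _random_bases(rng, length, p_at=0.3)
                # plant methylation-sensitive motifs through the island
                for pos in range(10, length - 4, 80):
                    motif = b"CCGG" if rng.random() < 0.5 else b"CGCG"
                    island[pos:pos + 4] = np.frombuffer(motif, dtype="S1")
                bases[start:end] = island
                island_rows.append((chrom, start, end, f"island_{chrom}_{k:04d}"))
        genome[chrom] = bases.tobytes().decode("ascii")
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end", "name"])
    return genome, islands


# ---------------------------------------------------------------------------
# array design

def design_array(
    fragments: list[Fragment], config: SimulationConfig
) -> pd.DataFrame:
    """Design probes against MseI fragments.

    Fragments carrying at least one methylation-sensitive site and long
    enough for a probe are targeted with 1-33 probes of 45-60 bp placed
    uniformly inside the fragment (most fragments get 1 or 2).  A
    configurable fraction of decoy probes spans fragment boundaries to
    exercise the complete-probe filter downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    pid = 0
    for frag in fragments:
        if frag.n_sites == 0:
            continue
        if frag.length < config.probe_length_min:
            logger.debug("fragment %s (%d bp) too short for a probe", frag.id, frag.length)
            continue
        cap = min(config.max_probes_per_fragment, max(1, frag.length // 100))
        n_probes = min(int(rng.geometric(0.6)), cap)
        for _ in range(n_probes):
            plen = int(rng.integers(config.probe_length_min, config.probe_length_max + 1))
            if plen > frag.length:
                plen = frag.length
            start = frag.start + int(rng.integers(0, frag.length - plen + 1))
            rows.append((f"probe_{pid:06d}", frag.chrom, start, start + plen, False, frag.id))
            pid += 1
    n_regular = len(rows)
    f = config.decoy_fraction
    n_decoys = round(n_regular * f / (1 - f)) if f > 0 else 0
    boundaries = [
        (fr.chrom, fr.start) for fr in fragments if fr.start > 0
    ]
    for _ in range(n_decoys):
        chrom, cut = boundaries[int(rng.integers(len(boundaries)))]
        plen = int(rng.integers(config.probe_length_min, config.probe_length_max + 1))
        start = max(0, cut - plen // 2)
        rows.append((f"probe_{pid:06d}", chrom, start, start + plen, True, None))
        pid += 1
    return pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "start", "end", "is_decoy", "true_fragment_id"],
    )


# ---------------------------------------------------------------------------
# cohort truth

def make_samples(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: BRAF mutants first, all of them CIMP-positive."""
    rows = []
    for i in range(config.n_samples):
        mutant = i < config.n_mutant
        cimp = i < config.n_cimp_pos
        rows.append((f"S{i + 1:02d}", "mutant" if mutant else "wildtype",
                     "positive" if cimp else "negative"))
    return pd.DataFrame(rows, columns=["sample_id", "braf", "cimp"])


def simulate_methylation_cohort(
    config: SimulationConfig,
    informative: list[Fragment],
    genome_sizes: dict[str, int],
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant true per-fragment, per-sample log2 methylation differences.

    True M is additive: a tumor-vs-normal effect shared by all samples on
    tumor regions, a group effect on CIMP regions in CIMP-positive
    samples and on BRAF regions in mutant samples (the two region lists
    share a configurable fraction, mirroring the co-occurrence of the
    phenotypes), and a negative copy-number shift where a sample carries
    a loss.  Losses are contiguous intervals concentrated in BRAF
    wildtype samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    samples = make_samples(config)
    frag_ids = [f.id for f in informative]
    n_frag = len(frag_ids)
    n_shared = round(config.dmr_shared_fraction * config.n_group_dmr)
    n_needed = config.n_tumor_dmr + 2 * config.n_group_dmr - n_shared
    if n_needed > n_frag:
        raise ValueError(
            f"requested {n_needed} planted regions but only {n_frag} "
            "informative fragments are available"
        )
    perm = rng.permutation(n_frag)
    tumor_idx = perm[: config.n_tumor_dmr]
    rest = perm[config.n_tumor_dmr:]
    shared_idx = rest[:n_shared]
    cimp_only = rest[n_shared: config.n_group_dmr]
    braf_only = rest[config.n_group_dmr: 2 * config.n_group_dmr - n_shared]
    cimp_idx = np.concatenate([shared_idx, cimp_only])
    braf_idx = np.concatenate([shared_idx, braf_only])

    def signs(n: int, positive_fraction: float) -> np.ndarray:
        return np.where(rng.random(n) < positive_fraction, 1.0, -1.0)

    tumor_eff = np.zeros(n_frag)
    tumor_eff[tumor_idx] = config.tumor_effect * signs(
        len(tumor_idx), config.tumor_positive_fraction
    )
    cimp_eff = np.zeros(n_frag)
    cimp_eff[cimp_idx] = config.dmr_effect * signs(
        len(cimp_idx), config.group_positive_fraction
    )
    braf_eff = np.zeros(n_frag)
    braf_eff[braf_idx] = config.dmr_effect * signs(
        len(braf_idx), config.group_positive_fraction
    )

    is_cimp = (samples["cimp"] == "positive").to_numpy()
    is_mut = (samples["braf"] == "mutant").to_numpy()
    m = (
        tumor_eff[:, None]
        + cimp_eff[:, None] * is_cimp[None, :]
        + braf_eff[:, None] * is_mut[None, :]
    )

    # copy-number losses: contiguous intervals in a fraction of wildtypes
    frag_chrom = np.array([f.chrom for f in informative])
    frag_start = np.array([f.start for f in informative])
    frag_end = np.array([f.end for f in informative])
    cn_rows = []
    has_loss = []
    total_len = sum(genome_sizes.values())
    for si, row in samples.iterrows():
        loss = row["braf"] == "wildtype" and rng.random() < config.cn_loss_fraction
        has_loss.append(loss)
        if not loss:
            continue
        lo, hi = config.cn_loss_genome_fraction
        target = rng.uniform(lo, hi) * total_len
        n_intervals = int(rng.integers(2, 5))
        for _ in range(n_intervals):
            chrom = str(rng.choice(list(genome_sizes)))
            length = int(target / n_intervals)
            size = genome_sizes[chrom]
            length = min(length, size - 1)
            start = int(rng.integers(0, size - length))
            cn_rows.append((row["sample_id"], chrom, start, start + length))
            covered = (
                (frag_chrom == chrom)
                & (frag_start >= start)
                & (frag_end <= start + length)
            )
            shift = rng.normal(config.cn_loss_log2, config.cn_loss_sd, covered.sum())
            m[covered, si] += shift
    samples = samples.assign(has_cn_loss=has_loss)

    true_m = pd.DataFrame(m, index=pd.Index(frag_ids, name="fragment_id"),
                          columns=samples["sample_id"].tolist())
    effects = pd.DataFrame(
        {
            "fragment_id": frag_ids,
            "tumor_effect": tumor_eff,
            "cimp_effect": cimp_eff,
            "braf_effect": braf_eff,
        }
    )
    cn_intervals = pd.DataFrame(cn_rows, columns=["sample_id", "chrom", "start", "end"])
    return true_m, SyntheticTruth(effects, samples, cn_intervals)


# ---------------------------------------------------------------------------
# scans

def curvature(a: np.ndarray, amp: float, a_mean: float, a_spread: float) -> np.ndarray:
    """Smooth cubic intensity-dependent trend added to raw log ratios.

    Pivoted at the middle of the intensity range and scaled to its half
    width, so the trend stays within roughly +/- amp over the support of
    the A distribution.
    """
    half = a_spread / 2.0
    return amp * ((a - (a_mean + half)) / half) ** 3


def simulate_array_scans(
    true_m: pd.DataFrame,
    probes: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Emit dye-swap scan pairs for every sample.

    The observed raw log ratio of a probe is the true fragment M in the
    dye orientation of the array, plus a probe-specific additive dye bias
    (shared across arrays, attached to the dye rather than the sample),
    an intensity-dependent cubic trend, and Gaussian noise.  A is mostly
    probe-driven (hybridization affinity is a sequence property): a
    right-skewed per-probe affinity (scaled Beta on a bounded log2
    range) plus a small per-array jitter.  Channel intensities are
    strictly positive by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    probe_ids = probes["probe_id"].to_numpy()
    n_probes = len(probe_ids)
    frag_of_probe = probes["true_fragment_id"].to_numpy()
    dye_bias = rng.normal(0.0, config.dye_bias_sd, n_probes)
    affinity = config.a_spread * rng.beta(*A_BETA_SHAPE, n_probes)

    m_lookup = {fid: i for i, fid in enumerate(true_m.index)}
    frag_row = np.array([m_lookup.get(f, -1) for f in frag_of_probe])
    m_values = true_m.to_numpy()

    frames = []
    for si, sample_id in enumerate(true_m.columns):
        true_probe_m = np.where(frag_row >= 0, m_values[frag_row, si], 0.0)
        for orient_sign, orientation in ((1, "tumor_in_ch1"), (-1, "tumor_in_ch2")):
            array_id = f"{sample_id}_{'fwd' if orient_sign == 1 else 'rev'}"
            a = config.a_mean + affinity + rng.normal(0.0, config.a_jitter, n_probes)
            raw_m = (
                orient_sign * true_probe_m
                + dye_bias
                + curvature(a, config.curvature_amp, config.a_mean, config.a_spread)
                + rng.normal(0.0, config.noise_sd, n_probes)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probe_ids,
                        "array_id": array_id,
                        "sample_id": sample_id,
                        "orientation": orientation,
                        "ch1": 2.0 ** (a + raw_m / 2),
                        "ch2": 2.0 ** (a - raw_m / 2),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# chromatin tracks

def generate_chromatin_tracks(
    informative: list[Fragment],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw chromatin-mark membership per fragment and emit BED tracks.

    Membership is Bernoulli with a background rate for unplanted
    fragments and an odds-ratio-scaled rate for planted (CIMP or BRAF)
    regions: repressive marks (SUZ12, H3K27me3) enriched, active marks
    (CTCF, H3K4me3) depleted by default.  Each member fragment
    contributes one track interval jittered around the fragment but
    overlapping it by well over 20 bp.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    eff = truth.fragment_effects
    planted = ((eff["cimp_effect"] != 0) | (eff["braf_effect"] != 0)).to_numpy()
    p0 = config.track_background_rate
    tracks: dict[str, pd.DataFrame] = {}
    membership = pd.DataFrame({"fragment_id": eff["fragment_id"]})
    for name in TRACK_NAMES:
        odds = config.track_odds.get(name, 1.0)
        p1 = odds * p0 / (1 - p0 + odds * p0)
        member = rng.random(len(eff)) < np.where(planted, p1, p0)
        membership[name] = member
        rows = []
        for frag, is_member in zip(informative, member):
            if not is_member:
                continue
            # jitter stays below the 20 bp overlap threshold so an interval
            # never counts as overlapping a neighbouring fragment
            jitter = int(rng.integers(-19, 20))
            rows.append(
                (frag.chrom, max(0, frag.start + jitter), frag.end + jitter,
                 f"{name}_{frag.id}")
            )
        tracks[name] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return tracks, membership


# ---------------------------------------------------------------------------
# gene annotation and gene sets

def generate_gene_annotation(
    islands: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """One synthetic gene per CpG island, TSS at an island edge."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    rows = []
    for gi, row in islands.iterrows():
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = int(row["end"]) - 100
            start, end = tss, tss + 2000
        else:
            tss = int(row["start"]) + 100
            start, end = max(0, tss - 2000), tss
        rows.append((f"GENE{gi:04d}", row["chrom"], start, end, strand, tss))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand", "tss"])


def generate_gene_sets(
    genes: pd.DataFrame,
    enriched_genes: list[str],
    config: SimulationConfig,
    n_sets: int = 20,
) -> dict[str, set[str]]:
    """GMT collection over the synthetic gene universe.

    One set is seeded with genes hit by planted BRAF regions (so a
    binomial enrichment run has something to find); the rest are random
    draws from the universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    universe = genes["gene"].tolist()
    sets: dict[str, set[str]] = {}
    planted = set(enriched_genes)
    filler = [g for g in universe if g not in planted]
    seed_size = min(len(planted), 8)
    chosen = list(rng.choice(sorted(planted), size=seed_size, replace=False)) if planted else []
    n_pad = min(max(0, 12 - seed_size), len(filler))
    pad = list(rng.choice(filler, size=n_pad, replace=False))
    sets["pathway_planted"] = set(chosen) | set(pad)
    for k in range(n_sets - 1):
        size = min(int(rng.integers(5, 40)), len(universe))
        sets[f"pathway_{k:02d}"] = set(rng.choice(universe, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# marker panels

def generate_marker_panels(samples: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Tri-state CIMP marker panel consistent with each sample's truth.

    CIMP-positive samples receive at least two CIMP1 markers (the BRAF
    mutation itself counts for mutants) or three CIMP2 markers;
    CIMP-negative samples receive at least two negative markers.  A
    configurable fraction of samples is left uninformative (all markers
    unknown) to exercise the undetermined call.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 8]))
    all_markers = CIMP1_MARKERS + CIMP2_MARKERS + NEGATIVE_MARKERS
    rows = []
    for _, s in samples.iterrows():
        state = {m: "unknown" for m in all_markers}
        if rng.random() < config.marker_ambiguous_fraction:
            rows.append({"sample_id": s["sample_id"], **state})
            continue
        if s["cimp"] == "positive":
            state["BRAF_mut"] = "yes" if s["braf"] == "mutant" else "no"
            state["MLH1_meth"] = "yes"
            state["TIMP3_meth"] = "yes" if (s["braf"] != "mutant" or rng.random() < 0.5) else "no"
            if rng.random() < 0.5:
                state["MINT1_meth"] = "yes"
                state["MINT1_unmeth"] = "no"
            for m in NEGATIVE_MARKERS:
                if state.get(m, "unknown") == "unknown":
                    state[m] = "no"
        else:
            state["BRAF_mut"] = "no"
            state["TP53_mut"] = "yes"
            state["MINT2_unmeth"] = "yes"
            state["MINT2_meth"] = "no"
            if rng.random() < 0.5:
                state["MINT31_unmeth"] = "yes"
                state["MINT31_meth"] = "no"
            for m in CIMP1_MARKERS + CIMP2_MARKERS:
                if state[m] == "unknown":
                    state[m] = "no"
        rows.append({"sample_id": s["sample_id"], **state})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bisulfite tables

def generate_bisulfite_dataset(
    samples: pd.DataFrame, config: SimulationConfig
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-CpG methylation tables (percent) for validation genes.

    Normal tissue methylation stays below ``normal_meth_max`` (the assay
    background); mutant tumors gain ``bisulfite_delta`` percentage points
    on average.  A configurable fraction of cells is missing (ND).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9]))
    out: dict[str, dict[str, pd.DataFrame]] = {}
    cpg_cols = [f"CpG_{i + 1:02d}" for i in range(config.bisulfite_n_cpgs)]
    sample_ids = samples["sample_id"].tolist()
    is_mut = (samples["braf"] == "mutant").to_numpy()
    n, k = len(sample_ids), config.bisulfite_n_cpgs
    for g in range(config.bisulfite_genes):
        normal = rng.uniform(0.5, config.normal_meth_max - 0.5, (n, k))
        tumor = normal + rng.normal(0.0, 3.0, (n, k))
        tumor[is_mut] += rng.normal(config.bisulfite_delta, 5.0, (is_mut.sum(), k))
        tumor = np.clip(tumor, 0.0, 100.0)
        nd_t = rng.random((n, k)) < config.bisulfite_nd_fraction
        nd_n = rng.random((n, k)) < config.bisulfite_nd_fraction
        tumor = np.where(nd_t, np.nan, tumor)
        normal_masked = np.where(nd_n, np.nan, normal)
        idx = pd.Index(sample_ids, name="sample_id")
        out[f"VGENE{g + 1}"] = {
            "tumor": pd.DataFrame(tumor, index=idx, columns=cpg_cols),
            "normal": pd.DataFrame(normal_masked, index=idx, columns=cpg_cols),
        }
    return out


# ---------------------------------------------------------------------------
# study assembly and serialization

def probes_frame_to_list(probes: pd.DataFrame) -> list[Probe]:
    return [
        Probe(id=r.probe_id, chrom=r.chrom, start=int(r.start), end=int(r.end))
        for r in probes.itertuples()
    ]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage and return the assembled in-memory study."""
    genome, islands = generate_genome(config)
    fragments = digest_genome(genome)
    probes = design_array(fragments, config)
    mapped = map_probes(probes_frame_to_list(probes), fragments)
    with_probes = attach_probes(fragments, mapped)
    informative = select_informative_fragments(with_probes)
    genome_sizes = {c: len(s) for c, s in genome.items()}
    true_m, truth = simulate_methylation_cohort(config, informative, genome_sizes)
    scans = simulate_array_scans(true_m, probes, config)
    tracks, membership = generate_chromatin_tracks(informative, truth, config)
    truth.track_membership = membership
    genes = generate_gene_annotation(islands, config)

    # genes whose promoter window intersects a planted BRAF fragment
    eff = truth.fragment_effects.set_index("fragment_id")
    frag_by_id = {f.id: f for f in informative}
    braf_genes = []
    for fid, e in eff["braf_effect"].items():
        if e == 0:
            continue
        frag = frag_by_id[fid]
        near = genes[
            (genes["chrom"] == frag.chrom)
            & (genes["tss"] > frag.start - 2000)
            & (genes["tss"] < frag.end + 2000)
        ]
        braf_genes.extend(near["gene"].tolist())
    gene_sets = generate_gene_sets(genes, sorted(set(braf_genes)), config)
    markers = generate_marker_panels(truth.samples, config)
    bisulfite = generate_bisulfite_dataset(truth.samples, config)
    return SyntheticStudy(
        config=config, genome=genome, islands=islands, fragments=fragments,
        informative=informative, probes=probes, true_m=true_m, truth=truth,
        scans=scans, tracks=tracks, genes=genes, gene_sets=gene_sets,
        markers=markers, bisulfite=bisulfite,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write every study artifact under ``outdir`` with a hash manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "bisulfite").mkdir(exist_ok=True)

    io.write_fasta(study.genome, outdir / "genome.fa")
    io.write_bed(study.islands, outdir / "islands.bed")
    io.write_tsv(fragments_to_frame(study.fragments), outdir / "fragments_all.tsv")
    io.write_tsv(fragments_to_frame(study.informative), outdir / "fragments_informative.tsv")
    io.write_tsv(study.probes, outdir / "probes.tsv")
    scans = study.scans.copy()
    scans["ch1"] = scans["ch1"].round(4)
    scans["ch2"] = scans["ch2"].round(4)
    io.write_tsv(scans, outdir / "scans.tsv")
    io.write_tsv(study.true_m.reset_index(), outdir / "truth_m.tsv")
    io.write_tsv(study.truth.fragment_effects, outdir / "truth_effects.tsv")
    io.write_tsv(study.truth.samples, outdir / "samples.tsv")
    if len(study.truth.cn_intervals):
        io.write_bed(
            study.truth.cn_intervals.rename(columns={"sample_id": "name"})
            [["chrom", "start", "end", "name"]],
            outdir / "cn_losses.bed",
        )
    else:
        (outdir / "cn_losses.bed").write_text("")
    io.write_tsv(study.truth.track_membership, outdir / "truth_tracks.tsv")
    for name, track in study.tracks.items():
        io.write_bed(track, outdir / "tracks" / f"{name}.bed")
    io.write_tsv(study.genes, outdir / "genes.tsv")
    io.write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
    io.write_tsv(study.markers, outdir / "markers.tsv")
    for gene, pair in study.bisulfite.items():
        for tissue, df in pair.items():
            io.write_tsv(df.round(2).reset_index(),
                         outdir / "bisulfite" / f"{gene}_{tissue}.tsv")

    manifest = {
        "seed": study.config.seed,
        "files": {
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
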