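"""End-to-end orchestration: simulate -> digest -> normalize -> test ->
annotate -> classify -> downstream -> report.

Each step reads its inputs from and writes its outputs to a run
directory, so steps can be re-run individually (from the CLI or the
analysis drivers) and a full run is reproducible byte for byte under a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import annotation, classify, diffmeth, io, normalize, simulate, stats
from .config import PipelineConfig
from .digestion import (
    attach_probes,
    digest_genome,
    fragments_to_frame,
    map_probes,
    Probe,
    probes_to_frame,
    select_informative_fragments,
)

logger = logging.getLogger(__name__)

TRACK_NAMES = simulate.TRACK_NAMES


class StepError(RuntimeError):
    """A pipeline step failed; carries the step name."""

    def __init__(self, step: str, message: str):
        super().__init__(f"step {step!r} failed: {message}")
        self.step = step


def _require(path: Path, step: str) -> Path:
    if not path.exists():
        raise StepError(step, f"missing input {path} (was the producing step run?)")
    return path


def step_simulate(cfg: PipelineConfig, run_dir: Path) -> Path:
    sim_dir = run_dir / "sim"
    study = simulate.simulate_study(cfg.simulation)
    simulate.write_study(study, sim_dir)
    logger.info("simulated study written to %s", sim_dir)
    return sim_dir


def step_digest(cfg: PipelineConfig, run_dir: Path) -> None:
    """Digest the genome, map probes, select informative fragments."""
    step = "digest"
    sim_dir = run_dir / "sim"
    genome_path = cfg.genome_fasta or sim_dir / "genome.fa"
    probe_path = cfg.probe_table or sim_dir / "probes.tsv"
    genome = io.read_fasta(_require(Path(genome_path), step))
    probes_df = io.read_tsv(_require(Path(probe_path), step))
    probes = [
        Probe(id=r.probe_id, chrom=r.chrom, start=int(r.start), end=int(r.end))
        for r in probes_df.itertuples()
    ]
    fragments = digest_genome(genome)
    mapped = map_probes(probes, fragments)
    with_probes = attach_probes(fragments, mapped)
    informative = select_informative_fragments(
        with_probes,
        min_length=cfg.analysis["min_fragment_length"],
        max_length=cfg.analysis["max_fragment_length"],
    )
    out = run_dir / "digest"
    out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(fragments_to_frame(fragments), out / "fragments.tsv")
    io.write_tsv(fragments_to_frame(informative), out / "informative.tsv")
    io.write_tsv(probes_to_frame(mapped), out / "probe_map.tsv")


def step_normalize(cfg: PipelineConfig, run_dir: Path) -> None:
    step = "normalize"
    scan_path = cfg.scan_table or run_dir / "sim" / "scans.tsv"
    scans = io.read_tsv(_require(Path(scan_path), step))
    probe_map = io.read_tsv(_require(run_dir / "digest" / "probe_map.tsv", step))
    informative = io.read_tsv(_require(run_dir / "digest" / "informative.tsv", step))
    # restrict to probes on informative fragments
    probe_map = probe_map[probe_map["fragment_id"].isin(informative["fragment_id"])]
    matrix = normalize.normalize_experiment(
        scans, probe_map,
        span=cfg.analysis["loess_span"],
        robustness_iters=cfg.analysis["robustness_iters"],
    )
    out = run_dir / "normalize"
    out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(matrix.round(6).reset_index(), out / "matrix.tsv")


def _load_matrix(run_dir: Path, step: str) -> pd.DataFrame:
    path = _require(run_dir / "normalize" / "matrix.tsv", step)
    return io.read_tsv(path).set_index("fragment_id")


def _load_samples(cfg: PipelineConfig, run_dir: Path, step: str) -> pd.DataFrame:
    return io.read_tsv(_require(run_dir / "sim" / "samples.tsv", step))


def step_test(cfg: PipelineConfig, run_dir: Path) -> None:
    step = "test"
    matrix = _load_matrix(run_dir, step)
    samples = _load_samples(cfg, run_dir, step)
    out = run_dir / "test"
    out.mkdir(parents=True, exist_ok=True)
    for contrast in diffmeth.CONTRASTS:
        res = diffmeth.run_contrast(
            matrix, samples, contrast, fdr_threshold=cfg.analysis["fdr_threshold"]
        )
        io.write_tsv(res.round(10), out / f"results_{contrast}.tsv")
    logger.info(
        "selection at FDR <= %s on %d fragments", cfg.analysis["fdr_threshold"],
        len(matrix),
    )


def _selected_region_set(run_dir: Path, contrast: str, informative: pd.DataFrame,
                         step: str) -> annotation.RegionSet:
    res = io.read_tsv(_require(run_dir / "test" / f"results_{contrast}.tsv", step))
    sel = res[res["selected"]]
    coords = informative.merge(sel[["fragment_id"]], on="fragment_id")
    return annotation.RegionSet.from_fragments(f"{contrast}_dmrs", coords)


def step_annotate(cfg: PipelineConfig, run_dir: Path) -> None:
    step = "annotate"
    informative = io.read_tsv(_require(run_dir / "digest" / "informative.tsv", step))
    universe = annotation.RegionSet.from_fragments("informative", informative)
    tracks = {
        name: annotation.RegionSet.from_bed(
            name, io.read_bed(_require(run_dir / "sim" / "tracks" / f"{name}.bed", step))
        )
        for name in TRACK_NAMES
    }
    genes = io.read_tsv(_require(run_dir / "sim" / "genes.tsv", step))
    min_bp = cfg.analysis["min_overlap_bp"]
    out = run_dir / "annotate"
    out.mkdir(parents=True, exist_ok=True)

    grids = []
    sets = {}
    for contrast in diffmeth.CONTRASTS:
        selected = _selected_region_set(run_dir, contrast, informative, step)
        sets[contrast] = selected
        if len(selected) == 0:
            logger.warning("no regions selected for contrast %s", contrast)
            continue
        grid = annotation.enrichment_table(selected, universe, tracks, min_bp)
        grid.insert(0, "contrast", contrast)
        grids.append(grid)
    if grids:
        io.write_tsv(pd.concat(grids, ignore_index=True), out / "enrichment.tsv")

    a_only, shared, b_only = annotation.venn_overlap(sets["cimp"], sets["braf"])
    venn = {"cimp_only": a_only, "shared": shared, "braf_only": b_only}

    filtered, n_removed = annotation.filter_premarked(
        sets["braf"], tracks["H3K27me3"], min_bp
    )
    io.write_tsv(filtered.regions, out / "braf_not_premarked.tsv")
    promoters = annotation.assign_promoters(
        filtered, genes,
        upstream=cfg.analysis["promoter_upstream"],
        downstream=cfg.analysis["promoter_downstream"],
        min_bp=min_bp,
    )
    io.write_tsv(promoters, out / "braf_promoter_genes.tsv")
    (out / "summary.json").write_text(json.dumps({
        "venn_cimp_braf": venn,
        "premarked_removed": n_removed,
        "braf_promoter_genes": int(promoters[promoters["promoter"]]["gene"].nunique())
        if len(promoters) else 0,
    }, indent=2))


def step_classify(cfg: PipelineConfig, run_dir: Path) -> None:
    step = "classify"
    markers = io.read_tsv(_require(run_dir / "sim" / "markers.tsv", step))
    calls = classify.classify_panel(markers)
    out = run_dir / "classify"
    out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(calls, out / "cimp_calls.tsv")

    # copy-number filter on the BRAF-specific regions
    matrix = _load_matrix(run_dir, step)
    samples = _load_samples(cfg, run_dir, step)
    res = io.read_tsv(_require(run_dir / "test" / "results_braf.tsv", step))
    sel = res[res["selected"]]["fragment_id"].tolist()
    wt = samples[samples["braf"] == "wildtype"]["sample_id"].tolist()
    if len(sel) >= 2:
        report, retained = classify.copy_number_filter(sel, matrix[wt])
        io.write_tsv(report.round(6), out / "cn_filter.tsv")
        io.write_tsv(retained.round(6), out / "cn_retained.tsv")
    else:
        logger.warning("fewer than 2 BRAF-specific regions; CN filter skipped")


def step_downstream(cfg: PipelineConfig, run_dir: Path) -> None:
    step = "downstream"
    out = run_dir / "downstream"
    out.mkdir(parents=True, exist_ok=True)
    genes = io.read_tsv(_require(run_dir / "sim" / "genes.tsv", step))
    gene_sets = io.read_gmt(_require(run_dir / "sim" / "gene_sets.gmt", step))
    promoters = io.read_tsv(
        _require(run_dir / "annotate" / "braf_promoter_genes.tsv", step)
    ) if (run_dir / "annotate" / "braf_promoter_genes.tsv").stat().st_size > 1 else pd.DataFrame(
        columns=["region_id", "gene", "promoter"]
    )
    retained_path = run_dir / "classify" / "cn_retained.tsv"
    query = set(promoters[promoters["promoter"]]["gene"]) if len(promoters) else set()
    if retained_path.exists() and query:
        retained = set(io.read_tsv(retained_path)["fragment_id"])
        kept_regions = set(promoters[promoters["region_id"].isin(retained)]["gene"])
        query &= kept_regions
    universe = set(genes["gene"])
    report = stats.enrichment_report(query, gene_sets, universe)
    io.write_tsv(report, out / "enrichment.tsv")

    # bisulfite validation per gene
    bs_dir = run_dir / "sim" / "bisulfite"
    samples = _load_samples(cfg, run_dir, step)
    rows = []
    if bs_dir.exists():
        tumors = sorted(p.name[:-len("_tumor.tsv")] for p in bs_dir.glob("*_tumor.tsv"))
        for gene in tumors:
            tumor = io.read_tsv(bs_dir / f"{gene}_tumor.tsv").set_index("sample_id")
            normal = io.read_tsv(bs_dir / f"{gene}_normal.tsv").set_index("sample_id")
            diff = stats.bsa_average_and_subtract(tumor, normal)
            diff = diff.join(samples.set_index("sample_id")["braf"])
            ok = diff[~diff["excluded"]]
            u, p = stats.mann_whitney_one_sided(
                ok[ok["braf"] == "wildtype"]["difference"].to_numpy(),
                ok[ok["braf"] == "mutant"]["difference"].to_numpy(),
            )
            rows.append({"gene": gene, "U": u, "P": p,
                         "n_wildtype": int((ok["braf"] == "wildtype").sum()),
                         "n_mutant": int((ok["braf"] == "mutant").sum())})
    io.write_tsv(pd.DataFrame(rows), out / "bisulfite_tests.tsv")


def step_report(cfg: PipelineConfig, run_dir: Path) -> dict:
    """Collect the headline numbers of a run into report.json."""
    step = "report"
    summary: dict = {"seed": cfg.seed}
    informative = io.read_tsv(_require(run_dir / "digest" / "informative.tsv", step))
    summary["n_informative_fragments"] = len(informative)
    for contrast in diffmeth.CONTRASTS:
        res = io.read_tsv(_require(run_dir / "test" / f"results_{contrast}.tsv", step))
        sel = res[res["selected"]]
        summary[f"n_dmr_{contrast}"] = int(len(sel))
        summary[f"pct_hyper_{contrast}"] = (
            100.0 * float((sel["effect"] > 0).mean()) if len(sel) else float("nan")
        )
    ann = run_dir / "annotate" / "summary.json"
    if ann.exists():
        summary.update(json.loads(ann.read_text()))
    enr = run_dir / "annotate" / "enrichment.tsv"
    if enr.exists():
        summary["enrichment_grid"] = io.read_tsv(enr).to_dict(orient="records")
    calls = run_dir / "classify" / "cimp_calls.tsv"
    if calls.exists():
        counts = io.read_tsv(calls)["call"].value_counts().to_dict()
        summary["cimp_calls"] = {k: int(v) for k, v in counts.items()}
    cn = run_dir / "classify" / "cn_filter.tsv"
    if cn.exists():
        rep = io.read_tsv(cn)
        summary["cn_excluded"] = int(rep["excluded"].sum())
        summary["cn_threshold"] = float(rep["threshold"].iloc[0])
    bs = run_dir / "downstream" / "bisulfite_tests.tsv"
    if bs.exists() and bs.stat().st_size > 10:
        summary["bisulfite_tests"] = io.read_tsv(bs).to_dict(orient="records")
    (run_dir / "report.json").write_text(json.dumps(summary, indent=2))
    # thresholds actually applied, for the run log
    logger.info(
        "thresholds: fragment length [%d, %d] bp, FDR <= %s, overlap >= %d bp, "
        "CN rule median - SD",
        cfg.analysis["min_fragment_length"], cfg.analysis["max_fragment_length"],
        cfg.analysis["fdr_threshold"], cfg.analysis["min_overlap_bp"],
    )
    return summary


_STEP_FUNCS = {
    "simulate": step_simulate,
    "digest": step_digest,
    "normalize": step_normalize,
    "test": step_test,
    "annotate": step_annotate,
    "classify": step_classify,
    "downstream": step_downstream,
    "report": step_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled step in order; returns the summary report."""
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid pipeline config:\n" + "\n".join(errors))
    run_dir = Path(cfg.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for name, func in _STEP_FUNCS.items():
        if not cfg.steps.get(name, True):
            logger.info("step %s disabled; skipping", name)
            continue
        if name == "simulate" and not cfg.simulate:
            continue
        logger.info("running step %s", name)
        try:
            result = func(cfg, run_dir)
        except StepError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the step name
            raise StepError(name, str(exc)) from exc
        if name == "report":
            summary = result
    return summary


def results_digest(run_dir: Path) -> str:
    """SHA-256 over every result table of a run (determinism check)."""
    h = hashlib.sha256()
    for path in sorted(Path(run_dir).rglob("*.tsv")):
        h.update(str(path.relative_to(run_dir)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
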