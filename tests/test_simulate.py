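"""Synthetic-study generator: determinism, planted truth, emitted formats."""

import json

import numpy as np
import pandas as pd
import pytest

from dmh.config import SimulationConfig
from dmh import simulate
from dmh.digestion import digest_genome


def test_genome_deterministic_and_seed_sensitive():
    cfg1 = SimulationConfig(seed=1, genome_length=100_000, n_chromosomes=1)
    g1, isl1 = simulate.generate_genome(cfg1)
    g1b, _ = simulate.generate_genome(cfg1)
    assert g1 == g1b
    g2, _ = simulate.generate_genome(SimulationConfig(seed=2, genome_length=100_000,
                                                      n_chromosomes=1))
    assert g1 != g2
    # fragment-length distributions agree across seeds (same composition)
    l1 = np.mean([f.length for f in digest_genome(g1)])
    l2 = np.mean([f.length for f in digest_genome(g2)])
    assert abs(l1 - l2) / l1 < 0.2


def test_zero_island_density_is_valid():
    cfg = SimulationConfig(seed=1, genome_length=100_000, cpg_island_density=0.0)
    genome, islands = simulate.generate_genome(cfg)
    assert len(islands) == 0
    assert len(digest_genome(genome)) > 0


def test_positive_density_yielding_zero_islands_errors():
    cfg = SimulationConfig(seed=1, genome_length=100_000, cpg_island_density=1.0)
    with pytest.raises(ValueError, match="cpg_island_density"):
        simulate.generate_genome(cfg)


def test_islands_enriched_for_restriction_motifs():
    cfg = SimulationConfig(seed=4, genome_length=200_000, n_chromosomes=1)
    genome, islands = simulate.generate_genome(cfg)
    seq = genome["chr1"]
    inside = "".join(seq[r.start:r.end] for r in islands.itertuples())
    density_in = (inside.count("CCGG") + inside.count("CGCG")) / len(inside)
    density_genome = (seq.count("CCGG") + seq.count("CGCG")) / len(seq)
    assert density_in > 3 * density_genome


class TestDesignArray:
    def test_probe_counts_within_bounds(self, small_study):
        per_frag = small_study.probes[~small_study.probes["is_decoy"]]
        counts = per_frag.groupby("true_fragment_id").size()
        assert counts.between(1, 33).all()

    def test_probes_fit_inside_fragments(self, small_study):
        frag = {f.id: f for f in small_study.fragments}
        for p in small_study.probes[~small_study.probes["is_decoy"]].itertuples():
            f = frag[p.true_fragment_id]
            assert f.start <= p.start and p.end <= f.end
            assert 45 <= p.end - p.start <= 60

    def test_short_fragment_gets_no_probe(self, small_study):
        probed = set(small_study.probes["true_fragment_id"].dropna())
        for f in small_study.fragments:
            if f.length < 45:
                assert f.id not in probed

    def test_decoy_fraction(self):
        cfg = SimulationConfig(seed=5, genome_length=400_000, decoy_fraction=0.1)
        genome, _ = simulate.generate_genome(cfg)
        probes = simulate.design_array(digest_genome(genome), cfg)
        assert probes["is_decoy"].mean() == pytest.approx(0.1, abs=0.02)


class TestCohortTruth:
    def test_all_zero_when_no_effects(self):
        cfg = SimulationConfig(seed=6, genome_length=200_000,
                               dmr_effect=0.0, tumor_effect=0.0,
                               cn_loss_fraction=0.0, n_tumor_dmr=10, n_group_dmr=10)
        study = simulate.simulate_study(cfg)
        assert (study.true_m.to_numpy() == 0).all()

    def test_truth_bookkeeping_counts(self, small_study):
        cfg = small_study.config
        eff = small_study.truth.fragment_effects
        assert (eff["tumor_effect"] != 0).sum() == cfg.n_tumor_dmr
        assert (eff["cimp_effect"] != 0).sum() == cfg.n_group_dmr
        assert (eff["braf_effect"] != 0).sum() == cfg.n_group_dmr
        shared = ((eff["cimp_effect"] != 0) & (eff["braf_effect"] != 0)).sum()
        assert shared == round(cfg.dmr_shared_fraction * cfg.n_group_dmr)
        # truth covers every informative fragment exactly once
        assert sorted(eff["fragment_id"]) == sorted(f.id for f in small_study.informative)

    def test_requesting_too_many_dmrs_errors(self):
        cfg = SimulationConfig(seed=6, genome_length=100_000,
                               n_tumor_dmr=100_000, n_group_dmr=10)
        with pytest.raises(ValueError, match="informative fragments"):
            simulate.simulate_study(cfg)

    def test_braf_effect_mostly_positive(self, small_study):
        eff = small_study.truth.fragment_effects
        braf = eff.loc[eff["braf_effect"] != 0, "braf_effect"]
        assert (braf > 0).mean() >= 0.9

    def test_cn_loss_mean_shift(self):
        """Mean true M over CN-loss fragments recovers the planted shift."""
        cfg = SimulationConfig(seed=8, genome_length=600_000, n_tumor_dmr=0,
                               n_group_dmr=0, dmr_effect=0.0, tumor_effect=0.0,
                               cn_loss_fraction=1.0)
        study = simulate.simulate_study(cfg)
        m = study.true_m
        vals = []
        samples = study.truth.samples.set_index("sample_id")
        for s in m.columns:
            if not samples.loc[s, "has_cn_loss"]:
                continue
            col = m[s]
            vals.extend(col[col != 0].tolist())
        assert np.mean(vals) == pytest.approx(-0.26, abs=0.05)

    def test_cn_losses_only_in_wildtypes(self, small_study):
        s = small_study.truth.samples
        assert not s.loc[s["braf"] == "mutant", "has_cn_loss"].any()


class TestScans:
    def test_row_count(self, small_study):
        n = small_study.config.n_samples
        assert len(small_study.scans) == len(small_study.probes) * 2 * n

    def test_intensities_positive(self, small_study):
        assert (small_study.scans[["ch1", "ch2"]] > 0).all().all()

    def test_dye_swap_pairs_per_sample(self, small_study):
        per = small_study.scans.groupby("sample_id")["orientation"].nunique()
        assert (per == 2).all()

    def test_dye_swap_algebra_zero_noise(self, noisefree_study):
        """(M_fwd - M_rev)/2 equals true fragment M exactly at zero noise."""
        st = noisefree_study
        scans = st.scans
        m = np.log2(scans["ch1"].to_numpy() / scans["ch2"].to_numpy())
        scans = scans.assign(M=m)
        fwd = scans[scans["orientation"] == "tumor_in_ch1"]
        rev = scans[scans["orientation"] == "tumor_in_ch2"]
        merged = fwd.merge(rev, on=["probe_id", "sample_id"], suffixes=("_f", "_r"))
        corrected = (merged["M_f"] - merged["M_r"]) / 2
        truth = st.true_m
        frag = merged["probe_id"].map(
            st.probes.set_index("probe_id")["true_fragment_id"]
        )
        expected = [
            truth.at[f, s] if f in truth.index else 0.0
            for f, s in zip(frag, merged["sample_id"])
        ]
        assert np.allclose(corrected, expected, atol=1e-9)

    def test_dye_bias_recoverable_from_swap_sum(self):
        """(M_fwd + M_rev)/2 isolates the additive probe dye bias."""
        cfg = SimulationConfig(seed=9, genome_length=200_000, n_tumor_dmr=5,
                               n_group_dmr=5, noise_sd=0.0, curvature_amp=0.0,
                               dye_bias_sd=0.5, cn_loss_fraction=0.0)
        st = simulate.simulate_study(cfg)
        scans = st.scans
        m = np.log2(scans["ch1"].to_numpy() / scans["ch2"].to_numpy())
        scans = scans.assign(M=m)
        fwd = scans[scans["orientation"] == "tumor_in_ch1"]
        rev = scans[scans["orientation"] == "tumor_in_ch2"]
        merged = fwd.merge(rev, on=["probe_id", "sample_id"], suffixes=("_f", "_r"))
        bias_est = merged.groupby("probe_id")[["M_f", "M_r"]].mean().sum(axis=1) / 2
        assert bias_est.std() == pytest.approx(0.5, rel=0.1)


class TestTracksMarkersBisulfite:
    def test_track_direction(self, small_study):
        """Repressive marks enriched, active marks depleted on planted DMRs."""
        mem = small_study.truth.track_membership.set_index("fragment_id")
        eff = small_study.truth.fragment_effects.set_index("fragment_id")
        planted = (eff["cimp_effect"] != 0) | (eff["braf_effect"] != 0)
        for mark, enriched in [("SUZ12", True), ("H3K27me3", True),
                               ("CTCF", False), ("H3K4me3", False)]:
            r_planted = mem.loc[planted, mark].mean()
            r_rest = mem.loc[~planted, mark].mean()
            assert bool(r_planted > r_rest) == enriched

    def test_marker_round_trip(self, small_study):
        from dmh.classify import classify_panel
        calls = classify_panel(small_study.markers).set_index("sample_id")
        truth = small_study.truth.samples.set_index("sample_id")
        for sid in truth.index:
            assert calls.loc[sid, "call"] == truth.loc[sid, "cimp"]

    def test_ambiguous_fraction_undetermined(self):
        from dmh.classify import classify_panel
        cfg = SimulationConfig(seed=10, genome_length=100_000,
                               n_wildtype=60, n_mutant=40, n_cimp_pos=50,
                               marker_ambiguous_fraction=0.1)
        markers = simulate.generate_marker_panels(simulate.make_samples(cfg), cfg)
        calls = classify_panel(markers)
        assert (calls["call"] == "undetermined").mean() == pytest.approx(0.1, abs=0.06)

    def test_bisulfite_constraints(self, small_study):
        for gene, pair in small_study.bisulfite.items():
            normal = pair["normal"]
            assert (normal.fillna(0) < 8).all().all()
            nd = pair["tumor"].isna().mean().mean()
            assert nd == pytest.approx(small_study.config.bisulfite_nd_fraction, abs=0.03)

    def test_bisulfite_mutants_elevated(self, small_study):
        samples = small_study.truth.samples.set_index("sample_id")
        for gene, pair in small_study.bisulfite.items():
            means = pair["tumor"].mean(axis=1)
            mut = means[samples["braf"] == "mutant"].mean()
            wt = means[samples["braf"] == "wildtype"].mean()
            assert mut > wt + 10


def test_write_study_deterministic(tmp_path, small_config):
    """Identical config and seed give byte-identical study files."""
    cfg = SimulationConfig(seed=21, genome_length=120_000, n_tumor_dmr=10,
                           n_group_dmr=8)
    d1 = simulate.write_study(simulate.simulate_study(cfg), tmp_path / "a")
    d2 = simulate.write_study(simulate.simulate_study(cfg), tmp_path / "b")
    m1 = json.loads((d1 / "manifest.json").read_text())
    m2 = json.loads((d2 / "manifest.json").read_text())
    assert m1["files"] == m2["files"]
    assert len(m1["files"]) > 10
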