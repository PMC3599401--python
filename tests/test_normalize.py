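"""Two-color preprocessing: LOESS, aquantile, dye-swap, summarization."""

import numpy as np
import pandas as pd
import pytest

from dmh import normalize
from dmh.config import SimulationConfig
from dmh import simulate
from tests.conftest import informative_probe_map


def _scan(probe_ids, m, a, sample="S01", orientation="tumor_in_ch1"):
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "array_id": f"{sample}_{orientation}",
            "sample_id": sample,
            "orientation": orientation,
            "ch1": 2.0 ** (a + m / 2),
            "ch2": 2.0 ** (a - m / 2),
            "M": m,
            "A": a,
        }
    )


class TestLoess:
    def test_flat_data_unchanged(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(8, 14, 500)
        m = np.full(500, 0.3)
        fit = normalize.loess_fit(a, m)
        assert np.abs(fit - 0.3).max() < 1e-8

    def test_planted_cubic_removed_zero_noise(self):
        rng = np.random.default_rng(1)
        a = 10 + 4 * rng.beta(2, 5, 4000)
        trend = simulate.curvature(a, 0.3, 10.0, 4.0)
        m = trend.copy()
        fit = normalize.loess_fit(a, m)
        assert np.abs(m - fit).max() < 0.01

    def test_span_one_linear_equals_linear_detrending(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, 300)
        m = 1.5 + 0.4 * a
        fit = normalize.loess_fit(a, m, span=1.0, robustness_iters=0)
        coef = np.polyfit(a, m, 1)
        assert np.abs(fit - np.polyval(coef, a)).max() < 1e-6

    def test_outlier_signal_does_not_bend_trend(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(8, 14, 2000)
        m = rng.normal(0, 0.05, 2000)
        spikes = rng.choice(2000, 100, replace=False)
        m[spikes] += 1.0
        fit = normalize.loess_fit(a, m)
        non_spike = np.setdiff1d(np.arange(2000), spikes)
        assert np.abs(fit[non_spike]).max() < 0.05

    def test_too_few_probes_error(self):
        with pytest.raises(ValueError, match="at least"):
            normalize.loess_fit(np.arange(10.0), np.arange(10.0))

    def test_bad_span_error(self):
        with pytest.raises(ValueError, match="span"):
            normalize.loess_fit(np.arange(100.0), np.arange(100.0), span=0.0)


class TestAquantile:
    def test_identical_arrays_unchanged(self):
        a = np.sort(np.random.default_rng(4).uniform(8, 14, 200))
        s1 = _scan([f"p{i}" for i in range(200)], np.zeros(200), a)
        s2 = _scan([f"p{i}" for i in range(200)], np.zeros(200), a, sample="S02")
        out = normalize.aquantile_between([s1, s2])
        assert np.allclose(out[0]["A"], a)
        assert np.allclose(out[1]["A"], a)

    def test_a_distributions_identical_and_m_untouched(self):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(300)]
        scans = [
            _scan(ids, rng.normal(0, 1, 300), rng.uniform(6 + j, 15 + j, 300),
                  sample=f"S{j:02d}")
            for j in range(3)
        ]
        m_before = [s["M"].copy() for s in scans]
        out = normalize.aquantile_between(scans)
        sorted_as = [np.sort(s["A"].to_numpy()) for s in out]
        for arr in sorted_as[1:]:
            assert np.allclose(arr, sorted_as[0])
        for before, after in zip(m_before, out):
            assert np.array_equal(before.to_numpy(), after["M"].to_numpy())

    def test_mismatched_probe_sets_error(self):
        s1 = _scan([f"p{i}" for i in range(60)], np.zeros(60), np.linspace(8, 12, 60))
        s2 = _scan([f"p{i}" for i in range(50)], np.zeros(50), np.linspace(8, 12, 50))
        with pytest.raises(ValueError):
            normalize.aquantile_between([s1, s2])


def test_loess_aquantile_order_immaterial_on_shared_a():
    """When arrays already share one A distribution, swapping the LOESS
    and aquantile steps leaves the corrected M unchanged."""
    rng = np.random.default_rng(9)
    ids = [f"p{i}" for i in range(300)]
    a = rng.uniform(8, 14, 300)
    scans = [
        _scan(ids, rng.normal(0, 0.2, 300) + 0.05 * (a - 11) ** 2, a,
              sample=f"S{j}")
        for j in range(2)
    ]
    loess_then_aq = normalize.aquantile_between(
        [normalize.loess_within(s) for s in scans]
    )
    aq_then_loess = [
        normalize.loess_within(s) for s in normalize.aquantile_between(scans)
    ]
    for x, y in zip(loess_then_aq, aq_then_loess):
        assert np.allclose(x["M"], y["M"], atol=1e-10)
        assert np.allclose(x["A"], y["A"], atol=1e-10)


class TestDyeSwap:
    def test_probe_bias_cancels_exactly(self):
        rng = np.random.default_rng(6)
        ids = [f"p{i}" for i in range(100)]
        true_m = rng.normal(0, 0.5, 100)
        bias = rng.normal(0, 0.3, 100)
        a = rng.uniform(8, 14, 100)
        fwd = _scan(ids, true_m + bias, a, orientation="tumor_in_ch1")
        rev = _scan(ids, -true_m + bias, a, orientation="tumor_in_ch2")
        out = normalize.combine_dye_swap(fwd, rev)
        assert np.allclose(out["M"], true_m, atol=1e-12)

    def test_argument_order_irrelevant(self):
        ids = ["p0", "p1"]
        fwd = _scan(ids, [0.5, 0.1], [10, 11], orientation="tumor_in_ch1")
        rev = _scan(ids, [-0.5, -0.1], [10, 11], orientation="tumor_in_ch2")
        out1 = normalize.combine_dye_swap(fwd, rev)
        out2 = normalize.combine_dye_swap(rev, fwd)
        assert np.allclose(out1["M"], out2["M"])

    def test_same_orientation_refused(self):
        s = _scan(["p0"], [0.5], [10])
        with pytest.raises(ValueError, match="orientation"):
            normalize.combine_dye_swap(s, s.copy())

    def test_mismatched_probes_listed(self):
        fwd = _scan(["p0", "p1"], [0, 0], [10, 10], orientation="tumor_in_ch1")
        rev = _scan(["p0", "p2"], [0, 0], [10, 10], orientation="tumor_in_ch2")
        with pytest.raises(ValueError, match="p1"):
            normalize.combine_dye_swap(fwd, rev)


class TestSummarize:
    @pytest.mark.parametrize(
        "values, expected",
        [([0.1, 0.5, 0.9], 0.5), ([0.1, 0.5], 0.3), ([0.7], 0.7)],
    )
    def test_median_rules(self, values, expected):
        probe_m = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(values))],
                "sample_id": "S01",
                "M": values,
            }
        )
        pmap = pd.DataFrame(
            {"probe_id": probe_m["probe_id"], "fragment_id": "frag"}
        )
        out = normalize.summarize_fragments(probe_m, pmap)
        assert out.loc["frag", "S01"] == pytest.approx(expected)

    def test_unmapped_probes_dropped(self):
        probe_m = pd.DataFrame(
            {"probe_id": ["p0", "p1"], "sample_id": "S01", "M": [0.2, 9.9]}
        )
        pmap = pd.DataFrame({"probe_id": ["p0", "p1"], "fragment_id": ["f", None]})
        out = normalize.summarize_fragments(probe_m, pmap)
        assert out.loc["f", "S01"] == pytest.approx(0.2)
        assert out.shape == (1, 1)


class TestEndToEnd:
    def test_zero_noise_recovery(self, noisefree_study):
        """With dye bias and curvature but no noise the matrix matches truth."""
        st = noisefree_study
        mat = normalize.normalize_experiment(st.scans, informative_probe_map(st))
        err = (mat - st.true_m.loc[mat.index]).abs()
        assert float(err.stack().max()) < 1e-2

    def test_exact_recovery_without_bias_or_curvature(self):
        cfg = SimulationConfig(seed=17, genome_length=200_000, n_tumor_dmr=20,
                               n_group_dmr=15, noise_sd=0.0, dye_bias_sd=0.0,
                               curvature_amp=0.0, cn_loss_fraction=0.0)
        st = simulate.simulate_study(cfg)
        mat = normalize.normalize_experiment(st.scans, informative_probe_map(st))
        err = (mat - st.true_m.loc[mat.index]).abs()
        assert float(err.stack().max()) < 1e-6

    def test_fragment_sd_shrinks_with_probe_count(self, small_study):
        """Residual SD of multi-probe fragments scales roughly as 1/sqrt(n)."""
        st = small_study
        mat = normalize.normalize_experiment(st.scans, informative_probe_map(st))
        resid = (mat - st.true_m.loc[mat.index]).stack()
        n_probes = st.probes[~st.probes["is_decoy"]].groupby("true_fragment_id").size()
        counts = n_probes.reindex(mat.index).fillna(0)
        sd1 = resid[counts[counts == 1].index.intersection(mat.index)].std()
        multi = counts[counts >= 3].index.intersection(mat.index)
        if len(multi) >= 20:
            sd3 = resid[multi].std()
            assert sd3 < sd1
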