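"""Interval overlap, chi-squared enrichment, promoters, Venn counts."""

import numpy as np
import pandas as pd
import pytest

from dmh.annotation import (
    assign_promoters,
    enrichment_chi_squared,
    enrichment_table,
    filter_premarked,
    overlap_min_bp,
    RegionSet,
    venn_overlap,
)


def _regions(name, triples):
    return RegionSet(
        name,
        pd.DataFrame(
            [(f"{name}_{i}", c, s, e) for i, (c, s, e) in enumerate(triples)],
            columns=["region_id", "chrom", "start", "end"],
        ),
    )


class TestOverlap:
    def test_19_bp_is_not_enough(self):
        regions = _regions("r", [("chr1", 0, 100)])
        track = _regions("t", [("chr1", 81, 200)])
        assert not overlap_min_bp(regions, track).iloc[0]

    def test_20_bp_boundary_counts(self):
        regions = _regions("r", [("chr1", 0, 100)])
        track = _regions("t", [("chr1", 80, 200)])
        assert overlap_min_bp(regions, track).iloc[0]

    def test_per_interval_not_summed(self):
        """Two 15 bp overlaps with different track intervals do not add up."""
        regions = _regions("r", [("chr1", 0, 100)])
        track = _regions("t", [("chr1", -10, 15), ("chr1", 85, 200)])
        # shift to keep starts non-negative
        track = _regions("t", [("chr1", 0, 15), ("chr1", 85, 200)])
        assert not overlap_min_bp(regions, track).iloc[0]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        chroms = ["chr1", "chr2"]
        reg = [(chroms[rng.integers(2)], int(s := rng.integers(0, 5000)),
                int(s + rng.integers(30, 400))) for _ in range(1000)]
        trk = [(chroms[rng.integers(2)], int(s := rng.integers(0, 5000)),
                int(s + rng.integers(30, 400))) for _ in range(300)]
        regions, track = _regions("r", reg), _regions("t", trk)
        got = overlap_min_bp(regions, track, min_bp=20)
        for i, (c, s, e) in enumerate(reg):
            expect = any(
                tc == c and min(e, te) - max(s, ts) >= 20 for tc, ts, te in trk
            )
            assert got.iloc[i] == expect


class TestChiSquared:
    def test_closed_form_identity(self):
        """Pearson chi2 equals N(ad-bc)^2 / row/col products."""
        a, b, c, d = 30, 70, 45, 255
        chi2, _ = enrichment_chi_squared(a, a + b, c, c + d)
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, abs=1e-9)

    def test_equal_proportions_null(self):
        chi2, p = enrichment_chi_squared(10, 100, 100, 1000)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            enrichment_chi_squared(0, 10, 0, 100)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            enrichment_chi_squared(11, 10, 5, 100)

    def test_published_contingency_values(self):
        """Chromatin-mark depletion tables reproduce their printed P-values."""
        _, p = enrichment_chi_squared(195, 758, 10321, 31413)
        assert round(p, 6) == 0.000035
        _, p = enrichment_chi_squared(183, 749, 10333, 31422)
        assert round(p, 6) == 0.000001


class TestFilterPremarked:
    def test_empty_track_identity(self):
        regions = _regions("r", [("chr1", 0, 100), ("chr1", 200, 300)])
        empty = RegionSet("t", pd.DataFrame(
            columns=["region_id", "chrom", "start", "end"]))
        out, removed = filter_premarked(regions, empty)
        assert removed == 0 and len(out) == 2

    def test_all_covering_track_empties(self):
        regions = _regions("r", [("chr1", 0, 100), ("chr1", 200, 300)])
        track = _regions("t", [("chr1", 0, 1000)])
        out, removed = filter_premarked(regions, track)
        assert removed == 2 and len(out) == 0

    def test_matches_generator_bookkeeping(self, small_study):
        """Removal count equals planted H3K27me3 membership among regions."""
        mem = small_study.truth.track_membership.set_index("fragment_id")
        frame = pd.DataFrame(
            {
                "region_id": [f.id for f in small_study.informative],
                "chrom": [f.chrom for f in small_study.informative],
                "start": [f.start for f in small_study.informative],
                "end": [f.end for f in small_study.informative],
            }
        )
        regions = RegionSet("informative", frame)
        track = RegionSet.from_bed(
            "H3K27me3",
            small_study.tracks["H3K27me3"],
        )
        _, removed = filter_premarked(regions, track)
        assert removed == int(mem["H3K27me3"].sum())


class TestPromoters:
    GENES = pd.DataFrame(
        {
            "gene": ["G+", "G-"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 30_000],
            "end": [12_000, 32_000],
            "strand": ["+", "-"],
            "tss": [10_000, 32_000],
        }
    )

    def test_region_at_tss_is_promoter(self):
        regions = _regions("r", [("chr1", 9_900, 10_100)])
        out = assign_promoters(regions, self.GENES)
        assert out.iloc[0]["gene"] == "G+" and bool(out.iloc[0]["promoter"])

    def test_strand_aware_window(self):
        # for the minus-strand gene, upstream extends to the right of the TSS
        regions = _regions("r", [("chr1", 33_000, 33_200)])
        out = assign_promoters(regions, self.GENES)
        assert out.iloc[0]["gene"] == "G-" and bool(out.iloc[0]["promoter"])

    def test_distant_region_unassigned(self):
        regions = _regions("r", [("chr1", 20_000, 20_200)])
        out = assign_promoters(regions, self.GENES)
        assert len(out) == 0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        triples = [("chr1", int(s := rng.integers(0, 40_000)),
                    int(s + rng.integers(30, 500))) for _ in range(300)]
        regions = _regions("r", triples)
        out = assign_promoters(regions, self.GENES, upstream=2000, downstream=500)
        got = {(r.region_id, r.gene): r.promoter for r in out.itertuples()}
        for i, (c, s, e) in enumerate(triples):
            rid = f"r_{i}"
            for g in self.GENES.itertuples():
                body = min(e, g.end) - max(s, g.start) >= 20
                if g.strand == "+":
                    ps, pe = g.tss - 2000, g.tss + 500
                else:
                    ps, pe = g.tss - 500, g.tss + 2000
                prom = min(e, pe) - max(s, ps) >= 20
                if body or prom:
                    assert got[(rid, g.gene)] == prom
                else:
                    assert (rid, g.gene) not in got


class TestVenn:
    def test_disjoint(self):
        a = _regions("a", [("chr1", 0, 100)])
        b = _regions("b", [("chr1", 0, 100)])
        assert venn_overlap(a, b) == (1, 0, 1)

    def test_identical(self):
        frame = pd.DataFrame(
            {"region_id": ["x", "y"], "chrom": "chr1", "start": [0, 200],
             "end": [100, 300]}
        )
        a = RegionSet("a", frame)
        b = RegionSet("b", frame.copy())
        assert venn_overlap(a, b) == (0, 2, 0)

    def test_random_sets_match_set_algebra(self):
        rng = np.random.default_rng(2)
        ids = [f"f{i}" for i in range(200)]
        ida = set(rng.choice(ids, 80, replace=False))
        idb = set(rng.choice(ids, 60, replace=False))
        def mk(name, chosen):
            return RegionSet(name, pd.DataFrame(
                {"region_id": sorted(chosen), "chrom": "chr1",
                 "start": range(len(chosen)), "end": range(100, 100 + len(chosen))}))
        counts = venn_overlap(mk("a", ida), mk("b", idb))
        assert counts == (len(ida - idb), len(ida & idb), len(idb - ida))
        assert sum(counts) == len(ida | idb)


def test_enrichment_table_null_uniform(small_study):
    """With odds ratio 1 the enrichment P-values are null-distributed."""
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(
        {
            "region_id": [f.id for f in small_study.informative],
            "chrom": [f.chrom for f in small_study.informative],
            "start": [f.start for f in small_study.informative],
            "end": [f.end for f in small_study.informative],
        }
    )
    universe = RegionSet("informative", frame)
    pvals = []
    for _ in range(40):
        sel_ids = rng.choice(frame["region_id"], 60, replace=False)
        selected = RegionSet("sel", frame[frame["region_id"].isin(sel_ids)])
        member = frame.sample(frac=0.2, random_state=int(rng.integers(1 << 31)))
        track = RegionSet("t", member)
        grid = enrichment_table(selected, universe, {"t": track})
        pvals.append(grid["P"].iloc[0])
    # crude uniformity checks: no mass collapse at either end
    assert 0.1 < np.mean(np.array(pvals) < 0.5) < 0.9
    assert np.mean(np.array(pvals) < 0.05) < 0.25
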