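"""Chromatin-mark overlap, enrichment testing and promoter assignment.

Differentially methylated regions are compared against chromatin-mark
tracks (SUZ12, H3K27me3, CTCF, H3K4me3 in ES cells) by requiring at
least 20 bp of overlap with a single track interval; enrichment among
selected versus remaining regions is tested by an uncorrected Pearson
chi-squared on the 2x2 table.  Regions pre-marked by H3K27me3 can be
filtered out before pathway analysis, and regions are assigned to genes
and promoters by the same >=20 bp rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_MIN_OVERLAP_BP = 20


@dataclass
class RegionSet:
    """A named set of genomic intervals with unique region ids."""

    name: str
    regions: pd.DataFrame  # columns: region_id, chrom, start, end
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        req = {"region_id", "chrom", "start", "end"}
        missing = req - set(self.regions.columns)
        if missing:
            raise ValueError(f"RegionSet {self.name}: missing columns {sorted(missing)}")
        if self.regions["region_id"].duplicated().any():
            raise ValueError(f"RegionSet {self.name}: duplicate region ids")
        if (self.regions["end"] <= self.regions["start"]).any():
            raise ValueError(f"RegionSet {self.name}: empty or inverted intervals")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def ids(self) -> set[str]:
        return set(self.regions["region_id"])

    def tree(self, chrom: str) -> IntervalTree:
        if not self._trees:
            for c, grp in self.regions.groupby("chrom"):
                self._trees[c] = IntervalTree.from_tuples(
                    zip(grp["start"], grp["end"], grp["region_id"])
                )
        return self._trees.get(chrom, IntervalTree())

    @classmethod
    def from_bed(cls, name: str, bed: pd.DataFrame) -> "RegionSet":
        df = bed.copy()
        if "name" in df.columns:
            df = df.rename(columns={"name": "region_id"})
        else:
            df["region_id"] = [f"{name}_{i}" for i in range(len(df))]
        return cls(name=name, regions=df[["region_id", "chrom", "start", "end"]])

    @classmethod
    def from_fragments(cls, name: str, fragments: pd.DataFrame) -> "RegionSet":
        df = fragments.rename(columns={"fragment_id": "region_id"})
        return cls(name=name, regions=df[["region_id", "chrom", "start", "end"]])


def overlap_min_bp(
    regions: RegionSet, track: RegionSet, min_bp: int = DEFAULT_MIN_OVERLAP_BP
) -> pd.Series:
    """Per-region flag: does any single track interval overlap >= min_bp?

    The threshold applies to each track interval separately; two short
    overlaps with different intervals do not add up.  The relation is not
    symmetric in general: a region can clear the threshold against a
    track whose own intervals, queried the other way around, would not.
    """
    flags = []
    for row in regions.regions.itertuples():
        tree = track.tree(row.chrom)
        hit = any(
            min(row.end, iv.end) - max(row.start, iv.begin) >= min_bp
            for iv in tree.overlap(row.start, row.end)
        )
        flags.append(hit)
    return pd.Series(flags, index=regions.regions["region_id"].to_numpy(), name=track.name)


def enrichment_chi_squared(
    k_sel: int, n_sel: int, k_rest: int, n_rest: int
) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on a 2x2 table.

    Rows are selected vs remaining regions, columns overlap vs no
    overlap.  Returns (chi2, two-sided P).
    """
    if min(k_sel, k_rest) < 0 or n_sel <= 0 or n_rest <= 0:
        raise ValueError("counts must be non-negative with positive totals")
    if k_sel > n_sel or k_rest > n_rest:
        raise ValueError("overlap count exceeds set size")
    table = np.array([[k_sel, n_sel - k_sel], [k_rest, n_rest - k_rest]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: an expected cell is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def enrichment_table(
    selected: RegionSet,
    universe: RegionSet,
    tracks: dict[str, RegionSet],
    min_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> pd.DataFrame:
    """Enrichment grid of a selected region set against each track.

    ``universe`` holds every informative region; the comparison group is
    the universe minus the selected set.  Output mirrors the standard
    report: per track the overlap counts, percentages, chi2 and P.
    """
    sel_ids = selected.ids
    rest = RegionSet(
        name=f"{universe.name}_minus_{selected.name}",
        regions=universe.regions[~universe.regions["region_id"].isin(sel_ids)],
    )
    rows = []
    for name, track in tracks.items():
        k_sel = int(overlap_min_bp(selected, track, min_bp).sum())
        k_rest = int(overlap_min_bp(rest, track, min_bp).sum())
        chi2, p = enrichment_chi_squared(k_sel, len(selected), k_rest, len(rest))
        rows.append(
            {
                "track": name,
                "selected_total": len(selected),
                "selected_overlap": k_sel,
                "selected_pct": 100.0 * k_sel / len(selected),
                "rest_total": len(rest),
                "rest_overlap": k_rest,
                "rest_pct": 100.0 * k_rest / len(rest),
                "chi2": chi2,
                "P": p,
            }
        )
    return pd.DataFrame(rows)


def filter_premarked(
    regions: RegionSet,
    h3k27me3_track: RegionSet,
    min_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> tuple[RegionSet, int]:
    """Drop regions pre-marked by H3K27me3 (>= min_bp overlap).

    Pre-marked loci are likely silenced already during differentiation,
    so their methylation is uninformative for tumor-specific silencing.
    Returns the filtered set and the number of regions removed.
    """
    marked = overlap_min_bp(regions, h3k27me3_track, min_bp)
    keep = regions.regions[~regions.regions["region_id"].map(marked)]
    return RegionSet(name=regions.name, regions=keep.reset_index(drop=True)), int(marked.sum())


def assign_promoters(
    regions: RegionSet,
    genes: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 500,
    min_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> pd.DataFrame:
    """Map regions to genes; flag promoter overlaps.

    The promoter window is [TSS - upstream, TSS + downstream) in the
    gene's reading direction (strand-aware).  A region is gene-assigned
    when it overlaps the gene body by >= min_bp and promoter-assigned
    when it overlaps the promoter window by >= min_bp; a region may map
    to several genes (one output row each).
    """
    req = {"gene", "chrom", "start", "end", "strand", "tss"}
    if req - set(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(req)}")
    prom = genes.copy()
    plus = prom["strand"] == "+"
    prom["p_start"] = np.where(plus, prom["tss"] - upstream, prom["tss"] - downstream)
    prom["p_end"] = np.where(plus, prom["tss"] + downstream, prom["tss"] + upstream)
    prom["p_start"] = prom["p_start"].clip(lower=0)

    body = RegionSet(
        "gene_bodies",
        prom.rename(columns={"gene": "region_id"})[["region_id", "chrom", "start", "end"]],
    )
    win = RegionSet(
        "promoters",
        prom.rename(columns={"gene": "region_id", "p_start": "start2"})
        .assign(start=lambda d: d["start2"], end=lambda d: d["p_end"])
        [["region_id", "chrom", "start", "end"]],
    )
    rows = []
    for row in regions.regions.itertuples():
        hits: dict[str, bool] = {}
        for gene_set, is_promoter in ((body, False), (win, True)):
            tree = gene_set.tree(row.chrom)
            for iv in tree.overlap(row.start, row.end):
                if min(row.end, iv.end) - max(row.start, iv.begin) >= min_bp:
                    hits[iv.data] = hits.get(iv.data, False) or is_promoter
        for gene, promoter in sorted(hits.items()):
            rows.append(
                {"region_id": row.region_id, "gene": gene, "promoter": promoter}
            )
    return pd.DataFrame(rows, columns=["region_id", "gene", "promoter"])


def venn_overlap(set_a: RegionSet, set_b: RegionSet) -> tuple[int, int, int]:
    """Counts (a_only, shared, b_only), keyed by region id."""
    a, b = set_a.ids, set_b.ids
    return len(a - b), len(a & b), len(b - a)
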