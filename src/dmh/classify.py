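"""Rule-based CIMP calling and the copy-number exclusion filter.

A tumor is CIMP-positive when two or more CIMP1 markers (BRAF mutation,
methylated MLH1, TIMP3, MINT1, PRDM2/RIZ1) or three or more CIMP2
markers (KRAS mutation, methylated MINT27, MINT2, MINT31, LRP2/megalin)
are present, and CIMP-negative when two or more negative markers (TP53
mutation, unmethylated MINT27, MINT2, MINT31, MINT1) are present;
otherwise the call is undetermined.  The positive rule is evaluated
first when both would fire.

Apparent hypomethylation of group-specific regions in the wildtype group
is more plausibly chromosomal loss; the copy-number filter excludes
regions whose wildtype-group median log2 ratio falls below the
population median minus one standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CIMP1_MARKERS, CIMP2_MARKERS, NEGATIVE_MARKERS

#: marker pairs that cannot both be present
_CONTRADICTORY = (
    ("MINT27_meth", "MINT27_unmeth"),
    ("MINT2_meth", "MINT2_unmeth"),
    ("MINT31_meth", "MINT31_unmeth"),
    ("MINT1_meth", "MINT1_unmeth"),
)

CIMP_POS_MIN_CIMP1 = 2
CIMP_POS_MIN_CIMP2 = 3
CIMP_NEG_MIN = 2


@dataclass(frozen=True)
class CIMPCall:
    sample_id: str
    call: str               # positive / negative / undetermined
    rule: str               # which rule fired
    n_cimp1: int
    n_cimp2: int
    n_negative: int


def _count(profile: dict[str, str], markers: tuple[str, ...]) -> int:
    """Count markers present; unknown states are excluded from counts."""
    return sum(1 for m in markers if profile.get(m, "unknown") == "yes")


def classify_cimp(profile: dict[str, str], sample_id: str = "") -> CIMPCall:
    """Classify one sample from its tri-state marker profile.

    ``profile`` maps marker name to ``"yes"``/``"no"``/``"unknown"``.
    Positive iff #CIMP1 >= 2 or #CIMP2 >= 3; else negative iff
    #negative >= 2; else undetermined.
    """
    for a, b in _CONTRADICTORY:
        if profile.get(a) == "yes" and profile.get(b) == "yes":
            raise ValueError(
                f"contradictory marker states: {a} and {b} both present"
                + (f" for sample {sample_id}" if sample_id else "")
            )
    n1 = _count(profile, CIMP1_MARKERS)
    n2 = _count(profile, CIMP2_MARKERS)
    nn = _count(profile, NEGATIVE_MARKERS)
    if n1 >= CIMP_POS_MIN_CIMP1:
        call, rule = "positive", "cimp1"
    elif n2 >= CIMP_POS_MIN_CIMP2:
        call, rule = "positive", "cimp2"
    elif nn >= CIMP_NEG_MIN:
        call, rule = "negative", "negative"
    else:
        call, rule = "undetermined", "none"
    return CIMPCall(sample_id, call, rule, n1, n2, nn)


def classify_panel(markers: pd.DataFrame) -> pd.DataFrame:
    """Classify every sample of a marker-panel table (one row per sample)."""
    calls = []
    for _, row in markers.iterrows():
        profile = {k: v for k, v in row.items() if k != "sample_id"}
        c = classify_cimp(profile, sample_id=row["sample_id"])
        calls.append(
            {
                "sample_id": c.sample_id, "call": c.call, "rule": c.rule,
                "n_cimp1": c.n_cimp1, "n_cimp2": c.n_cimp2, "n_negative": c.n_negative,
            }
        )
    return pd.DataFrame(calls)


def copy_number_filter(
    regions: pd.DataFrame | list[str],
    wildtype_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude likely copy-number-loss regions from a region list.

    For each region the statistic is the median log2 ratio over the
    wildtype samples; with population median ``m`` and sample standard
    deviation ``s`` (n-1 denominator) of these statistics, a region is
    excluded iff its statistic < m - s.

    ``regions`` is a list of fragment ids (or a DataFrame with a
    ``fragment_id`` column); ``wildtype_matrix`` holds the wildtype
    samples' log2 ratios indexed by fragment.  Returns (report, retained)
    where the report lists statistic, threshold and decision per region.
    """
    ids = (
        list(regions["fragment_id"])
        if isinstance(regions, pd.DataFrame)
        else list(regions)
    )
    if len(ids) < 2:
        raise ValueError("copy-number filter needs at least 2 regions (SD undefined)")
    missing = [i for i in ids if i not in wildtype_matrix.index]
    if missing:
        raise ValueError(f"regions absent from the ratio matrix: {missing[:5]}")
    stat = wildtype_matrix.loc[ids].median(axis=1)
    m = float(stat.median())
    s = float(stat.std(ddof=1))
    threshold = m - s
    report = pd.DataFrame(
        {
            "fragment_id": ids,
            "statistic": stat.to_numpy(),
            "median": m,
            "sd": s,
            "threshold": threshold,
            "excluded": (stat < threshold).to_numpy(),
        }
    )
    retained = report[~report["excluded"]].reset_index(drop=True)
    return report, retained
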