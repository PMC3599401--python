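"""Downstream statistics: gene-set enrichment and bisulfite validation.

Gene-set enrichment is a generic exact binomial upper-tail test over a
user-supplied GMT collection (expected hits = n_query * |set| / U).
Bisulfite validation averages per-CpG methylation per sample over the
detected (non-missing) CpGs, subtracts the matched normal, and compares
BRAF-mutant with wildtype tumors by a one-sided Mann-Whitney test, exact
by enumeration for the small group sizes the design uses.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_LIMIT = 400  # exact enumeration when n1*n2 <= this


def binomial_enrichment(
    query: set[str], gene_set: set[str], universe: set[str]
) -> tuple[float, int, float]:
    """Exact binomial over-representation of ``gene_set`` in ``query``.

    Returns (expected, observed, P) where expected = n_q * |set| / U and
    P = P(X >= observed) for X ~ Binomial(n_q, |set|/U), by exact
    summation.  Genes outside the universe are ignored.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    q = query & universe
    gs = gene_set & universe
    n_q = len(q)
    if n_q > len(universe):
        raise ValueError("query larger than universe")
    p = len(gs) / len(universe)
    observed = len(q & gs)
    if observed > n_q:
        raise ValueError("observed hits exceed query size")
    expected = n_q * p
    p_value = float(sps.binom.sf(observed - 1, n_q, p)) if observed > 0 else 1.0
    return expected, observed, p_value


def enrichment_report(
    query: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    rows = []
    for name, gs in gene_sets.items():
        expected, observed, p = binomial_enrichment(query, gs, universe)
        rows.append(
            {
                "set": name, "set_size": len(gs & universe),
                "expected": expected, "observed": observed, "P": p,
            }
        )
    return pd.DataFrame(rows).sort_values("P", kind="stable").reset_index(drop=True)


def bsa_average_and_subtract(
    tumor: pd.DataFrame, normal: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample mean methylation over detected CpGs, normal-subtracted.

    ``tumor`` and ``normal`` are samples x CpGs percentage matrices with
    NaN for not-detected cells; matching is by sample index.  Negative
    differences are retained.  Samples with no detected CpG in either
    tissue are flagged ``excluded`` and carry NaN.
    """
    if not tumor.index.equals(normal.index):
        raise ValueError("tumor and normal tables must share the sample index")
    t_mean = tumor.mean(axis=1, skipna=True)
    n_mean = normal.mean(axis=1, skipna=True)
    diff = t_mean - n_mean
    excluded = t_mean.isna() | n_mean.isna()
    return pd.DataFrame(
        {
            "tumor_mean": t_mean,
            "normal_mean": n_mean,
            "difference": diff.where(~excluded),
            "excluded": excluded,
        }
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_one_sided(
    wildtype: np.ndarray, mutant: np.ndarray
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of mutant > wildtype.

    Returns (U, P) where U counts mutant-over-wildtype wins (ties half).
    For small problems (n1*n2 <= 400) the P-value is exact by
    enumerating all group assignments of the pooled midranks, which
    handles ties correctly; larger problems use the normal approximation
    with tie correction.
    """
    w = np.asarray(wildtype, dtype=float)
    m = np.asarray(mutant, dtype=float)
    w, m = w[~np.isnan(w)], m[~np.isnan(m)]
    if len(w) == 0 or len(m) == 0:
        raise ValueError("need at least one value per group")
    n_w, n_m = len(w), len(m)
    pooled = np.concatenate([m, w])
    ranks = _midranks(pooled)
    r_m = ranks[:n_m].sum()
    u = r_m - n_m * (n_m + 1) / 2
    if n_w * n_m <= EXACT_MW_LIMIT:
        total = comb(n_w + n_m, n_m)
        count = 0
        idx = np.arange(n_w + n_m)
        for chosen in combinations(idx, n_m):
            if ranks[list(chosen)].sum() >= r_m - 1e-9:
                count += 1
        p = count / total
    else:
        _, p = sps.mannwhitneyu(m, w, alternative="greater", method="asymptotic")
        p = float(p)
    return float(u), p
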