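"""Two-color array preprocessing.

Turns raw dye-swap scan pairs into one tumor/normal log2 ratio per
fragment per sample, in the order the method prescribes: within-array
LOESS normalization of M against A, between-array aquantile
normalization (A only), dye-bias cancellation by the dye-swap
half-difference, and median-per-fragment summarization.  No background
correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_PROBES_FOR_LOESS = 50
LOESS_GRID_POINTS = 200


def compute_ma(scan: pd.DataFrame) -> pd.DataFrame:
    """Attach raw M = log2(ch1/ch2) and A = (log2 ch1 + log2 ch2)/2."""
    out = scan.copy()
    if (out["ch1"] <= 0).any() or (out["ch2"] <= 0).any():
        raise ValueError("channel intensities must be strictly positive")
    l1 = np.log2(out["ch1"].to_numpy())
    l2 = np.log2(out["ch2"].to_numpy())
    out["M"] = l1 - l2
    out["A"] = (l1 + l2) / 2
    return out


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def loess_fit(
    a: np.ndarray,
    m: np.ndarray,
    span: float = 0.3,
    robustness_iters: int = 4,
    degree: int = 3,
) -> np.ndarray:
    """Robust LOESS fit of M on A, evaluated at every A.

    Local polynomial regression with tricube weights over the ``span``
    nearest neighbours, evaluated on a quantile-plus-uniform grid and
    interpolated.  The default local basis is cubic: odd degrees keep
    their interior bias order at the support boundary, and a cubic basis
    absorbs the strongest intensity trend two-color scanners produce.
    Robustness iterations reweight by the bisquare of scaled residuals,
    so strong differential signals (large residuals) do not bend the
    trend.  With ``span=1`` and ``degree`` >= 1 on exactly linear data
    the fit equals ordinary linear regression.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(a)
    if n < MIN_PROBES_FOR_LOESS:
        raise ValueError(
            f"need at least {MIN_PROBES_FOR_LOESS} probes for the local fit, got {n}"
        )
    a = np.asarray(a, dtype=float)
    m = np.asarray(m, dtype=float)
    order = np.argsort(a, kind="stable")
    a_s, m_s = a[order], m[order]
    k = max(int(round(span * n)), degree + 2)
    k = min(k, n)
    # evaluation grid: A quantiles (dense where data are dense) plus a
    # uniform component so sparse tails are not bridged by interpolation
    qs = np.linspace(0.0, 1.0, min(LOESS_GRID_POINTS, n))
    grid = np.unique(
        np.concatenate(
            [np.quantile(a_s, qs),
             np.linspace(a_s[0], a_s[-1], LOESS_GRID_POINTS // 2)]
        )
    )
    robust = np.ones(n)
    fit_s = np.zeros(n)
    for iteration in range(max(1, robustness_iters + 1)):
        gfit = np.empty(len(grid))
        for gi, x0 in enumerate(grid):
            # k nearest neighbours are contiguous in the sorted order
            left = np.searchsorted(a_s, x0)
            lo = max(0, left - k)
            hi = min(n, left + k)
            d = np.abs(a_s[lo:hi] - x0)
            if hi - lo > k:
                cut = np.partition(d, k - 1)[k - 1]
                keep = d <= cut
            else:
                keep = slice(None)
            x = a_s[lo:hi][keep]
            y = m_s[lo:hi][keep]
            dd = np.abs(x - x0)
            h = dd.max()
            w = (_tricube(dd / h) if h > 0 else np.ones_like(dd)) * robust[lo:hi][keep]
            if w.sum() <= 0:
                gfit[gi] = gfit[gi - 1] if gi else 0.0
                continue
            xc = x - x0
            basis = np.vander(xc, degree + 1, increasing=True)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(basis * sw[:, None], y * sw, rcond=None)
            gfit[gi] = coef[0]
        fit_s = np.interp(a_s, grid, gfit)
        resid = m_s - fit_s
        scale = np.median(np.abs(resid))
        if scale == 0 or iteration == robustness_iters:
            break
        new_robust = np.clip(1.0 - (resid / (6.0 * scale)) ** 2, 0.0, None) ** 2
        # bisquare assumes minority contamination; when most points would be
        # down-weighted (near-noiseless data) reweighting is meaningless
        if (new_robust < 0.5).mean() > 0.3:
            break
        robust = new_robust
    fit = np.empty(n)
    fit[order] = fit_s
    return fit


def loess_within(
    scan: pd.DataFrame, span: float = 0.3, robustness_iters: int = 4
) -> pd.DataFrame:
    """Within-array normalization: replace M by M − loess_fit(M ~ A)."""
    out = scan if "M" in scan.columns else compute_ma(scan)
    out = out.copy()
    fit = loess_fit(out["A"].to_numpy(), out["M"].to_numpy(), span, robustness_iters)
    out["M"] = out["M"] - fit
    return out


def _quantile_reference(a_matrix: np.ndarray) -> np.ndarray:
    """Mean of the sorted A vectors across arrays (the aquantile target)."""
    return np.sort(a_matrix, axis=0).mean(axis=1)


def aquantile_between(scans: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Quantile-normalize A across arrays; M is left bitwise unchanged.

    After the operation the sorted A vector is identical on every array;
    tied A values within an array receive the mean of the reference
    values at the tied ranks.
    """
    if not scans:
        return []
    n = len(scans[0])
    if any(len(s) != n for s in scans):
        raise ValueError("arrays must share one probe set for aquantile normalization")
    a_matrix = np.column_stack([s["A"].to_numpy(dtype=float) for s in scans])
    ref = _quantile_reference(a_matrix)
    out = []
    for j, scan in enumerate(scans):
        a = a_matrix[:, j]
        order = np.argsort(a, kind="stable")
        new_a = np.empty(n)
        new_a[order] = ref
        # average reference values over ties
        s = pd.Series(new_a)
        new_a = s.groupby(a).transform("mean").to_numpy()
        scan = scan.copy()
        scan["A"] = new_a
        out.append(scan)
    return out


def combine_dye_swap(scan_fwd: pd.DataFrame, scan_rev: pd.DataFrame) -> pd.DataFrame:
    """Dye-bias-corrected per-probe M from a dye-swap pair.

    Both scans carry raw M = log2(ch1/ch2).  With the tumor in channel 1
    on the forward array and in channel 2 on the reverse array, the
    tumor/normal ratio enters the two raw Ms with opposite sign while any
    probe-specific additive dye effect enters both with the same sign, so
    ``(M_fwd − M_rev) / 2`` is the tumor/normal log ratio with the dye
    term cancelled exactly.
    """
    for scan in (scan_fwd, scan_rev):
        if "M" not in scan.columns:
            raise ValueError("scans must carry M (run compute_ma first)")
    o_fwd = scan_fwd["orientation"].iloc[0]
    o_rev = scan_rev["orientation"].iloc[0]
    if o_fwd == o_rev:
        raise ValueError(
            f"dye-swap pair must have opposite orientations, both are {o_fwd!r}"
        )
    if o_fwd != "tumor_in_ch1":
        scan_fwd, scan_rev = scan_rev, scan_fwd
    fwd = scan_fwd.set_index("probe_id")
    rev = scan_rev.set_index("probe_id")
    if not fwd.index.equals(rev.index):
        offenders = sorted(set(fwd.index).symmetric_difference(rev.index))
        raise ValueError(f"mismatched probe sets in dye-swap pair: {offenders[:10]}")
    return pd.DataFrame(
        {
            "probe_id": fwd.index,
            "sample_id": scan_fwd["sample_id"].iloc[0],
            "M": (fwd["M"].to_numpy() - rev["M"].to_numpy()) / 2.0,
        }
    )


def summarize_fragments(
    probe_m: pd.DataFrame, probe_map: pd.DataFrame
) -> pd.DataFrame:
    """Median log ratio per fragment per sample (NormalizedMatrix).

    ``probe_m`` holds columns probe_id/sample_id/M; ``probe_map`` maps
    probe_id to fragment_id (unmapped probes are dropped).  An even probe
    count yields the mean of the two central values; fragments with no
    surviving probe are absent from the output (and counted in the log).
    """
    mapping = probe_map.dropna(subset=["fragment_id"])[["probe_id", "fragment_id"]]
    merged = probe_m.merge(mapping, on="probe_id", how="inner")
    n_dropped = probe_m["probe_id"].nunique() - merged["probe_id"].nunique()
    if n_dropped:
        logger.info("dropped %d probes without fragment assignment", n_dropped)
    matrix = (
        merged.groupby(["fragment_id", "sample_id"], sort=True)["M"]
        .median()
        .unstack("sample_id")
    )
    matrix.index.name = "fragment_id"
    return matrix


def normalize_experiment(
    scans: pd.DataFrame,
    probe_map: pd.DataFrame,
    span: float = 0.3,
    robustness_iters: int = 4,
    loess: bool = True,
    aquantile: bool = True,
) -> pd.DataFrame:
    """Full preprocessing of a long-format scan table to a NormalizedMatrix.

    Pipeline order: within-array LOESS, between-array aquantile (A only),
    dye-swap combination, median-per-fragment summarization.  ``loess``
    and ``aquantile`` toggles exist for controlled experiments.
    """
    per_array = [g.reset_index(drop=True) for _, g in scans.groupby("array_id", sort=True)]
    per_array = [compute_ma(s) for s in per_array]
    if loess:
        per_array = [loess_within(s, span, robustness_iters) for s in per_array]
    if aquantile:
        per_array = [
            s.sort_values("probe_id", kind="stable").reset_index(drop=True)
            for s in per_array
        ]
        per_array = aquantile_between(per_array)
    by_sample: dict[str, dict[str, pd.DataFrame]] = {}
    for scan in per_array:
        sample = scan["sample_id"].iloc[0]
        orient = scan["orientation"].iloc[0]
        by_sample.setdefault(sample, {})[orient] = scan
    corrected = []
    for sample, pair in sorted(by_sample.items()):
        if set(pair) != {"tumor_in_ch1", "tumor_in_ch2"}:
            raise ValueError(f"sample {sample} lacks a complete dye-swap pair")
        corrected.append(combine_dye_swap(pair["tumor_in_ch1"], pair["tumor_in_ch2"]))
    return summarize_fragments(pd.concat(corrected, ignore_index=True), probe_map)
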