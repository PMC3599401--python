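"""Per-fragment linear modeling with empirical-Bayes variance moderation.

Each fragment's tumor/normal log2 ratios are fit by ordinary least
squares against a small design (intercept-only for tumor-vs-normal, a
two-group design for CIMP and BRAF contrasts).  Residual variances are
shrunk toward a common prior estimated by matching the moments of
``log s²`` to scaled-F theory (trigamma inversion), giving a moderated
t-statistic with ``d0 + d`` degrees of freedom.  Regions are selected by
Benjamini-Hochberg FDR at an inclusive threshold of 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

CONTRASTS = ("tumor", "cimp", "braf")


@dataclass(frozen=True)
class ModerationPrior:
    """Prior degrees of freedom and variance of the moderation model."""

    d0: float           # may be math.inf
    s0_sq: float

    def posterior_s2(self, s2: np.ndarray, d: np.ndarray) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + d * s2) / (self.d0 + d)


def make_design(samples: pd.DataFrame, contrast: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and contrast vector for one comparison.

    The matrix of tumor/normal ratios already encodes the tumor-vs-normal
    comparison, so that contrast is an intercept-only model; group
    contrasts add a group indicator column and test its coefficient.
    """
    n = len(samples)
    if contrast == "tumor":
        x = pd.DataFrame({"intercept": np.ones(n)}, index=samples["sample_id"])
        c = np.array([1.0])
    elif contrast == "cimp":
        ind = (samples["cimp"] == "positive").astype(float).to_numpy()
        x = pd.DataFrame({"intercept": np.ones(n), "cimp_pos": ind},
                         index=samples["sample_id"])
        c = np.array([0.0, 1.0])
    elif contrast == "braf":
        ind = (samples["braf"] == "mutant").astype(float).to_numpy()
        x = pd.DataFrame({"intercept": np.ones(n), "braf_mut": ind},
                         index=samples["sample_id"])
        c = np.array([0.0, 1.0])
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    return x, c


def _ols_block(y: np.ndarray, x: np.ndarray, c: np.ndarray):
    """Vectorized OLS of many responses (rows of y) on one design."""
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank-deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T                   # (m, p)
    resid = y - beta @ x.T
    d = n - p
    s2 = (resid ** 2).sum(axis=1) / d if d > 0 else np.full(len(y), np.nan)
    effect = beta @ c
    v = float(c @ xtx_inv @ c)
    return effect, s2, d, v


def fit_linear_model(
    matrix: pd.DataFrame, design: pd.DataFrame, contrast_vector: np.ndarray
) -> pd.DataFrame:
    """Per-fragment OLS fit of the normalized matrix against ``design``.

    Fragments with missing samples are refit on the available samples
    with a correspondingly reduced residual df; fragments whose reduced
    design loses rank or leaves ``d < 1`` get NaN results.  Returns one
    row per fragment: effect, s2, d, v (unscaled coefficient variance).
    """
    design = design.loc[matrix.columns]
    y = matrix.to_numpy(dtype=float)
    x = design.to_numpy(dtype=float)
    out = pd.DataFrame(index=matrix.index, columns=["effect", "s2", "d", "v"],
                       dtype=float)
    mask = ~np.isnan(y)
    if mask.all():
        effect, s2, d, v = _ols_block(y, x, contrast_vector)
        out["effect"], out["s2"], out["d"], out["v"] = effect, s2, d, v
        return out
    # group fragments by missingness pattern and refit per pattern
    patterns = pd.DataFrame(mask, index=matrix.index).groupby(list(range(y.shape[1])))
    for pattern, idx in patterns.groups.items():
        keep = np.array(pattern, dtype=bool)
        rows = matrix.index.get_indexer(idx)
        x_sub = x[keep]
        if keep.sum() - x.shape[1] < 1 or np.linalg.matrix_rank(x_sub) < x.shape[1]:
            continue
        effect, s2, d, v = _ols_block(y[np.ix_(rows, np.where(keep)[0])], x_sub,
                                      contrast_vector)
        out.iloc[rows, 0] = effect
        out.iloc[rows, 1] = s2
        out.iloc[rows, 2] = d
        out.iloc[rows, 3] = v
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a monotone function)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_eb_prior(s2: np.ndarray, d: np.ndarray | float) -> ModerationPrior:
    """Estimate (d0, s0²) by moment-matching log residual variances.

    Under the scaled-F model, ``log s²`` has variance
    ``trigamma(d/2) + trigamma(d0/2)`` around its mean; the excess of the
    empirical variance over the sampling term identifies d0 by trigamma
    inversion, and the mean then identifies s0² through the digamma
    correction.  When the empirical variance does not exceed the sampling
    term, d0 is infinite and s0² is the (bias-corrected) mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if ok.sum() < 30:
        raise ValueError(
            f"need at least 30 positive residual variances, got {int(ok.sum())}"
        )
    s2, d = s2[ok], d[ok]
    if np.allclose(s2, s2[0]):
        return ModerationPrior(d0=math.inf, s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, d / 2).mean()
    if excess <= 0:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(float(excess))
    d0 = 2 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - math.log(half_d0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_test(
    effect: np.ndarray,
    s2: np.ndarray,
    d: np.ndarray | float,
    prior: ModerationPrior,
    v: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided P with ``d0 + d`` degrees of freedom.

    ``prior.d0 = 0`` reduces to the ordinary t-test; infinite d0 gives a
    z-like test against s0.
    """
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), effect.shape)
    v = np.broadcast_to(np.asarray(v, dtype=float), effect.shape)
    s2_post = prior.posterior_s2(s2, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * v)
    if math.isinf(prior.d0):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=prior.d0 + d)
    p = np.where(effect == 0, 1.0, p)
    return t, p


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (cumulative minimum)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_contrast(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: str,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Full moderated analysis of one contrast on a NormalizedMatrix.

    Returns per-fragment effect, s2, moderated t, P, BH FDR and the
    selection flag (FDR <= threshold, inclusive).  Fragments that could
    not be fit (insufficient non-missing samples) are dropped with their
    count recorded in ``DataFrame.attrs['n_unfit']``.
    """
    design, c = make_design(samples, contrast)
    fit = fit_linear_model(matrix, design, c)
    unfit = fit["effect"].isna()
    fit = fit[~unfit]
    prior = estimate_eb_prior(fit["s2"].to_numpy(), fit["d"].to_numpy())
    t, p = moderated_test(
        fit["effect"].to_numpy(), fit["s2"].to_numpy(), fit["d"].to_numpy(),
        prior, fit["v"].to_numpy(),
    )
    res = pd.DataFrame(
        {
            "fragment_id": fit.index,
            "contrast": contrast,
            "effect": fit["effect"].to_numpy(),
            "s2": fit["s2"].to_numpy(),
            "t": t,
            "P": p,
            "FDR": bh_fdr(p),
        }
    )
    res["selected"] = res["FDR"] <= fdr_threshold
    res.attrs["n_unfit"] = int(unfit.sum())
    res.attrs["prior_d0"] = prior.d0
    res.attrs["prior_s0_sq"] = prior.s0_sq
    return res


def select_dmrs(results: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Rows of ``results`` passing the FDR threshold (inclusive)."""
    return results[results["FDR"] <= threshold].reset_index(drop=True)
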