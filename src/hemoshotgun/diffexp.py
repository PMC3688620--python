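"""Negative-binomial differential abundance from spectral counts.

Two-column (fed vs starved) count matrices, median-of-ratios size
factors, a mean-dispersion relationship fitted by local regression with
the two samples pooled as pseudo-replicates, and a two-sided conditional
exact test on each row's count split.  No multiple-testing adjustment is
applied by default; ranking is by raw p-value and the top decile is
flagged with its fold-change direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

_MIN_DISPERSION = 1e-8


class DiffExpError(ValueError):
    pass


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only rows with nonzero counts in every sample enter the median.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise DiffExpError("negative counts")
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise DiffExpError("no row with nonzero counts in all samples")
    sub = mat[nonzero]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return factors


def fit_dispersion(
    normalized: pd.DataFrame,
    span: float = 0.7,
    min_rows_local: int = 50,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit dispersion as a smooth function of the mean normalized count.

    Per-row method-of-moments estimates ``(var - mean) / mean^2`` (samples
    pooled as pseudo-replicates — the no-replicate design) are smoothed
    against log mean by tricube-weighted local linear regression; a
    hyperbolic parametric fit ``a0 + a1/mean`` is used below
    ``min_rows_local`` rows.  The returned callable clips at a small
    positive floor.
    """
    mat = normalized.to_numpy(dtype=float)
    if mat.shape[0] < 10:
        raise DiffExpError("need at least 10 rows to fit dispersion")
    means = mat.mean(axis=1)
    variances = mat.var(axis=1, ddof=1)
    ok = means > 0
    m, v = means[ok], variances[ok]
    if len(m) == 0 or np.allclose(v, 0) and np.allclose(m, m[0]):
        warnings.warn("degenerate count matrix; using constant dispersion fallback")
        return lambda q: np.full_like(np.asarray(q, dtype=float), 0.01)
    raw = (v - m) / m**2

    x = np.log(m)
    if len(m) >= min_rows_local:
        order = np.argsort(x)
        xs, ys = x[order], raw[order]
        # fit at each observed point, interpolate between them afterwards
        k = max(int(np.ceil(span * len(xs))), 2)
        fitted = np.empty_like(xs)
        for i, x0 in enumerate(xs):
            d = np.abs(xs - x0)
            h = np.sort(d)[k - 1]
            w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, 1) ** 3
            W = w > 0
            xw, yw, ww = xs[W], ys[W], w[W]
            X = np.column_stack([np.ones_like(xw), xw - x0])
            A = X.T @ (X * ww[:, None])
            b = X.T @ (yw * ww)
            try:
                beta = np.linalg.solve(A, b)
                fitted[i] = beta[0]
            except np.linalg.LinAlgError:  # pragma: no cover
                fitted[i] = np.average(yw, weights=ww)
        grid_x, grid_y = xs, fitted

        def disp(q):
            q = np.asarray(q, dtype=float)
            val = np.interp(np.log(np.maximum(q, 1e-12)), grid_x, grid_y)
            return np.maximum(val, _MIN_DISPERSION)

        return disp

    # parametric fallback: alpha(m) = a0 + a1/m by least squares
    X = np.column_stack([np.ones_like(m), 1.0 / m])
    beta, *_ = np.linalg.lstsq(X, raw, rcond=None)

    def disp(q):
        q = np.asarray(q, dtype=float)
        val = beta[0] + beta[1] / np.maximum(q, 1e-12)
        return np.maximum(val, _MIN_DISPERSION)

    return disp


def _nb_logpmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """log PMF of NB with var = mean + dispersion * mean^2 (Poisson at 0)."""
    if mean <= 0:
        out = np.full_like(np.asarray(k, dtype=float), -np.inf)
        out[np.asarray(k) == 0] = 0.0
        return out
    if dispersion < 1e-10:
        return stats.poisson.logpmf(k, mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return stats.nbinom.logpmf(k, size, p)


def nb_exact_test(
    k_a: int,
    k_b: int,
    size_factor_a: float,
    size_factor_b: float,
    dispersion_fn: Callable[[np.ndarray], np.ndarray],
) -> float:
    """Two-sided conditional exact test of equal abundance.

    Conditions on the total ``k_a + k_b``; sums the probability of all
    splits no more probable than the observed one, under independent NB
    marginals with means proportional to the size factors and dispersion
    evaluated at the pooled normalized mean.
    """
    if k_a < 0 or k_b < 0:
        raise DiffExpError("negative counts")
    total = k_a + k_b
    if total == 0:
        return 1.0
    q0 = total / (size_factor_a + size_factor_b)
    mu_a = size_factor_a * q0
    mu_b = size_factor_b * q0
    alpha = float(np.atleast_1d(dispersion_fn(np.array([q0])))[0])

    ks = np.arange(total + 1)
    logp = _nb_logpmf(ks, mu_a, alpha) + _nb_logpmf(ks[::-1], mu_b, alpha)
    logp -= logp.max()
    p = np.exp(logp)
    obs = p[k_a]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum() / p.sum()))


@dataclass
class DiffExpResult:
    table: pd.DataFrame
    size_factors: np.ndarray
    normalization_caveat: str = (
        "size-factor normalization assumes comparable count composition; "
        "large global shifts in total protein between conditions are not "
        "corrected and should be interpreted with caution"
    )


def diff_expression(
    counts: pd.DataFrame,
    condition_a: str | None = None,
    condition_b: str | None = None,
    decile: float = 0.1,
    adjust: bool = True,
) -> DiffExpResult:
    """Full two-condition analysis on a two-column count matrix.

    Returns a table with mean normalized count, log2 fold change (B over
    A, exact ±Inf when one side's normalized count is zero), exact-test
    p-value, optional Benjamini-Hochberg column, rank and top-decile flag.
    """
    if counts.shape[1] != 2:
        raise DiffExpError("expected exactly two sample columns")
    if condition_a is None:
        condition_a, condition_b = counts.columns[:2]
    sf = size_factors(counts)
    norm = counts / sf
    disp = fit_dispersion(norm)
    a = counts[condition_a].to_numpy(dtype=int)
    b = counts[condition_b].to_numpy(dtype=int)
    i_a = list(counts.columns).index(condition_a)
    i_b = list(counts.columns).index(condition_b)
    pvals = np.array(
        [nb_exact_test(a[i], b[i], sf[i_a], sf[i_b], disp) for i in range(len(a))]
    )
    na = norm[condition_a].to_numpy()
    nb = norm[condition_b].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(nb / na)
    table = pd.DataFrame(
        {
            "id": counts.index,
            "base_mean": (na + nb) / 2,
            "log2fc": log2fc,
            "p_value": pvals,
        }
    )
    if adjust:
        table["padj"] = _benjamini_hochberg(pvals)
    table = rank_and_call(table, decile=decile)
    return DiffExpResult(table=table, size_factors=sf)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def rank_and_call(table: pd.DataFrame, decile: float = 0.1) -> pd.DataFrame:
    """Rank by ascending p-value and flag the top decile with direction.

    Ties are broken by larger ``|log2fc|`` then by id, so the output is a
    deterministic permutation.
    """
    if not 0 < decile <= 1:
        raise DiffExpError("decile must be in (0, 1]")
    t = table.copy()
    abs_fc = t["log2fc"].abs().fillna(0.0)
    abs_fc = abs_fc.replace(np.inf, np.finfo(float).max)
    t["_absfc"] = abs_fc
    t = t.sort_values(
        by=["p_value", "_absfc", "id"], ascending=[True, False, True], kind="mergesort"
    )
    t["rank"] = np.arange(1, len(t) + 1)
    n_flag = int(round(decile * len(t)))
    flagged = t["rank"] <= n_flag
    direction = np.where(t["log2fc"] > 0, "up", np.where(t["log2fc"] < 0, "down", ""))
    t["top_decile"] = flagged
    t["direction"] = np.where(flagged, direction, "")
    return t.drop(columns=["_absfc"]).reset_index(drop=True)
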