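"""Shared statistical primitives: BH step-up FDR, hypergeometric tails,
and many-to-one (Dunnett) multiple comparisons.

The Dunnett adjustment is computed from the equicorrelated multivariate-t
distribution of the comparison statistics (all treatment groups share the
control, giving correlation lambda_i*lambda_j between statistics). For
balanced designs the joint tail probability reduces to a two-dimensional
integral over the shared control variate and the pooled-variance chi
factor, which we evaluate by Gaussian quadrature; unbalanced designs fall
back to a seeded Monte-Carlo evaluation of the same probability.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln, ndtr

__all__ = [
    "bh_adjust",
    "hypergeom_sf",
    "dunnett_max_abs_cdf",
    "dunnett_adjusted_pvalues",
    "welch_ttest",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN inputs propagate to NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank down enforces monotonicity
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated entities in a size-``n`` draw from a universe of
    ``N`` entities of which ``K`` carry the annotation.
    """
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _chi_nodes(df: int, n_nodes: int = 48):
    """Quadrature nodes/weights for W where W**2 ~ chi2(df)/df."""
    lo = np.sqrt(stats.chi2.ppf(1e-10, df) / df)
    hi = np.sqrt(stats.chi2.ppf(1 - 1e-10, df) / df)
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    wv = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    half = 0.5 * (hi - lo) * w
    logpdf = (
        np.log(2.0)
        + 0.5 * df * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1) * np.log(wv)
        - df * wv**2 / 2.0
    )
    return wv, half * np.exp(logpdf)


def dunnett_max_abs_cdf(q, n_compare: int, df: int, lam: float = np.sqrt(0.5)):
    """P(max_i |T_i| <= q) for equicorrelated many-to-one t statistics.

    ``lam`` is the loading on the shared control variate; the pairwise
    correlation of the statistics is ``lam**2`` (0.5 for balanced designs).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(64)
    gh_w = gh_w / np.sqrt(2.0 * np.pi)
    wv, ww = _chi_nodes(df)
    s = np.sqrt(1.0 - lam * lam)
    # grid: (nq, n_w, n_z0)
    qw = q[:, None, None] * wv[None, :, None]
    lz = lam * gh_x[None, None, :]
    inner = ndtr((qw - lz) / s) - ndtr((-qw - lz) / s)
    np.clip(inner, 0.0, 1.0, out=inner)
    probs = np.einsum("ijk,j,k->i", inner**n_compare, ww, gh_w)
    return np.clip(probs, 0.0, 1.0)


def dunnett_adjusted_pvalues(
    t_obs,
    n_compare: int,
    df: int,
    lam: float = np.sqrt(0.5),
    *,
    grid_size: int = 600,
) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values for observed t statistics.

    Evaluates the joint CDF on a monotone grid once and interpolates, so
    large batches of proteins are adjusted at array speed.
    """
    t = np.abs(np.asarray(t_obs, dtype=float))
    finite = np.isfinite(t)
    out = np.full(t.shape, np.nan)
    if not finite.any():
        return out
    hi = max(10.0, np.nanmax(t[finite]) * 1.05)
    grid = np.concatenate([[0.0], np.geomspace(1e-3, hi, grid_size)])
    cdf = dunnett_max_abs_cdf(grid, n_compare, df, lam)
    cdf = np.maximum.accumulate(cdf)
    out[finite] = 1.0 - np.interp(t[finite], grid, cdf)
    return np.clip(out, 0.0, 1.0)


def dunnett_adjusted_pvalues_mc(
    t_obs, lams, df: int, *, n_draws: int = 200_000, seed: int = 0
) -> np.ndarray:
    """Seeded Monte-Carlo Dunnett adjustment for unbalanced designs.

    ``lams`` gives the control loading per comparison; the statistics are
    simulated from their joint multivariate-t law and the max-|T| null
    distribution is tabulated empirically.
    """
    lams = np.asarray(lams, dtype=float)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, lams.size))
    w = np.sqrt(rng.chisquare(df, n_draws) / df)
    tmax = np.max(
        np.abs(lams[None, :] * z0[:, None] + np.sqrt(1 - lams**2)[None, :] * z),
        axis=1,
    ) / w
    tmax.sort()
    t = np.abs(np.asarray(t_obs, dtype=float))
    ranks = np.searchsorted(tmax, t, side="right")
    return 1.0 - ranks / n_draws


def welch_ttest(a, b):
    """Two-tailed Welch t-test returning (t, p); degenerate zero-variance
    equal-mean input yields p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
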