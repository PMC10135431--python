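"""Shared statistical machinery.

Everything here is used by more than one analysis module: Benjamini-Hochberg
adjustment, empirical-Bayes variance moderation (limma-style shrinkage of
gene-wise residual variances toward a common prior), and the hypergeometric
upper-tail probability that backs both the over-representation analysis and
the splicing overlap test.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "bh_adjust",
    "fit_inverse_chisq_prior",
    "moderate_variances",
    "hypergeom_tail",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR).

    NaN entries are ignored for the ranking and propagated unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for the asymptotic regime
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_inverse_chisq_prior(s2, df):
    """Estimate the scaled inverse chi-square prior (d0, s0^2) for gene
    variances by the method of moments on log s^2.

    Given per-gene residual variances ``s2`` on ``df`` residual degrees of
    freedom, fits s^2 ~ s0^2 * F(df, d0) via the distribution of
    e = log(s2) - digamma(df/2) + log(df/2).  Returns ``d0 = inf`` when the
    observed spread of e is no larger than expected under a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    df = float(df)
    z = np.log(s2)
    if z.var(ddof=1) < 1e-12:
        # degenerate: every gene reports the same variance, no sampling
        # spread to model — the prior is a point mass there
        return np.inf, float(np.exp(z.mean()))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        half_d0 = _trigamma_inverse(np.array([e_var]))[0]
        d0 = 2.0 * half_d0
        s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def moderate_variances(s2, df):
    """Shrink gene-wise variances toward the fitted prior.

    Returns ``(s2_tilde, d0, s0_2)`` where
    ``s2_tilde = (d0*s0^2 + df*s2) / (d0 + df)`` (posterior mean of the
    variance), and the moderated test statistic gains ``d0`` extra degrees
    of freedom.
    """
    s2 = np.asarray(s2, dtype=float)
    d0, s0_2 = fit_inverse_chisq_prior(s2, df)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    return s2_tilde, d0, s0_2


def moderated_t_pvalues(effect, stderr_unit, s2_tilde, total_df):
    """Two-sided p-values for effect / (sqrt(s2_tilde) * stderr_unit).

    ``stderr_unit`` is the design-dependent standard-error multiplier
    (sqrt of the contrast's diagonal of (X'X)^-1).
    """
    effect = np.asarray(effect, dtype=float)
    se = np.sqrt(np.asarray(s2_tilde, dtype=float)) * np.asarray(stderr_unit, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.where(effect == 0, 0.0, np.inf))
    p = 2.0 * sps.t.sf(np.abs(t), total_df)
    # an exactly-zero effect is never evidence against the null
    p = np.where(effect == 0.0, 1.0, p)
    return t, np.clip(p, 0.0, 1.0)


def hypergeom_tail(k: int, universe: int, n_a: int, n_b: int, log: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a fixed set of size ``n_a`` and a random set
    of size ``n_b`` drawn without replacement from ``universe`` items — the
    one-sided Fisher exact test for enrichment.  Computed in log space so that
    astronomically small tails (e.g. 1e-250) remain representable via the
    returned log value.
    """
    if not (0 <= k <= min(n_a, n_b) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={k}, sets={n_a}/{n_b}, universe={universe}"
        )
    if k == 0:
        return 0.0 if log else 1.0
    logp = sps.hypergeom.logsf(k - 1, universe, n_a, n_b)
    return float(logp) if log else float(np.exp(logp))
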