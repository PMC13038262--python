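"""Post-hoc inference for group contrasts.

Pooled-variance two-sample t test (the df convention implied by reporting
t(259) for groups of 127 and 134), the default JZS Bayes factor for that
contrast under a zero-centered Cauchy prior on standardized effect size
(scale 0.707), and Pearson correlation for the age analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    bf10: float | None = None


def pooled_t(x, y, welch: bool = False) -> TestResult:
    """Two-sample t test; pooled (Student) variance by default.

    With pooled variance, df = n1 + n2 - 2.  ``welch=True`` switches to the
    unequal-variance form (df then non-integer, reported rounded down in the
    dataclass field).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both samples; t undefined")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = x.size + y.size - 2 if not welch else res.df
    return TestResult(t=float(res.statistic), df=int(df), p=float(res.pvalue))


def jzs_bf10(t: float, n1: int, n2: int, r_scale: float = 0.707) -> float:
    """JZS Bayes factor BF10 for a two-sample t statistic.

    Evidence for a group difference relative to the point null, with a
    Cauchy(0, ``r_scale``) prior on the standardized effect size d.  With
    effective sample size N = n1 n2 / (n1 + n2) and df = n1 + n2 - 2,

        BF10 = int T_df(t; ncp = d sqrt(N)) Cauchy(d; 0, r) dd / T_df(t; 0)

    evaluated by adaptive quadrature over the prior.  Symmetric in t <-> -t
    and strictly increasing in |t|.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least two observations")
    if r_scale <= 0:
        raise ValueError("Cauchy prior scale must be positive")
    t = float(t)
    df = n1 + n2 - 2
    sqrt_n = np.sqrt(n1 * n2 / (n1 + n2))

    def integrand(d):
        # scipy's noncentral-t pdf underflows to nan far in the tail
        # (|ncp - t| large); the true density there is numerically zero
        val = stats.nct.pdf(t, df, d * sqrt_n)
        return (val if np.isfinite(val) else 0.0) * stats.cauchy.pdf(d, 0.0, r_scale)

    # split at 0 and at the MLE of d, where the integrand peaks
    d_hat = t / sqrt_n
    num = 0.0
    total_err = 0.0
    edges = [-np.inf, *sorted({0.0, d_hat}), np.inf]
    for a, b in zip(edges[:-1], edges[1:]):
        val, err = integrate.quad(integrand, a, b, epsabs=1e-13, epsrel=1e-10)
        if not np.isfinite(val):
            raise RuntimeError(f"Bayes factor quadrature failed on ({a}, {b})")
        num += val
        total_err += err
    if total_err > 1e-8 * num + 1e-12:
        raise RuntimeError("Bayes factor quadrature did not converge")
    denom = stats.t.pdf(t, df)
    return num / denom


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length samples of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_contrast(x, y, r_scale: float = 0.707) -> TestResult:
    """Pooled t test plus the JZS Bayes factor, as reported in summaries."""
    res = pooled_t(x, y)
    res.bf10 = jzs_bf10(res.t, len(x), len(y), r_scale=r_scale)
    return res
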