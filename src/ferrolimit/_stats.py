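"""Shared small-sample statistics: pooled-variance Student t-tests
(vectorized over many genes/peptides) and Fisher's combined p-value.

Zero-variance conventions (documented, deterministic):
  * both groups constant with equal means  -> t undefined, p = 1
  * both groups constant with unequal means -> p = 0 (two-tailed) or the
    directional limit (one-tailed: 0 if the observed difference lies in
    the tested direction, else 1)
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def pooled_t_pvalue(
    n1: np.ndarray,
    mean1: np.ndarray,
    var1: np.ndarray,
    n2: np.ndarray,
    mean2: np.ndarray,
    var2: np.ndarray,
    alternative: str = "two-sided",
) -> np.ndarray:
    """P-values for the pooled-variance (Student) two-sample t-test from
    per-group summary statistics; all inputs broadcast elementwise.

    ``var`` is the unbiased (ddof=1) sample variance. ``alternative`` is
    ``two-sided``, ``greater`` (group 1 > group 2) or ``less``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    var1 = np.asarray(var1, dtype=float)
    var2 = np.asarray(var2, dtype=float)

    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (mean1 - mean2) / se

    diff = mean1 - mean2
    degenerate = se == 0
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
        p = np.where(degenerate, np.where(diff > 0, 0.0, 1.0), p)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
        p = np.where(degenerate, np.where(diff < 0, 0.0, 1.0), p)
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown alternative {alternative!r}")
    return np.minimum(p, 1.0)


def fisher_combine(p_values, p_floor: float = 1e-300) -> tuple[float, int, float]:
    """Combine k independent p-values by Fisher's method.

    chi2 = -2 * sum(ln p_i) on 2k degrees of freedom; the combined p is
    the chi-square upper-tail probability.  Zero p-values are floored at
    ``p_floor`` before the log so the statistic stays finite.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, p_floor)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))
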