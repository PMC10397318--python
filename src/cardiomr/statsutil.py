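"""Shared statistical utilities: P/Z conversions, Bonferroni thresholds, Chow test.

These are the small conversions the rest of the pipeline leans on.  P-values are
two-sided normal throughout, matching the convention of GWAS summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def z_from_p(p):
    """Two-sided P-value -> non-negative standard-normal quantile.

    ``z_from_p(9.75e-3)`` is about 2.585, the Z that corresponds to the lowest
    tissue-enrichment Z with FDR < 0.05 in the conditional-enrichment stage.

    Parameters
    ----------
    p : float or array-like
        Two-sided P in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    out = stats.norm.isf(p / 2.0)
    return out.item() if out.ndim == 0 else out


def p_from_z(z):
    """Z statistic -> two-sided normal P-value (vectorised)."""
    z = np.asarray(z, dtype=float)
    out = 2.0 * stats.norm.sf(np.abs(z))
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class ThresholdSpec:
    """A family-wise Bonferroni threshold alpha/m."""

    alpha: float
    m: int
    threshold: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        object.__setattr__(self, "threshold", self.alpha / self.m)

    def __format__(self, spec):  # 3-significant-figure convenience
        return format(self.threshold, spec or ".3g")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    return ThresholdSpec(alpha, m).threshold


def chow_test(group_a, group_b):
    """Chow test for equality of regression coefficients across two groups.

    Fits the same linear design in each group and pooled, then

        F = [(RSS_p - RSS_a - RSS_b)/k] / [(RSS_a + RSS_b)/(n_a + n_b - 2k)]

    with k design columns, referred to F(k, n_a + n_b - 2k).  This is the
    classical homoscedastic form; used post hoc to ask whether per-variant
    effects differ between strata (e.g. with/without cardiovascular disease).

    Parameters
    ----------
    group_a, group_b : tuple of (X, y)
        Design matrix (n_i x k, including any intercept column) and response.

    Returns
    -------
    (F, p) : floats
    """
    Xa, ya = (np.asarray(a, dtype=float) for a in group_a)
    Xb, yb = (np.asarray(b, dtype=float) for b in group_b)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if Xb.ndim == 1:
        Xb = Xb[:, None]
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("groups must share the same design columns")
    k = Xa.shape[1]
    na, nb = len(ya), len(yb)
    if np.linalg.matrix_rank(Xa) < k or np.linalg.matrix_rank(Xb) < k:
        raise ValueError("rank-deficient design in one of the groups")

    def _rss(X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_a = _rss(Xa, ya)
    rss_b = _rss(Xb, yb)
    rss_p = _rss(np.vstack([Xa, Xb]), np.concatenate([ya, yb]))
    df2 = na + nb - 2 * k
    num = (rss_p - rss_a - rss_b) / k
    den = (rss_a + rss_b) / df2
    if den == 0:
        return (0.0, 1.0) if num <= 0 else (np.inf, 0.0)
    F = max(num / den, 0.0)
    return F, float(stats.f.sf(F, k, df2))
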