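"""Multivariable two-sample Mendelian randomization.

Joint regression of outcome effects on several exposures' genetic effects,
weighted by the inverse outcome variance, with the conditional
instrument-strength statistics (Q_x per exposure), the pleiotropy statistic
Q_a, and attenuation of a total effect by a secondary exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .statsutil import p_from_z
from .univariable import MREstimate, Z95


@dataclass
class MVInput:
    """k variants x p exposures of genetic effects, plus the outcome effects.

    ``beta_x``/``se_x`` are (k, p); ``beta_y``/``se_y`` are length k.
    """

    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    exposures: list[str]
    variant_ids: list[str] | None = None

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        if self.beta_x.shape[0] == 1 and len(self.beta_y) > 1:
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
        self.beta_y = np.asarray(self.beta_y, float)
        self.se_y = np.asarray(self.se_y, float)
        k, p = self.beta_x.shape
        if k <= p:
            raise ValueError("insufficient instruments: need more variants than exposures")
        if len(self.exposures) != p:
            raise ValueError("exposure labels do not match the beta matrix")
        if np.any(np.all(self.beta_x == 0, axis=0)):
            raise ValueError("an exposure column is all zero")
        if np.any(self.se_y <= 0):
            raise ValueError("outcome SEs must be positive")

    @property
    def k(self):
        return self.beta_x.shape[0]

    @property
    def p(self):
        return self.beta_x.shape[1]


@dataclass
class MVDiagnostics:
    """Instrument-strength (Q_x) and pleiotropy (Q_a) diagnostics.

    Q_x per exposure is compared to the χ² critical value at df = k − 1: when
    every Q_x exceeds it there is little evidence of weak-instrument bias.
    Q_a above the χ²(k − 2) critical value indicates potential pleiotropy.
    """

    q_x: dict
    q_x_critical: float
    weak_flag: dict
    q_a: float | None = None
    q_a_critical: float | None = None
    pleiotropy_flag: bool | None = None


def _wls(X, y, w):
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient exposure matrix")
    cov = np.linalg.inv(Xw.T @ Xw)
    coef = cov @ (Xw.T @ yw)
    resid_q = float(((yw - Xw @ coef) ** 2).sum())
    return coef, cov, resid_q


def mv_estimate(inp: MVInput, method: str = "ivw", seed: int | None = 0,
                n_boot: int = 500) -> list[MREstimate]:
    """Per-exposure direct effects by multivariable MR.

    * ``ivw`` — weighted least squares of beta_y on the exposure matrix with
      no intercept, weights 1/se_y²; multiplicative random-effects SE scaling.
    * ``egger`` — adds an intercept after orienting every variant so the first
      exposure's beta is positive.
    * ``lasso`` — adds per-variant L1-penalized intercepts; the penalty is
      tuned by the heterogeneity rule (largest penalty whose retained set's
      Q_a is below the χ² critical value) and the estimate is MV-IVW on the
      retained variants.
    * ``median`` — coordinate-wise weighted-median estimating equations;
      SE by seeded parametric bootstrap.
    """
    X, y, w = inp.beta_x.copy(), inp.beta_y.copy(), 1.0 / inp.se_y**2
    k, p = inp.k, inp.p

    if method == "ivw":
        coef, cov, q = _wls(X, y, w)
        scale = max(1.0, np.sqrt(q / (k - p))) if k > p else 1.0
        ses = np.sqrt(np.diag(cov)) * scale
    elif method == "egger":
        flip = np.sign(X[:, 0])
        flip[flip == 0] = 1
        Xf, yf = X * flip[:, None], y * flip
        D = np.column_stack([np.ones(k), Xf])
        coef_all, cov_all, q = _wls(D, yf, w)
        scale = max(1.0, np.sqrt(q / (k - p - 1))) if k > p + 1 else 1.0
        coef = coef_all[1:]
        ses = np.sqrt(np.diag(cov_all))[1:] * scale
    elif method == "lasso":
        coef, ses, retained = _mv_lasso(X, y, w)
        out = []
        for j, name in enumerate(inp.exposures):
            b, s = float(coef[j]), float(ses[j])
            out.append(MREstimate(f"mv_lasso[{name}]", b, s, p_from_z(b / s), len(retained),
                                  notes={"retained": retained.tolist()}))
        return out
    elif method == "median":
        coef = _mv_median(X, y, w)
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, p))
        for i in range(n_boot):
            Xs = rng.normal(X, inp.se_x)
            ys = rng.normal(y, inp.se_y)
            boots[i] = _mv_median(Xs, ys, w)
        ses = np.std(boots, axis=0, ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")

    return [
        MREstimate(f"mv_{method}[{name}]", float(coef[j]), float(ses[j]),
                   p_from_z(coef[j] / ses[j]), k)
        for j, name in enumerate(inp.exposures)
    ]


def _mv_lasso(X, y, w, n_lambda: int = 100):
    k, p = X.shape
    coef0, _, _ = _wls(X, y, w)
    r0 = y - X @ coef0
    lam_max = float(np.max(2 * w * np.abs(r0))) * 1.001 or 1.0
    for lam in lam_max * np.geomspace(1.0, 1e-4, n_lambda):
        coef, alpha = coef0.copy(), np.zeros(k)
        for _ in range(500):
            r = y - X @ coef
            alpha_new = np.sign(r) * np.maximum(np.abs(r) - lam / (2 * w), 0.0)
            coef_new, _, _ = _wls(X, y - alpha_new, w)
            if np.max(np.abs(alpha_new - alpha)) < 1e-12 and np.max(np.abs(coef_new - coef)) < 1e-12:
                coef, alpha = coef_new, alpha_new
                break
            coef, alpha = coef_new, alpha_new
        retained = np.flatnonzero(alpha == 0.0)
        if len(retained) <= p:
            break
        c, cov, q = _wls(X[retained], y[retained], w[retained])
        if q <= stats.chi2.ppf(0.95, len(retained) - p):
            scale = 1.0
            return c, np.sqrt(np.diag(cov)) * scale, retained
    raise ValueError("insufficient valid instruments: no homogeneous subset found")


def _mv_median(X, y, w, max_iter: int = 200, tol: float = 1e-10):
    """Coordinate-wise weighted-median solution of the estimating equations."""
    from .univariable import _weighted_median

    k, p = X.shape
    coef, _, _ = _wls(X, y, w)
    coef = coef.copy()
    for _ in range(max_iter):
        prev = coef.copy()
        for j in range(p):
            partial = y - X @ coef + X[:, j] * coef[j]
            good = X[:, j] != 0
            ratios = partial[good] / X[good, j]
            wj = w[good] * X[good, j] ** 2
            coef[j] = _weighted_median(ratios, wj)
        if np.max(np.abs(coef - prev)) < tol:
            break
    return coef


def instrument_strength(inp: MVInput) -> MVDiagnostics:
    """Conditional instrument-strength Q_x per exposure.

    Each exposure's per-variant effects are regressed (inverse-variance
    weighted) on the other exposures' effects; Q_x is the weighted residual
    heterogeneity — how much independent signal the instruments carry for
    that exposure conditional on the rest.  The critical value is the χ²
    quantile at 0.05 with df = k − 1; Q_x at or below it flags the exposure
    as weakly instrumented.
    """
    k, p = inp.k, inp.p
    crit = float(stats.chi2.ppf(0.95, k - 1))
    q_x, weak = {}, {}
    for j, name in enumerate(inp.exposures):
        target = inp.beta_x[:, j]
        wj = 1.0 / inp.se_x[:, j] ** 2
        others = np.delete(inp.beta_x, j, axis=1)
        if others.shape[1] == 0:
            resid = target - 0.0
            q = float((wj * target**2).sum())
            # single-exposure case: heterogeneity about zero = raw strength
        else:
            coef, _, q = _wls(others, target, wj)
        q_x[name] = float(q)
        weak[name] = q <= crit
    return MVDiagnostics(q_x=q_x, q_x_critical=crit, weak_flag=weak)


def pleiotropy_qa(inp: MVInput, diagnostics: MVDiagnostics | None = None) -> MVDiagnostics:
    """Q_a: weighted residual sum of squares of the MV-IVW fit, flagged when it
    exceeds the χ² critical value at df = k − 2 (α = 0.05)."""
    _, _, q_a = _wls(inp.beta_x, inp.beta_y, 1.0 / inp.se_y**2)
    crit = float(stats.chi2.ppf(0.95, inp.k - 2))
    d = diagnostics or instrument_strength(inp)
    d.q_a = float(q_a)
    d.q_a_critical = crit
    d.pleiotropy_flag = q_a > crit
    return d


def attenuation(total: MREstimate, direct: MREstimate, n_sim: int = 100_000,
                seed: int | None = 0):
    """Attenuation of a total effect by a secondary exposure, as a percentage:
    100·(1 − direct/total) on the regression (log-odds / log-hazard) scale.

    The CI comes from parametric simulation of the two estimates assuming
    independence.  Returns (percent, (ci_low, ci_high)).
    """
    if total.beta == 0:
        raise ZeroDivisionError("attenuation undefined for a null total effect")
    pct = 100.0 * (1.0 - direct.beta / total.beta)
    rng = np.random.default_rng(seed)
    t = rng.normal(total.beta, total.se, n_sim)
    d = rng.normal(direct.beta, direct.se, n_sim)
    sims = 100.0 * (1.0 - d / t)
    lo, hi = np.percentile(sims, [2.5, 97.5])
    return float(pct), (float(lo), float(hi))
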