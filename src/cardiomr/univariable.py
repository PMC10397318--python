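"""Univariable two-sample Mendelian randomization estimators.

Implements the ratio (Wald) estimate, inverse-variance-weighted regression
(fixed and multiplicative random effects), MR-Egger with I²_GX, the weighted
median, MR-Lasso outlier removal, the contamination-mixture model, the Rücker
heterogeneity framework used to choose the reporting model, and the
Wald-estimate locus-discovery scan.

All estimators consume a list of :class:`~cardiomr.instruments.HarmonizedVariant`
and return :class:`MREstimate`.  Causal effects are on the scale the
harmonizer produced (per 5 bpm of exposure by default); exponentiate
``beta``/CI at reporting time for odds or hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import HarmonizedVariant
from .statsutil import p_from_z
from .sumstats import SummaryStats, _align_to

log = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty."""

    method: str
    beta: float
    se: float
    p: float
    n_snp: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    @property
    def exp_or(self) -> tuple[float, float, float]:
        """(OR/HR, CI low, CI high) for log-odds / log-hazard outcomes."""
        return tuple(np.exp([self.beta, self.ci_low, self.ci_high]))


@dataclass
class RuckerReport:
    """Heterogeneity diagnostics driving the IVW-vs-Egger model choice."""

    q: float
    q_prime: float
    q_diff: float
    i2: float
    i2_gx: float
    egger_intercept: float
    egger_intercept_p: float
    p_q: float
    p_qdiff: float
    decision: str  # "IVW" or "EGGER"
    available: bool = True


def _arrays(variants: list[HarmonizedVariant]):
    bx = np.array([v.beta_exp for v in variants], float)
    sx = np.array([v.se_exp for v in variants], float)
    by = np.array([v.beta_out for v in variants], float)
    sy = np.array([v.se_out for v in variants], float)
    return bx, sx, by, sy


def wald_ratio(v: HarmonizedVariant) -> MREstimate:
    """Per-variant ratio estimate beta_out/beta_exp with first-order delta SE."""
    if v.beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    beta = v.beta_out / v.beta_exp
    se = v.se_out / abs(v.beta_exp)
    return MREstimate("wald_ratio", beta, se, p_from_z(beta / se), 1,
                      notes={"variant": v.variant_id})


def ivw(variants: list[HarmonizedVariant], model: str = "mre") -> MREstimate:
    """IVW estimate: regression of beta_out on beta_exp through the origin,
    weights 1/se_out².

    ``model="fixed"`` uses unit residual variance; ``"mre"`` (multiplicative
    random effects, the reporting default) scales the SE by
    max(1, √(Q/(k−1))), never below the fixed-effects SE.
    """
    if not variants:
        raise ValueError("empty instrument set")
    bx, _, by, sy = _arrays(variants)
    w = 1.0 / sy**2
    denom = float((w * bx**2).sum())
    beta = float((w * bx * by).sum()) / denom
    se_fe = 1.0 / np.sqrt(denom)
    k = len(variants)
    q = float((w * (by - beta * bx) ** 2).sum())
    scale = 1.0
    if model == "mre" and k >= 2:
        scale = max(1.0, np.sqrt(q / (k - 1)))
    elif model not in ("fixed", "mre"):
        raise ValueError("model must be 'fixed' or 'mre'")
    se = se_fe * scale
    return MREstimate(f"ivw_{model}", beta, se, p_from_z(beta / se), k,
                      notes={"Q": q, "se_scale": scale})


def egger(variants: list[HarmonizedVariant], model: str = "mre"):
    """MR-Egger: weighted regression with an intercept (the intercept estimates
    directional pleiotropy).  Pairs are sign-flipped so every beta_exp > 0
    before fitting.  Returns (estimate, intercept, intercept_p, i2_gx).

    I²_GX quantifies instrument measurement error for the Egger slope;
    values above 0.95 indicate low regression-dilution risk.
    """
    if len(variants) < 3:
        raise ValueError("MR-Egger needs at least 3 variants")
    bx, sx, by, sy = _arrays(variants)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise np.linalg.LinAlgError("all exposure effects equal: Egger slope non-identifiable")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ by)
    a, b = float(coef[0]), float(coef[1])
    k = len(variants)
    q_prime = float((w * (by - a - b * bx) ** 2).sum())
    scale = max(1.0, np.sqrt(q_prime / (k - 2))) if model == "mre" else 1.0
    se_b = float(np.sqrt(cov[1, 1])) * scale
    se_a = float(np.sqrt(cov[0, 0])) * scale
    # heterogeneity of the exposure effects themselves -> I2_GX
    wx = 1.0 / sx**2
    bx_bar = float((wx * bx).sum() / wx.sum())
    q_gx = float((wx * (bx - bx_bar) ** 2).sum())
    i2_gx = max(0.0, (q_gx - (k - 1)) / q_gx) if q_gx > 0 else 0.0
    est = MREstimate("egger", b, se_b, p_from_z(b / se_b), k,
                     notes={"Q_prime": q_prime, "se_scale": scale})
    return est, a, p_from_z(a / se_a), i2_gx


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: order statistics interpolated at
    cumulative weight 0.5 (standardised weights, half-step convention)."""
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(variants: list[HarmonizedVariant], n_boot: int = 1000,
                    seed: int | None = 0) -> MREstimate:
    """Weighted median of per-variant Wald ratios (weights 1/se_wald²);
    consistent when up to half the weight sits on invalid instruments.
    SE by seeded parametric bootstrap."""
    bx, sx, by, sy = _arrays(variants)
    if len(variants) == 1:
        return wald_ratio(variants[0])
    ratios = by / bx
    w = (bx / sy) ** 2  # 1/se_wald^2 with se_wald = se_out/|beta_exp|
    beta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        boots[i] = _weighted_median(bys / bxs, (bxs / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se, p_from_z(beta / se), len(variants),
                      notes={"n_boot": n_boot})


def mr_lasso(variants: list[HarmonizedVariant], n_lambda: int = 100):
    """MR-Lasso: per-variant intercepts under an L1 penalty identify outliers.

    The model is beta_out_j = θ·beta_exp_j + α_j with weights 1/se_out²; the
    penalty on Σ|α_j| is relaxed along a decreasing path and the tuning value
    is the largest penalty at which the retained (α_j = 0) set's Cochran Q
    stays below the χ² critical value (df = retained − 1, α = 0.05).  The
    reported estimate is plain IVW on the retained set.

    Returns (estimate, outlier_ids).
    """
    if len(variants) < 3:
        raise ValueError("MR-Lasso needs at least 3 variants")
    bx, _, by, sy = _arrays(variants)
    w = 1.0 / sy**2

    def _fit(lam):
        theta = float((w * bx * by).sum() / (w * bx**2).sum())
        alpha = np.zeros_like(by)
        for _ in range(500):
            r = by - theta * bx
            # soft-threshold per variant: argmin w_j (r_j - a_j)^2 + lam |a_j|
            thr = lam / (2 * w)
            alpha_new = np.sign(r) * np.maximum(np.abs(r) - thr, 0.0)
            theta_new = float((w * bx * (by - alpha_new)).sum() / (w * bx**2).sum())
            if np.max(np.abs(alpha_new - alpha)) < 1e-12 and abs(theta_new - theta) < 1e-12:
                theta, alpha = theta_new, alpha_new
                break
            theta, alpha = theta_new, alpha_new
        return theta, alpha

    theta0 = float((w * bx * by).sum() / (w * bx**2).sum())
    lam_max = float(np.max(2 * w * np.abs(by - theta0 * bx))) * 1.001
    if lam_max == 0:
        lam_max = 1.0
    lambdas = lam_max * np.geomspace(1.0, 1e-4, n_lambda)

    chosen = None
    for lam in lambdas:
        _, alpha = _fit(lam)
        retained = np.flatnonzero(alpha == 0.0)
        if len(retained) < 2:
            break
        sub = [variants[i] for i in retained]
        est_fe = ivw(sub, model="fixed")
        qcrit = stats.chi2.ppf(0.95, len(retained) - 1)
        if est_fe.notes["Q"] <= qcrit:
            chosen = retained
            break
    if chosen is None:
        raise ValueError("insufficient valid instruments: no homogeneous subset found")
    outliers = [variants[i].variant_id for i in range(len(variants)) if i not in set(chosen)]
    est = ivw([variants[i] for i in chosen], model="fixed")
    est.method = "mr_lasso"
    est.notes["outliers"] = outliers
    est.notes["retained"] = [variants[i].variant_id for i in chosen]
    return est, outliers


def contamination_mixture(
    variants: list[HarmonizedVariant],
    psi: float | None = None,
    grid_size: int = 1000,
    grid_halfwidth_mad: float = 5.0,
):
    """Contamination-mixture estimator: profile likelihood over candidate
    causal values, each variant classified valid (N(θ, se²)) or invalid
    (N(0, ψ² + se²)) by the larger log-density.

    Consistent when no larger subset of invalid instruments agrees on a
    common (wrong) value than the valid subset does.  ψ defaults to the SD of
    the Wald ratios.  The 95% confidence set {θ: 2(ℓ_max − ℓ(θ)) ≤ χ²₁(0.95)}
    may be a union of disjoint intervals; all are reported.

    Returns (estimate, list of CI intervals).
    """
    if len(variants) < 3:
        raise ValueError("contamination mixture needs at least 3 variants")
    bx, _, by, sy = _arrays(variants)
    ratios = by / bx
    se_r = sy / np.abs(bx)
    if psi is None:
        psi = float(np.std(ratios, ddof=1))
        if psi == 0:
            psi = float(np.mean(se_r))
    med = float(np.median(ratios))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    if mad == 0:
        mad = float(np.mean(se_r))
    grid = np.linspace(med - grid_halfwidth_mad * mad, med + grid_halfwidth_mad * mad, grid_size)

    ll_valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=se_r[None, :])
    ll_invalid = stats.norm.logpdf(ratios, loc=0.0, scale=np.sqrt(psi**2 + se_r**2))
    ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)
    imax = int(np.argmax(ll))
    beta = float(grid[imax])
    inside = 2 * (ll[imax] - ll) <= stats.chi2.ppf(0.95, 1)
    intervals = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    lo = min(i[0] for i in intervals)
    hi = max(i[1] for i in intervals)
    se = (hi - lo) / (2 * Z95)  # crude summary; the intervals are authoritative
    est = MREstimate("contamination_mixture", beta, se, p_from_z(beta / se) if se > 0 else 0.0,
                     len(variants), ci_low=lo, ci_high=hi,
                     notes={"psi": psi, "ci_components": intervals})
    return est, intervals


def rucker_framework(variants: list[HarmonizedVariant]) -> RuckerReport:
    """Rücker model-selection framework.

    Q is the Cochran heterogeneity of the fixed-effects IVW fit, Q' the
    MR-Egger residual heterogeneity; Q − Q' is a 1-df test of the Egger
    intercept under fixed-effects weighting.  The reporting model moves from
    IVW to Egger only when Q − Q' is significant *and* the Egger intercept is
    itself significant (both at 0.05); I² > 25% supports heterogeneity.
    """
    k = len(variants)
    if k < 3:
        return RuckerReport(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, decision="IVW", available=False)
    est_fe = ivw(variants, model="fixed")
    q = est_fe.notes["Q"]
    est_eg, intercept, intercept_p, i2_gx = egger(variants)
    q_prime = est_eg.notes["Q_prime"]
    q_diff = max(q - q_prime, 0.0)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    p_q = float(stats.chi2.sf(q, k - 1))
    p_qdiff = float(stats.chi2.sf(q_diff, 1))
    decision = "EGGER" if (p_qdiff < 0.05 and intercept_p < 0.05) else "IVW"
    return RuckerReport(q, q_prime, q_diff, i2, i2_gx, intercept, intercept_p,
                        p_q, p_qdiff, decision)


def wald_discovery(
    variants: list[HarmonizedVariant],
    outcome_a: SummaryStats,
    outcome_b: SummaryStats,
    alpha_bonf: float = 0.05 / 493,
    gwas_sig: float = 5e-8,
):
    """Scan per-variant Wald estimates for outcome loci not yet found by the
    outcome GWASs.

    A variant is flagged when its Wald P is below ``alpha_bonf`` in both
    outcome cohorts with concordant direction, while the variant itself is
    *not* genome-wide significant (P < ``gwas_sig``) in either outcome GWAS.
    Returns a DataFrame with per-cohort Wald estimates and the flag.
    """
    import pandas as pd

    ia, ib = outcome_a.indexed(), outcome_b.indexed()
    rows = []
    for v in variants:
        if v.variant_id not in ia.index or v.variant_id not in ib.index:
            continue
        ra, rb = ia.loc[v.variant_id], ib.loc[v.variant_id]
        out = {}
        for label, rec in (("a", ra), ("b", rb)):
            sign = _align_to(v.effect_allele, v.other_allele, v.eaf,
                             rec["EA"], rec["OA"], rec["EAF"])
            if sign is None:
                sign = 1
            w = (sign * rec["BETA"]) / v.beta_exp
            w_se = rec["SE"] / abs(v.beta_exp)
            out[label] = (w, w_se, p_from_z(w / w_se), rec["P"])
        (wa, sa_, pa, gpa), (wb, sb_, pb, gpb) = out["a"], out["b"]
        flagged = (
            pa < alpha_bonf and pb < alpha_bonf and wa * wb > 0
            and min(gpa, gpb) >= gwas_sig
        )
        rows.append(dict(SNP=v.variant_id, wald_a=wa, wald_se_a=sa_, wald_p_a=pa,
                         wald_b=wb, wald_se_b=sb_, wald_p_b=pb,
                         gwas_p_a=gpa, gwas_p_b=gpb, flagged=flagged))
    return pd.DataFrame(rows)
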