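"""Instrument preparation for two-sample Mendelian randomization.

Harmonizes exposure and outcome summary statistics to a common effect allele
(with the palindrome frequency rule and optional LD proxies), computes
variance explained and F-statistics for instrument strength, and applies
Steiger directionality filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDTable, SummaryStats, complement, is_palindromic
from .statsutil import p_from_z

log = logging.getLogger(__name__)


@dataclass
class LiabilityParams:
    """Threshold-model parameters for binary outcomes: population prevalence K
    and the sample case fraction."""

    prevalence: float
    case_fraction: float

    def __post_init__(self):
        for v in (self.prevalence, self.case_fraction):
            if not 0 < v < 1:
                raise ValueError("prevalence and case fraction must lie in (0, 1)")


@dataclass
class HarmonizedVariant:
    """One aligned exposure/outcome effect pair.

    Exposure effects are per `scale_bpm` bpm after harmonization (per 5 bpm by
    default), so every downstream causal estimate reads "per 5 bpm".
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float
    n_exp: float
    n_out: float
    r2_exp: float = np.nan
    r2_out: float = np.nan
    f_stat: float = np.nan
    weak: bool = False
    steiger_p: float = np.nan
    palindromic_dropped: bool = False
    proxy_used: bool = False
    proxy_id: str | None = None
    steiger_removed: bool = False


def harmonized_frame(variants: list[HarmonizedVariant]) -> pd.DataFrame:
    return pd.DataFrame([vars(v) for v in variants])


def r2_continuous(beta: float, se: float, n: float) -> float:
    """Variance of a continuous trait explained by one variant, from summary
    statistics: r² = t²/(t² + n − 2) with t = beta/se."""
    if n <= 2:
        raise ValueError("n must exceed 2")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def f_statistic(r2: float, n: float) -> float:
    """Instrument-strength F = r²(n−2)/(1−r²).

    Instruments with F < 10 are conventionally called weak; they are flagged
    downstream but never excluded (exclusion would feed winner's curse).
    """
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return r2 * (n - 2) / (1 - r2)


def r2_liability(beta_logodds: float, eaf: float, params: LiabilityParams, n: float) -> float:
    """Liability-scale variance explained by one variant for a binary outcome.

    The observed-scale (0/1) variance explained implied by the log-odds effect
    is converted with the threshold-model correction

        r²_liab = r²_obs · K(1−K)/φ(Φ⁻¹(K))² · K(1−K)/(P(1−P))

    where K is the population prevalence, P the sample case fraction and φ the
    normal density at the liability threshold.  First-order accurate for small
    per-variant effects, which is the GWAS regime.
    """
    K, P = params.prevalence, params.case_fraction
    if beta_logodds == 0:
        return 0.0
    # effect on the observed 0/1 scale via the logistic derivative at the mean
    beta01 = beta_logodds * P * (1 - P)
    var_g = 2 * eaf * (1 - eaf)
    r2_obs = var_g * beta01**2 / (P * (1 - P))
    z = stats.norm.pdf(stats.norm.ppf(K))
    c = K * (1 - K) / z**2 * (K * (1 - K)) / (P * (1 - P))
    return min(r2_obs * c, 1 - 1e-12)


def steiger_test(r2_exp, n_exp, r2_out, n_out):
    """One-sided Fisher-z comparison of |correlation| magnitudes.

    Tests whether the exposure correlation (√r²_exp) is *smaller* than the
    outcome correlation; small P favours reverse causation.
    """
    r_exp, r_out = np.sqrt(r2_exp), np.sqrt(r2_out)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3))
    return float(stats.norm.cdf(z))  # small when r_exp << r_out


def harmonize(
    exp: SummaryStats,
    out: SummaryStats,
    ld: LDTable | None = None,
    palindrome_maf_max: float = 0.42,
    proxy_r2: float = 0.8,
    scale_bpm: float = 5.0,
) -> list[HarmonizedVariant]:
    """Align outcome effects to the exposure effect allele.

    Strand flips are resolved through allele complements; palindromic (A/T,
    G/C) variants are oriented by allele frequency and dropped when the minor
    allele frequency exceeds ``palindrome_maf_max`` on either side.  When a
    variant is absent from the outcome and ``ld`` lists a proxy with
    r² > ``proxy_r2`` that is present, the proxy's outcome record substitutes
    (flagged).  On exit the exposure effect and SE are divided by
    ``scale_bpm`` so causal estimates are per ``scale_bpm`` bpm.
    """
    out_idx = out.indexed()
    harmonized: list[HarmonizedVariant] = []
    n_dropped_palindrome = 0
    for _, e in exp.table.iterrows():
        snp, proxy_used, proxy_id = e["SNP"], False, None
        if snp in out_idx.index:
            o = out_idx.loc[snp]
        else:
            o = None
            if ld is not None:
                for cand, r2 in ld.proxies(snp, proxy_r2):
                    if cand in out_idx.index:
                        o = out_idx.loc[cand]
                        proxy_used, proxy_id = True, cand
                        break
            if o is None:
                continue

        ea, oa, eaf_e = e["EA"], e["OA"], float(e["EAF"])
        beta_o, eaf_o = float(o["BETA"]), float(o["EAF"])
        if proxy_used:
            # proxy alleles are not comparable by label; orient by frequency
            sign = 1 if (eaf_e - 0.5) * (eaf_o - 0.5) > 0 else -1
        elif is_palindromic(ea, oa):
            maf_e = min(eaf_e, 1 - eaf_e)
            maf_o = min(eaf_o, 1 - eaf_o)
            if maf_e > palindrome_maf_max or maf_o > palindrome_maf_max:
                n_dropped_palindrome += 1
                continue
            # orientations agree iff EAFs are closer directly than mirrored
            agree = abs(eaf_e - eaf_o) < abs(eaf_e - (1 - eaf_o))
            sign = 1 if agree else -1
        else:
            o_ea, o_oa = o["EA"], o["OA"]
            if (o_ea, o_oa) == (ea, oa) or (complement(o_ea), complement(o_oa)) == (ea, oa):
                sign = 1
            elif (o_ea, o_oa) == (oa, ea) or (complement(o_ea), complement(o_oa)) == (oa, ea):
                sign = -1
            else:
                log.info("harmonize: variant %s alleles irreconcilable; dropped", snp)
                continue

        harmonized.append(
            HarmonizedVariant(
                variant_id=snp,
                effect_allele=ea,
                other_allele=oa,
                beta_exp=float(e["BETA"]) / scale_bpm,
                se_exp=float(e["SE"]) / scale_bpm,
                beta_out=sign * beta_o,
                se_out=float(o["SE"]),
                eaf=eaf_e,
                n_exp=float(e["N"]),
                n_out=float(o["N"]),
                proxy_used=proxy_used,
                proxy_id=proxy_id,
            )
        )
    if not harmonized:
        raise ValueError("no variants remain after harmonization")
    # instrument strength on the exposure side (scale-invariant in t)
    for v in harmonized:
        v.r2_exp = r2_continuous(v.beta_exp, v.se_exp, v.n_exp)
        v.f_stat = f_statistic(v.r2_exp, v.n_exp)
        v.weak = v.f_stat < 10
    log.info(
        "harmonize: %d variants aligned, %d palindromic dropped", len(harmonized), n_dropped_palindrome
    )
    return harmonized


def steiger_filter(
    variants: list[HarmonizedVariant],
    alpha: float = 0.05,
    binary_outcome: LiabilityParams | None = None,
) -> tuple[list[HarmonizedVariant], list[HarmonizedVariant]]:
    """Directionality filter: remove variants whose exposure variance explained
    is significantly smaller than their outcome variance explained.

    Outcome r² is computed on the trait scale (continuous) or the liability
    scale (binary, via ``binary_outcome``).  Variants whose outcome r² cannot
    be estimated (non-finite) are kept: a true exposure→outcome direction is
    assumed when the outcome signal is too small to measure.
    """
    kept, removed = [], []
    for v in variants:
        if binary_outcome is not None:
            v.r2_out = r2_liability(v.beta_out, v.eaf, binary_outcome, v.n_out)
        else:
            v.r2_out = r2_continuous(v.beta_out, v.se_out, v.n_out)
        if not np.isfinite(v.r2_out) or v.r2_out <= 0:
            v.steiger_p = np.nan
            kept.append(v)
            continue
        v.steiger_p = steiger_test(v.r2_exp, v.n_exp, v.r2_out, v.n_out)
        if v.steiger_p < alpha and v.r2_exp < v.r2_out:
            v.steiger_removed = True
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed
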