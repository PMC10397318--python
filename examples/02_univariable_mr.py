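"""Univariable two-sample Mendelian randomization on simulated cohorts.

The true causal effect is 0.2 per 5 bpm of exposure; 20% of instruments
carry directional pleiotropic effects, so the naive IVW estimate is biased
upward while the robust estimators stay near the truth, and the Rücker
framework flags the pleiotropy.
"""

from cardiomr.instruments import harmonize, steiger_filter
from cardiomr.simulate import Pleiotropy, SimulationConfig, simulate_two_sample
from cardiomr.univariable import (contamination_mixture, egger, ivw, mr_lasso,
                                  rucker_framework, weighted_median)

cfg = SimulationConfig(
    n_variants=100, n_exposure_cohort=30_000, n_outcome_cohort=30_000,
    causal_effect=0.04,  # per bpm = 0.2 per 5 bpm
    pleiotropy=Pleiotropy(fraction_invalid=0.2, mode="directional", scale=0.05),
    seed=11,
)
exposure_ss, outcome_ss, _ = simulate_two_sample(cfg)

variants = harmonize(exposure_ss, outcome_ss)  # per-5-bpm scaling applied here
variants, removed = steiger_filter(variants)
print(f"instruments: {len(variants)} (Steiger removed {len(removed)}); "
      f"mean F = {sum(v.f_stat for v in variants) / len(variants):.0f}")

print(f"{'method':24s}{'beta':>8s}{'se':>8s}   95% CI")
for est in [ivw(variants, "mre"),
            egger(variants)[0],
            weighted_median(variants, seed=0),
            mr_lasso(variants)[0],
            contamination_mixture(variants)[0]]:
    print(f"{est.method:24s}{est.beta:8.3f}{est.se:8.3f}   "
          f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")

rep = rucker_framework(variants)
print(f"\nRucker: Q = {rep.q:.1f}, Q' = {rep.q_prime:.1f}, "
      f"I2 = {100 * rep.i2:.0f}%, intercept P = {rep.egger_intercept_p:.2g} "
      f"-> report {rep.decision}")
print("truth: 0.2 per 5 bpm; the robust estimators sit closer to it than IVW")
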