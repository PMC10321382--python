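"""Fit the time-varying hazard model to one simulated variant.

Simulates a cohort of 20 000 pregnancies in which a MAF-0.3 allele raises
the delivery hazard most strongly early in pregnancy (decaying toward
term), fits the penalized-spline Poisson hazard model (PAMM), tests whether
the effect is time-varying, and prints the weekly log-hazard-ratio curve
alongside the Cox and proportionality sensitivity checks.
"""

import numpy as np

from gesthaz import (
    CohortConfig,
    EffectShape,
    PammSpec,
    expand_cohort,
    fit_cox,
    fit_linear_interaction,
    fit_pamm,
    predict_curve,
    shift_durations,
    simulate_durations,
    test_nonlinear,
    zph_test,
)

cfg = CohortConfig(
    n=20000, mafs=(0.3,), effects=(EffectShape("linear_decay", 0.5),), seed=42
)
cohort = simulate_durations(cfg)
ped = expand_cohort(cohort, variant=0)

fit = fit_pamm(ped, PammSpec())
p_nl = test_nonlinear(fit)
p_lin = fit_linear_interaction(ped).interaction_p()
simple = fit_pamm(ped, PammSpec(time_varying=False))

dur = shift_durations(cohort.durations)
cox = fit_cox(dur, cohort.spontaneous, cohort.dosages[:, 0])
_, p_zph = zph_test(cox, dur, cohort.spontaneous, cohort.dosages[:, 0])

print(f"constant-effect PAMM beta_g : {simple.beta_g:+.3f} (SE {simple.se_g:.3f})")
print(f"Cox log-HR (Breslow)        : {cox.coef[0]:+.3f} (SE {cox.se[0]:.3f})")
print(f"P time-varying (PAMM smooth): {p_nl:.2e}")
print(f"P linear time interaction   : {p_lin:.2e}")
print(f"P cox.zph (KM transform)    : {p_zph:.2e}")
print()
print("week  log-HR   95% CI")
curve = predict_curve(fit, np.arange(20.0, fit.t_range[1], 14.0))
for t, est, lo, hi in zip(curve.times, curve.estimate, curve.lower, curve.upper):
    week = (t + 169) / 7
    print(f"{week:4.0f}  {est:+.3f}  [{lo:+.3f}, {hi:+.3f}]")

# The three small p-values agree: the allele's effect on delivery risk is
# not constant - it is strongest weeks before term, which a plain Cox or
# linear GWAS coefficient would average away.
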