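"""Linear and logistic association scans plus effect concordance.

Simulates 40 variants (half with hazard-increasing effects that shorten
gestation), runs the duration (linear) and preterm (logistic) scans with
batch adjustment, and pairs the suggestive hits to show the concordance
between the two analyses: alleles that shorten gestation raise preterm
odds.
"""

import numpy as np

from gesthaz import (
    CohortConfig,
    EffectShape,
    linear_scan,
    logistic_scan,
    simulate_durations,
    suggestive_concordance,
)

m = 40
effects = tuple(
    EffectShape("constant", 0.25) if j < m // 2 else EffectShape("null")
    for j in range(m)
)
cfg = CohortConfig(n=25000, mafs=(0.3,) * m, effects=effects, seed=15)
cohort = simulate_durations(cfg)

lin = linear_scan(cohort)
logi = logistic_scan(cohort)

print(f"variants scanned      : {len(lin)}")
print(f"suggestive (P<1e-5)   : linear {sum(lin['p'] < 1e-5)}, "
      f"logistic {sum(logi['p'] < 1e-5)}")

pairs = suggestive_concordance(lin, logi, p_threshold=1e-5)
concordant = ((pairs["beta_a"] < 0) & (pairs["beta_b"] > 0)) | (
    (pairs["beta_a"] > 0) & (pairs["beta_b"] < 0)
)
print(f"suggestive after 1.5 Mbp pruning: {len(pairs)}")
print(f"sign-concordant pairs  : {concordant.sum()}/{len(pairs)}")
print("\n  id     days/allele   log-OR")
for _, r in pairs.head(8).iterrows():
    print(f"  {r['id']:<6} {r['beta_a']:+9.3f}   {r['beta_b']:+7.3f}")

# Nearly every suggestive variant lands in the concordant quadrant
# (negative days per allele, positive preterm log-OR): the dichotomized
# scan sees the same biology with far less power.
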