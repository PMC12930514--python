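"""Fit parametric survival curves to trial data and extrapolate.

Simulates one arm of progression-free survival, fits all six candidate
families by maximum likelihood, ranks them by AIC and extrapolates the
front-runner beyond follow-up.  The ranking is advisory: in a real
appraisal it is combined with visual inspection and clinical plausibility.
"""

import numpy as np
import pandas as pd

import baskethta as b

rng = np.random.default_rng(1)
n = 300
t = 8.0 * rng.weibull(1.3, n)          # median PFS around 6 months
obs = np.minimum(t, 24.0)              # 24 months of trial follow-up
ipd = pd.DataFrame({"time": obs, "event": (t <= 24.0).astype(int)})

fits = [b.fit_parametric(ipd, fam) for fam in b.FAMILIES]
ranked = b.select_distribution(fits)

print(f"{'family':<20} {'AIC':>10} {'BIC':>10}")
for f in ranked:
    print(f"{f.family:<20} {f.aic:>10.1f} {f.bic:>10.1f}")

best = ranked[0]
print(f"\nbest fit: {best.family}, parameters {np.round(best.params, 4)}")
for months in (12, 24, 60, 120):
    print(f"  extrapolated S({months} mo) = {b.survival_at(best, months):.3f}")
# The 60- and 120-month values are pure extrapolation: follow-up stopped at
# 24 months, which is why family choice matters so much downstream.
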