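"""Constraining extrapolated survival by general-population mortality.

Long extrapolations can imply cancer cohorts outliving the general
population.  The hazard-max convention applies, at every cycle, the larger
of the model hazard and the cohort-average life-table hazard at the
attained age, so the adjusted curve can never beat the population.
"""

import numpy as np
import pandas as pd

import baskethta as b

# synthetic life table with exponentially rising annual mortality
ages = np.arange(40, 121)
life_table = b.LifeTable(pd.concat([
    pd.DataFrame({"age": ages, "sex": sex,
                  "qx": np.minimum(s * 0.001 * np.exp(0.09 * (ages - 40)), 1.0)})
    for sex, s in (("male", 1.2), ("female", 0.9))
], ignore_index=True))

grid = b.TimeGrid(1.0, 360.0)  # 30 years
fit = b.FittedSurvival("weibull", np.array([0.55, 80.0]))  # optimistic tail
adjusted = b.apply_background_mortality(fit, life_table, start_age=70,
                                        sex_mix={"male": 0.5, "female": 0.5},
                                        grid=grid)

print(f"{'years':>6} {'model S(t)':>11} {'adjusted S(t)':>14}")
for years in (5, 10, 20, 30):
    t = 12.0 * years
    k = int(t / grid.cycle_length)
    print(f"{years:>6} {fit.survival(t):>11.3f} {adjusted.survival[k]:>14.3f}")
print(f"\nconvention: {adjusted.metadata['background_mortality']}")
# Where the fitted hazard drops below the life-table hazard at the cohort's
# attained age, the adjustment takes over and pulls the tail down.
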