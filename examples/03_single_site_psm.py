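"""A single-site three-state partitioned survival model.

State occupancy comes straight from the OS and PFS curves: progression-free
= PFS(t), progressed = OS(t) - PFS(t), dead = 1 - OS(t).  Costs and QALYs
accrue per monthly cycle and are discounted at 3 % a year.
"""

import numpy as np

import baskethta as b

grid = b.TimeGrid(cycle_length=1.0, horizon=240.0)  # 20-year horizon
econ = b.EconomicParams(discount_rate_costs=0.03, discount_rate_effects=0.03,
                        half_cycle_correction=True)


def curves(os_rate, pfs_rate):
    return dict(
        os_curve=b.tabulate(b.FittedSurvival("exponential", np.array([os_rate])), grid),
        pfs_curve=b.tabulate(b.FittedSurvival("exponential", np.array([pfs_rate])), grid),
    )


intervention = b.ArmInputs(
    **curves(0.035, 0.07), utility_pf=0.80, utility_pd=0.65,
    drug_cost_per_cycle=8000.0, admin_cost_per_cycle=300.0,
    disease_mgmt_cost_pf=500.0, disease_mgmt_cost_pd=1500.0,
    ae_cost_oneoff=2000.0, eol_cost_oneoff=10000.0,
)
comparator = b.ArmInputs(
    **curves(0.050, 0.10), utility_pf=0.78, utility_pd=0.65,
    drug_cost_per_cycle=2500.0, admin_cost_per_cycle=300.0,
    disease_mgmt_cost_pf=500.0, disease_mgmt_cost_pd=1500.0,
    ae_cost_oneoff=1000.0, eol_cost_oneoff=10000.0,
)

for name, arm in (("intervention", intervention), ("comparator", comparator)):
    res = b.evaluate_arm(arm, grid, econ)
    print(f"{name}: cost {res.total_cost:>10,.0f}  LY {res.life_years:.3f}  "
          f"QALY {res.qalys:.3f}")

inc = b.incremental(b.evaluate_arm(intervention, grid, econ),
                    b.evaluate_arm(comparator, grid, econ), wtp=100_000.0)
print(f"\ndelta cost {inc.delta_cost:,.0f}, delta QALY {inc.delta_qaly:.3f}")
print(f"ICER {inc.icer:,.0f} per QALY ({inc.classification}); "
      f"NMB at 100k = {inc.nmb:,.0f}")
# A positive NMB (equivalently ICER below the threshold) supports adoption.
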