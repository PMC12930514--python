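import numpy as np
import pandas as pd
import pytest

import baskethta as b
from baskethta.modelspec import ModelSpec, build_model


@pytest.fixture
def grid120():
    return b.TimeGrid(cycle_length=1.0, horizon=120.0)


def exp_curve(rate: float, grid: b.TimeGrid) -> b.TabulatedCurve:
    return b.tabulate(b.FittedSurvival("exponential", np.array([rate])), grid)


def make_arm(os_rate, pfs_rate, grid, **kwargs) -> b.ArmInputs:
    return b.ArmInputs(
        os_curve=exp_curve(os_rate, grid),
        pfs_curve=exp_curve(pfs_rate, grid),
        **kwargs,
    )


@pytest.fixture
def life_table() -> b.LifeTable:
    ages = np.arange(40, 111)
    rows = []
    for sex, scale in (("male", 1.2), ("female", 0.9)):
        qx = np.minimum(scale * 0.001 * np.exp(0.09 * (ages - 40)), 1.0)
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": qx}))
    return b.LifeTable(pd.concat(rows, ignore_index=True))


def constant_hazard_life_table(monthly_hazard: float) -> b.LifeTable:
    q = 1.0 - np.exp(-12.0 * monthly_hazard)
    ages = np.arange(0, 121)
    return b.LifeTable(pd.DataFrame({"age": ages, "sex": "all", "qx": q}))


@pytest.fixture(scope="session")
def heterogeneous_bundle():
    """IPD + spec + built model for the heterogeneous builtin scenario."""
    config = b.builtin_scenarios()["heterogeneous"]
    ipd, counts, spec = b.generate_basket_trial(config)
    model = build_model(ModelSpec.model_validate(spec), ipd=ipd)
    return {"config": config, "ipd": ipd, "counts": counts, "spec": spec,
            "model": model}


def simulate_censored(family, params, n, rng, censor_fraction=0.2):
    """Event times from a family with ~censor_fraction uniform censoring."""
    from scipy import integrate, optimize

    from baskethta.simulate import _draw_times
    from baskethta.survival import FittedSurvival

    t = _draw_times(family, params, n, rng)
    if censor_fraction <= 0:
        return pd.DataFrame({"time": t, "event": 1})
    fit = FittedSurvival(family, np.array(params, float))

    def censored_prob(u):  # P(T > C) with C ~ U(0, u)
        val, _ = integrate.quad(fit.survival, 0.0, u, limit=200)
        return val / u

    hi = np.quantile(t, 0.999)
    u = optimize.brentq(lambda x: censored_prob(x) - censor_fraction, 1e-6, 10 * hi)
    c = rng.uniform(0.0, u, n)
    return pd.DataFrame({
        "time": np.minimum(t, c),
        "event": (t <= c).astype(int),
    })
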