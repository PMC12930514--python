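"""Seeded generator of synthetic multi-site basket-trial evidence.

Tumour-agnostic therapies are typically licensed on single-arm basket
trials: small, heterogeneous cohorts per tumour site sharing a molecular
biomarker.  The generator emulates that evidence base so the whole
framework can be exercised without any external data: per site and arm it
draws coupled progression and death times, applies dropout and
administrative censoring, and emits standard-schema IPD together with
biomarker-positive prevalence counts (the weighting source) and a complete
model specification.

Coupling guarantees per-subject coherence (PFS time <= OS time): a latent
progression time, a pre-progression death time and a post-progression
survival time are drawn independently, and

    pfs_time = min(t_prog, t_death_pre)
    os_time  = t_death_pre               if death precedes progression
               t_prog + t_post           otherwise

so independently extrapolated curves can never cross in the underlying
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArmScenario",
    "SiteScenario",
    "ScenarioConfig",
    "generate_basket_trial",
    "builtin_scenarios",
    "true_endpoint_survival",
]


def _draw_times(family: str, params, size: int, rng: np.random.Generator):
    """Draw event times from any supported parametric family."""
    params = np.asarray(params, float)
    if family == "exponential":
        return rng.exponential(1.0 / params[0], size)
    if family == "weibull":
        shape, scale = params
        return scale * rng.weibull(shape, size)
    if family == "gompertz":
        shape, rate = params
        u = rng.uniform(size=size)
        if abs(shape) < 1e-12:
            return -np.log(u) / rate
        arg = 1.0 - shape * np.log(u) / rate
        # negative shape leaves a never-dying fraction; cap at a huge time
        out = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / shape, np.inf)
        return np.where(np.isfinite(out), out, 1e9)
    if family == "log_normal":
        mu, sigma = params
        return rng.lognormal(mu, sigma, size)
    if family == "log_logistic":
        shape, scale = params
        u = rng.uniform(size=size)
        return scale * (u / (1.0 - u)) ** (1.0 / shape)
    if family == "generalized_gamma":
        mu, sigma, q = params
        if abs(q) < 1e-8:
            return np.exp(rng.normal(mu, sigma, size))
        g = rng.gamma(q ** -2, 1.0, size)
        w = np.log((q ** 2) * g) / q
        return np.exp(mu + sigma * w)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class ArmScenario:
    """Latent event-time distributions for one arm of one site.

    Each entry is ``(family, params)`` in the package's parameterisation;
    rates are per month.
    """

    progression: tuple = ("exponential", (0.115,))
    pre_progression_death: tuple = ("exponential", (0.010,))
    post_progression_death: tuple = ("exponential", (0.058,))
    dropout_rate: float = 0.005   # per month, random loss to follow-up
    admin_censoring: float = 36.0  # months of trial follow-up


@dataclass
class SiteScenario:
    site_id: str
    n_per_arm: int
    biomarker_positive_count: int
    arms: dict[str, ArmScenario]

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")


@dataclass
class ScenarioConfig:
    name: str
    sites: list[SiteScenario]
    cost_blocks: dict[str, dict] = field(default_factory=dict)
    wtp: float = 100_000.0
    horizon: float = 240.0
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    seed: int = 20260921


def _default_cost_blocks() -> dict[str, dict]:
    # plausible late-stage oncology values, EUR per monthly cycle
    return {
        "intervention": {
            "utility_pf": 0.80, "utility_pd": 0.65,
            "drug_cost_per_cycle": 8000.0, "admin_cost_per_cycle": 300.0,
            "disease_mgmt_cost_pf": 500.0, "disease_mgmt_cost_pd": 1500.0,
            "ae_cost_oneoff": 2000.0, "eol_cost_oneoff": 10000.0,
        },
        "comparator": {
            "utility_pf": 0.78, "utility_pd": 0.65,
            "drug_cost_per_cycle": 2500.0, "admin_cost_per_cycle": 300.0,
            "disease_mgmt_cost_pf": 500.0, "disease_mgmt_cost_pd": 1500.0,
            "ae_cost_oneoff": 1000.0, "eol_cost_oneoff": 10000.0,
        },
    }


def generate_basket_trial(config: ScenarioConfig, seed: int | None = None):
    """Simulate a basket trial: IPD, prevalence counts and a model spec.

    Returns ``(ipd, counts, spec_dict)`` where ``ipd`` has the standard
    columns (site, arm, endpoint, time, event) plus a subject identifier
    linking each subject's OS and PFS rows, ``counts`` maps site to its
    biomarker-positive count and ``spec_dict`` is a loadable model
    specification.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for site in config.sites:
        for arm_name, arm in site.arms.items():
            n = site.n_per_arm
            t_prog = _draw_times(*arm.progression, n, rng)
            t_dpre = _draw_times(*arm.pre_progression_death, n, rng)
            t_post = _draw_times(*arm.post_progression_death, n, rng)
            pfs_true = np.minimum(t_prog, t_dpre)
            os_true = np.where(t_dpre <= t_prog, t_dpre, t_prog + t_post)
            if arm.dropout_rate > 0:
                dropout = rng.exponential(1.0 / arm.dropout_rate, n)
            else:
                dropout = np.full(n, np.inf)
            cens = np.minimum(dropout, arm.admin_censoring)
            for endpoint, t_true in (("OS", os_true), ("PFS", pfs_true)):
                obs = np.minimum(t_true, cens)
                event = (t_true <= cens).astype(int)
                frames.append(pd.DataFrame({
                    "site": site.site_id,
                    "arm": arm_name,
                    "endpoint": endpoint,
                    "time": obs,
                    "event": event,
                    "subject": [f"{site.site_id}-{arm_name}-{i}" for i in range(n)],
                }))
    ipd = pd.concat(frames, ignore_index=True)
    counts = {s.site_id: s.biomarker_positive_count for s in config.sites}
    spec = _scenario_to_spec(config)
    return ipd, counts, spec


def _scenario_to_spec(config: ScenarioConfig) -> dict:
    cost_blocks = config.cost_blocks or _default_cost_blocks()
    return {
        "name": config.name,
        "global": {
            "cycle_length": config.cycle_length,
            "horizon": config.horizon,
            "discount_rate_costs": config.discount_rate,
            "discount_rate_effects": config.discount_rate,
            "half_cycle_correction": True,
            "wtp": config.wtp,
            "seed": config.seed,
            "currency": "EUR",
            "time_unit": "months",
            # parsimonious families: follow-up is short relative to the
            # horizon, so flexible tails are poorly identified
            "candidate_families": ["exponential", "weibull"],
        },
        "cost_blocks": cost_blocks,
        "sites": [
            {
                "site_id": s.site_id,
                "weight_source_count": s.biomarker_positive_count,
                "evidence_level": "pooled",
                "evidence_n": s.n_per_arm * 2,
            }
            for s in config.sites
        ],
    }


def true_endpoint_survival(arm: ArmScenario):
    """Closed-form OS and PFS survivor functions for exponential latents.

    With progression rate a, pre-progression death rate b and
    post-progression death rate c (all exponential):

        S_PFS(t) = exp(-(a + b) t)
        S_OS(t)  = exp(-(a+b) t) + a exp(-c t) (1 - exp(-(a+b-c) t)) / (a+b-c)

    (the limit a+b = c handled separately).  Used as the oracle for
    end-to-end recovery tests.
    """
    for key in ("progression", "pre_progression_death", "post_progression_death"):
        fam, _ = getattr(arm, key)
        if fam != "exponential":
            raise ValueError("closed forms require exponential latents")
    a = arm.progression[1][0]
    b = arm.pre_progression_death[1][0]
    c = arm.post_progression_death[1][0]

    def s_pfs(t):
        return np.exp(-(a + b) * np.asarray(t, float))

    def s_os(t):
        t = np.asarray(t, float)
        if abs(a + b - c) < 1e-12:
            return np.exp(-(a + b) * t) * (1.0 + a * t)
        return (np.exp(-(a + b) * t)
                + a * np.exp(-c * t) * (1.0 - np.exp(-(a + b - c) * t)) / (a + b - c))

    return s_os, s_pfs


def _scaled(arm: ArmScenario, hr_prog: float, hr_death: float) -> ArmScenario:
    """Apply hazard ratios to an exponential reference arm."""
    a = arm.progression[1][0] * hr_prog
    b = arm.pre_progression_death[1][0] * hr_death
    c = arm.post_progression_death[1][0] * hr_death
    return ArmScenario(
        progression=("exponential", (a,)),
        pre_progression_death=("exponential", (b,)),
        post_progression_death=("exponential", (c,)),
        dropout_rate=arm.dropout_rate,
        admin_censoring=arm.admin_censoring,
    )


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Three fully specified study scenarios.

    - ``homogeneous``: three sites sharing one treatment effect (progression
      and death hazard ratio 0.6), so pooled and broken-out analyses target
      the same estimand.
    - ``heterogeneous``: as above but one site gains no benefit (hazard
      ratios 1.0), the case where pooling biases the aggregate.
    - ``small_n_site``: homogeneous effects but one site with only 10
      subjects per arm, emulating the thin cohorts of basket trials.
    """
    # site-specific comparator prognosis (median PFS ~5-9 months)
    baselines = {
        "lung": ArmScenario(progression=("exponential", (0.139,)),
                            pre_progression_death=("exponential", (0.012,)),
                            post_progression_death=("exponential", (0.069,))),
        "colorectal": ArmScenario(progression=("exponential", (0.099,)),
                                  pre_progression_death=("exponential", (0.008,)),
                                  post_progression_death=("exponential", (0.050,))),
        "thyroid": ArmScenario(progression=("exponential", (0.077,)),
                               pre_progression_death=("exponential", (0.005,)),
                               post_progression_death=("exponential", (0.039,))),
    }
    counts = {"lung": 600, "colorectal": 300, "thyroid": 100}

    def make(name, n_per_arm, hr_by_site, seed, small_site=None):
        sites = []
        for sid, base in baselines.items():
            hr = hr_by_site[sid]
            n = small_site.get(sid, n_per_arm) if small_site else n_per_arm
            sites.append(SiteScenario(
                site_id=sid,
                n_per_arm=n,
                biomarker_positive_count=counts[sid],
                arms={
                    "intervention": _scaled(base, hr, hr),
                    "comparator": _scaled(base, 1.0, 1.0),
                },
            ))
        return ScenarioConfig(name=name, sites=sites, seed=seed)

    return {
        "homogeneous": make(
            "homogeneous", 100,
            {"lung": 0.6, "colorectal": 0.6, "thyroid": 0.6}, seed=101),
        "heterogeneous": make(
            "heterogeneous", 100,
            {"lung": 0.6, "colorectal": 0.6, "thyroid": 1.0}, seed=202),
        "small_n_site": make(
            "small_n_site", 100,
            {"lung": 0.6, "colorectal": 0.6, "thyroid": 0.6}, seed=303,
            small_site={"thyroid": 10}),
    }
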