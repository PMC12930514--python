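"""Deterministic and probabilistic sensitivity analysis.

The distinguishing feature of the multi-site structure is not the number of
parameters but how they are varied: parameters representing assumptions
common to every tumour site (``scope="shared"``) are drawn once per PSA
iteration and written to all sites jointly, while tumour-specific
parameters (``scope="site_specific"``) are drawn independently.  The same
rule applies to one-way deterministic analysis, where a shared parameter is
moved in every site simultaneously.

Outputs follow standard practice: per-iteration incremental cost/QALY
samples, cost-effectiveness acceptability curves (CEAC) and a tornado
table ordered by net-monetary-benefit range.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aggregation import AggregatedResult, MultiSiteModel
from .engine import EconomicParams
from .survival import tabulate

__all__ = [
    "ParameterSpec",
    "PSAResult",
    "CEACCurve",
    "run_psa",
    "ceac",
    "dsa",
    "psa_from_samples",
]

_UTILITY_DISTS = {"beta", "fixed"}
_COST_DISTS = {"gamma", "lognormal", "fixed"}
_ALL_DISTS = {"normal", "lognormal", "beta", "gamma", "fixed"}

_ARM_ROLES = ("intervention", "comparator", "both")


@dataclass
class ParameterSpec:
    """One uncertain model parameter.

    ``target`` is a dotted path ``<role>.<field>`` where role is
    ``intervention``, ``comparator``, ``both`` or ``econ`` and field is a
    scalar model input (e.g. ``intervention.drug_cost_per_cycle``,
    ``both.utility_pf``, ``econ.discount_rate_effects``).  Utilities must
    use a beta (or fixed) distribution; costs a gamma or log-normal (or
    fixed) one, so draws respect the parameter's support.
    """

    name: str
    target: str
    distribution: str
    dist_params: dict
    scope: str = "shared"  # shared | site_specific
    site_id: str | None = None
    dsa_low: float | None = None
    dsa_high: float | None = None

    def __post_init__(self):
        if self.distribution not in _ALL_DISTS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scope not in ("shared", "site_specific"):
            raise ValueError("scope must be 'shared' or 'site_specific'")
        if self.scope == "site_specific" and not self.site_id:
            raise ValueError(f"parameter {self.name!r}: site_id required "
                             "for site-specific scope")
        role, _, fld = self.target.partition(".")
        if role not in _ARM_ROLES + ("econ",) or not fld:
            raise ValueError(f"cannot parse target {self.target!r}")
        if role == "econ" and self.scope != "shared":
            raise ValueError("economic settings are structural: shared scope only")
        if fld.startswith("utility") and self.distribution not in _UTILITY_DISTS:
            raise ValueError(
                f"{self.name!r}: utilities are bounded in [0,1]; use a beta "
                "(or fixed) distribution"
            )
        if "cost" in fld and self.distribution not in _COST_DISTS:
            raise ValueError(
                f"{self.name!r}: costs are non-negative; use gamma, lognormal "
                "or fixed"
            )
        if (self.dsa_low is not None and self.dsa_high is not None
                and self.dsa_low > self.dsa_high):
            raise ValueError(f"{self.name!r}: dsa_low > dsa_high")

    def draw(self, rng: np.random.Generator) -> float:
        p = self.dist_params
        if self.distribution == "fixed":
            return float(p["value"])
        if self.distribution == "normal":
            return float(rng.normal(p["mean"], p["sd"]))
        if self.distribution == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        if self.distribution == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError(f"{self.name!r}: beta hyperparameters must be > 0")
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.distribution == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError(f"{self.name!r}: gamma hyperparameters must be > 0")
            return float(rng.gamma(p["shape"], p["scale"]))
        raise AssertionError


def _apply_parameter(model: MultiSiteModel, spec: ParameterSpec,
                     value: float) -> None:
    """Write one parameter value into (a working copy of) the model."""
    role, _, fld = spec.target.partition(".")
    if role == "econ":
        if not hasattr(model.econ, fld):
            raise AttributeError(f"target {spec.target!r} does not resolve")
        model.econ = replace(model.econ, **{fld: value})
        return
    site_ids = ([spec.site_id] if spec.scope == "site_specific"
                else sorted(model.sites))
    roles = ("intervention", "comparator") if role == "both" else (role,)
    for sid in site_ids:
        if sid not in model.sites:
            raise KeyError(f"parameter {spec.name!r} targets unknown site {sid!r}")
        for r in roles:
            arm = getattr(model.sites[sid], r)
            if not hasattr(arm, fld):
                raise AttributeError(f"target {spec.target!r} does not resolve")
            setattr(arm, fld, value)


@dataclass
class PSAResult:
    n_iterations: int
    seed: int
    wtp: float
    samples: pd.DataFrame          # iteration, site, delta_cost, delta_qaly
    parameter_draws: pd.DataFrame  # iteration, parameter, site, value
    base_result: AggregatedResult | None = None
    resample_rejections: int = 0
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        agg = self.samples[self.samples["site"] == "aggregate"]
        if len(agg) != self.n_iterations:
            raise ValueError("sample count does not match n_iterations")
        if not np.all(np.isfinite(agg[["delta_cost", "delta_qaly"]])):
            raise ValueError("non-finite PSA samples")

    def aggregate_samples(self) -> pd.DataFrame:
        return (self.samples[self.samples["site"] == "aggregate"]
                .sort_values("iteration", ignore_index=True))

    def running_mean_nmb(self) -> np.ndarray:
        """Convergence diagnostic: running mean of aggregate NMB."""
        agg = self.aggregate_samples()
        nmb = self.wtp * agg["delta_qaly"].to_numpy() - agg["delta_cost"].to_numpy()
        return np.cumsum(nmb) / np.arange(1, len(nmb) + 1)

    def mean_incrementals(self) -> pd.DataFrame:
        return (self.samples.groupby("site")[["delta_cost", "delta_qaly"]]
                .mean().reset_index())


@dataclass
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self):
        self.wtp = np.asarray(self.wtp, float)
        self.probability = np.asarray(self.probability, float)
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def run_psa(model: MultiSiteModel, specs: list[ParameterSpec],
            n_iterations: int, seed: int,
            resample_survival: bool = False) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Per iteration each shared parameter is drawn once and written to every
    site; each site-specific parameter is drawn independently for its site;
    the full model (all sites plus aggregation) is then re-evaluated.  With
    ``resample_survival`` the fitted survival parameters are redrawn from
    their asymptotic MVN (one draw per distinct fit, so pooled curves move
    jointly across the sites that share them).  Reproducible given the seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    # fail fast on unresolvable targets
    probe = copy.deepcopy(model)
    for spec in specs:
        _apply_parameter(probe, spec, _base_value(model, spec))

    rng = np.random.default_rng(seed)
    rows, draw_rows = [], []
    rejections = 0
    for it in range(n_iterations):
        m = copy.deepcopy(model)
        for spec in specs:
            if spec.scope == "shared":
                value = spec.draw(rng)
                _apply_parameter(m, spec, value)
                for sid in sorted(m.sites):
                    draw_rows.append((it, spec.name, sid, value))
            else:
                value = spec.draw(rng)
                _apply_parameter(m, spec, value)
                draw_rows.append((it, spec.name, spec.site_id, value))
        if resample_survival:
            rejections += _resample_curves(m, rng)
        res = m.evaluate()
        for sid, r in sorted(res.per_site.items()):
            rows.append((it, sid, r.delta_cost, r.delta_qaly))
        rows.append((it, "aggregate", res.delta_cost_agg, res.delta_qaly_agg))

    samples = pd.DataFrame(rows, columns=["iteration", "site",
                                          "delta_cost", "delta_qaly"])
    draws = pd.DataFrame(draw_rows, columns=["iteration", "parameter",
                                             "site", "value"])
    return PSAResult(
        n_iterations=n_iterations, seed=seed, wtp=model.wtp,
        samples=samples, parameter_draws=draws,
        base_result=model.evaluate(),
        resample_rejections=rejections,
        notes={"resample_survival": resample_survival,
               "n_parameters": len(specs)},
    )


def _base_value(model: MultiSiteModel, spec: ParameterSpec) -> float:
    role, _, fld = spec.target.partition(".")
    if role == "econ":
        return getattr(model.econ, fld)
    sid = spec.site_id if spec.scope == "site_specific" else sorted(model.sites)[0]
    r = "intervention" if role == "both" else role
    return getattr(getattr(model.sites[sid], r), fld)


def _resample_curves(m: MultiSiteModel, rng: np.random.Generator) -> int:
    """Redraw survival parameters; one draw per distinct fitted object."""
    rejections = 0
    drawn: dict[int, object] = {}
    for sid in sorted(m.sites):
        site = m.sites[sid]
        for (arm, endpoint), fit in sorted(site.fits.items()):
            if fit.cov is None:
                continue
            key = id(fit)
            if key not in drawn:
                params = fit.sample_params(rng)
                drawn[key] = replace_params(fit, params)
            new_fit = drawn[key]
            curve = tabulate(new_fit, m.grid)
            target = getattr(site, arm) if hasattr(site, arm) else None
            if target is None:
                continue
            if endpoint == "OS":
                target.os_curve = curve
            else:
                target.pfs_curve = curve
    return rejections


def replace_params(fit, params):
    from dataclasses import replace as dc_replace

    return dc_replace(fit, params=np.asarray(params, float))


def ceac(psa: PSAResult, wtp_grid) -> dict[str, CEACCurve]:
    """Probability of cost-effectiveness across willingness-to-pay values.

    At each threshold the probability is the fraction of iterations with
    strictly positive net monetary benefit (ties count as not
    cost-effective).  Returned per site and for the aggregate.
    """
    grid = np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    out = {}
    for sid, sub in psa.samples.groupby("site"):
        dc = sub["delta_cost"].to_numpy()
        de = sub["delta_qaly"].to_numpy()
        prob = np.array([(lam * de - dc > 0).mean() for lam in grid])
        out[sid] = CEACCurve(grid, prob)
    return out


def psa_from_samples(delta_cost, delta_qaly, wtp: float,
                     seed: int = 0) -> PSAResult:
    """Wrap externally supplied (dC, dE) samples as a PSA result.

    Useful for validating CEAC machinery against distributions with known
    closed-form acceptability probabilities.
    """
    delta_cost = np.asarray(delta_cost, float)
    delta_qaly = np.asarray(delta_qaly, float)
    n = len(delta_cost)
    samples = pd.DataFrame({
        "iteration": np.arange(n),
        "site": "aggregate",
        "delta_cost": delta_cost,
        "delta_qaly": delta_qaly,
    })
    return PSAResult(n_iterations=n, seed=seed, wtp=wtp, samples=samples,
                     parameter_draws=pd.DataFrame(
                         columns=["iteration", "parameter", "site", "value"]))


def dsa(model: MultiSiteModel, specs: list[ParameterSpec],
        wtp: float | None = None) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Each parameter is set to its low and high bound in turn (shared
    parameters in every site simultaneously), the aggregate is re-evaluated,
    and the base model restored.  Rows are ordered by descending NMB range.
    """
    wtp = model.wtp if wtp is None else wtp
    for spec in specs:
        if spec.dsa_low is None or spec.dsa_high is None:
            raise ValueError(f"parameter {spec.name!r} has no DSA bounds")
    base = model.evaluate()
    base_nmb = wtp * base.delta_qaly_agg - base.delta_cost_agg
    rows = []
    for spec in specs:
        res = {}
        for bound, value in (("low", spec.dsa_low), ("high", spec.dsa_high)):
            m = copy.deepcopy(model)
            _apply_parameter(m, spec, value)
            r = m.evaluate()
            res[bound] = r
        nmb_low = wtp * res["low"].delta_qaly_agg - res["low"].delta_cost_agg
        nmb_high = wtp * res["high"].delta_qaly_agg - res["high"].delta_cost_agg
        rows.append({
            "parameter": spec.name,
            "target": spec.target,
            "scope": spec.scope,
            "site_id": spec.site_id,
            "low": spec.dsa_low,
            "high": spec.dsa_high,
            "nmb_low": nmb_low,
            "nmb_high": nmb_high,
            "nmb_base": base_nmb,
            "nmb_range": abs(nmb_high - nmb_low),
            "icer_low": res["low"].icer_agg,
            "icer_high": res["high"].icer_agg,
        })
    out = pd.DataFrame(rows).sort_values(
        "nmb_range", ascending=False, kind="stable", ignore_index=True
    )
    return out
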