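"""Weighted multi-site aggregation of cost-effectiveness results.

A tumour-agnostic therapy is evaluated as one model containing a
partitioned-survival submodel per tumour site.  Each site's incremental
costs and QALYs are combined with epidemiological weights (the site's share
of the biomarker-positive population) into pooled incremental costs and
QALYs, from which a single aggregated ICER is derived.  ICERs themselves
are never averaged: a ratio of averages is meaningful, an average of ratios
is not.

Sites start on pooled survival evidence and can be "broken out" onto their
own evidence as it matures; every re-analysis is recorded as an immutable
model version so that the effect of new data on the decision is explicit.
"""

from __future__ import annotations

import copy
import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    ArmInputs,
    ArmResult,
    EconomicParams,
    IncrementalResult,
    TimeGrid,
    classify,
    evaluate_arm,
    incremental,
)
from .survival import (
    FittedSurvival,
    TabulatedCurve,
    fit_parametric,
    select_distribution,
    tabulate,
)

__all__ = [
    "WeightSet",
    "SiteSubmodel",
    "AggregatedResult",
    "ModelVersion",
    "MultiSiteModel",
    "normalize_weights",
    "aggregate",
    "check_reanalysis_triggers",
    "diff_versions",
    "build_model_from_ipd",
]


@dataclass
class WeightSet:
    """Normalised site weights: non-negative, summing to one."""

    weights: dict[str, float]

    def __post_init__(self):
        vals = np.array(list(self.weights.values()), float)
        if np.any(vals < 0):
            raise ValueError("weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {vals.sum()}, not 1")

    def __getitem__(self, site_id: str) -> float:
        return self.weights[site_id]

    def items(self):
        return self.weights.items()


def normalize_weights(counts: dict[str, float]) -> WeightSet:
    """Weights proportional to each site's biomarker-positive count."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("at least one count must be positive")
    return WeightSet({k: c / total for k, c in sorted(counts.items())})


@dataclass
class SiteSubmodel:
    """One tumour site: two arms of inputs plus its weight contribution."""

    site_id: str
    weight_source_count: int
    intervention: ArmInputs
    comparator: ArmInputs
    evidence_level: str = "pooled"  # pooled | site_specific
    evidence_n: int = 0
    fits: dict = field(default_factory=dict)  # (arm, endpoint) -> FittedSurvival

    def __post_init__(self):
        if self.evidence_level not in ("pooled", "site_specific"):
            raise ValueError("evidence_level must be 'pooled' or 'site_specific'")
        if self.evidence_n < 0 or self.weight_source_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class AggregatedResult:
    delta_cost_agg: float
    delta_qaly_agg: float
    classification: str
    icer_agg: float | None
    nmb_agg: float
    wtp: float
    weights: dict[str, float]
    per_site: dict[str, IncrementalResult]

    def per_site_table(self) -> pd.DataFrame:
        rows = [
            {
                "site": sid,
                "weight": self.weights[sid],
                "delta_cost": r.delta_cost,
                "delta_qaly": r.delta_qaly,
                "icer": r.icer,
                "classification": r.classification,
                "nmb": r.nmb,
            }
            for sid, r in sorted(self.per_site.items())
        ]
        return pd.DataFrame(rows)


def aggregate(per_site: dict[str, IncrementalResult], weights: WeightSet,
              wtp: float | None = None) -> AggregatedResult:
    """Pool incremental results across sites by epidemiological weight.

    Weighted sums of delta-cost and delta-QALY are formed first and the
    aggregated ICER is derived last from those sums.
    """
    missing = sorted(set(weights.weights) ^ set(per_site))
    if missing:
        raise KeyError(f"sites present in only one of weights/results: {missing}")
    # accumulate in sorted site order: permutation invariant by construction
    dc = sum(weights[s] * per_site[s].delta_cost for s in sorted(per_site))
    de = sum(weights[s] * per_site[s].delta_qaly for s in sorted(per_site))
    if wtp is None:
        wtp = next(iter(per_site.values())).wtp
    cls = classify(dc, de)
    return AggregatedResult(
        delta_cost_agg=dc,
        delta_qaly_agg=de,
        classification=cls,
        icer_agg=dc / de if cls == "icer_defined" else None,
        nmb_agg=wtp * de - dc,
        wtp=wtp,
        weights=dict(weights.weights),
        per_site=dict(per_site),
    )


@dataclass
class ModelVersion:
    """An immutable snapshot of the model, its evidence and its results."""

    version_id: int
    timestamp: str
    spec_snapshot: dict
    evidence_registry: dict[str, int]
    results: AggregatedResult


class MultiSiteModel:
    """The weighted, modular, dynamic multi-site PSM.

    Structural settings (time grid, discounting, willingness to pay) are
    shared across all site submodels; evidence and parameters may differ by
    site.  Every call to :meth:`record_version` appends an immutable version
    to the in-memory log.
    """

    def __init__(self, sites: list[SiteSubmodel], grid: TimeGrid,
                 econ: EconomicParams, wtp: float,
                 weight_source: str = "biomarker_positive_counts",
                 metadata: dict | None = None):
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        self.sites: dict[str, SiteSubmodel] = {s.site_id: s for s in sites}
        self.grid = grid
        self.econ = econ
        self.wtp = wtp
        self.weight_source = weight_source
        self.metadata = metadata or {}
        self.versions: list[ModelVersion] = []

    # -- evaluation -------------------------------------------------------

    def weights(self) -> WeightSet:
        return normalize_weights(
            {sid: s.weight_source_count for sid, s in self.sites.items()}
        )

    def evaluate_site(self, site_id: str) -> IncrementalResult:
        s = self.sites[site_id]
        iv = evaluate_arm(s.intervention, self.grid, self.econ)
        cp = evaluate_arm(s.comparator, self.grid, self.econ)
        return incremental(iv, cp, self.wtp)

    def evaluate(self) -> AggregatedResult:
        per_site = {sid: self.evaluate_site(sid) for sid in sorted(self.sites)}
        return aggregate(per_site, self.weights(), self.wtp)

    # -- versioning -------------------------------------------------------

    def record_version(self, results: AggregatedResult | None = None,
                       timestamp: str | None = None) -> ModelVersion:
        if results is None:
            results = self.evaluate()
        version = ModelVersion(
            version_id=len(self.versions) + 1,
            timestamp=timestamp
            or datetime.datetime.now(datetime.timezone.utc).isoformat(),
            spec_snapshot=self.snapshot(),
            evidence_registry={sid: s.evidence_n for sid, s in self.sites.items()},
            results=results,
        )
        self.versions.append(version)
        return version

    def breakout(self, site_id: str, site_specific_inputs: dict,
                 timestamp: str | None = None) -> ModelVersion:
        """Switch one site from pooled evidence to its own dedicated inputs.

        ``site_specific_inputs`` must provide complete ``intervention`` and
        ``comparator`` :class:`ArmInputs` (and may update ``evidence_n`` and
        ``fits``).  All other sites and all structural settings are
        untouched; a new model version is recorded.
        """
        if site_id not in self.sites:
            raise KeyError(f"unknown site {site_id!r}")
        missing = [k for k in ("intervention", "comparator")
                   if k not in site_specific_inputs]
        if missing:
            raise ValueError(f"site-specific inputs missing fields: {missing}")
        for k in ("intervention", "comparator"):
            if not isinstance(site_specific_inputs[k], ArmInputs):
                raise ValueError(f"{k} must be a complete ArmInputs block")
        site = self.sites[site_id]
        site.intervention = site_specific_inputs["intervention"]
        site.comparator = site_specific_inputs["comparator"]
        site.evidence_level = "site_specific"
        if "evidence_n" in site_specific_inputs:
            site.evidence_n = int(site_specific_inputs["evidence_n"])
        if "fits" in site_specific_inputs:
            site.fits = dict(site_specific_inputs["fits"])
        return self.record_version(timestamp=timestamp)

    # -- (de)serialisation ------------------------------------------------

    def snapshot(self) -> dict:
        return {
            "grid": {"cycle_length": self.grid.cycle_length,
                     "horizon": self.grid.horizon},
            "econ": {
                "discount_rate_costs": self.econ.discount_rate_costs,
                "discount_rate_effects": self.econ.discount_rate_effects,
                "half_cycle_correction": self.econ.half_cycle_correction,
            },
            "wtp": self.wtp,
            "weight_source": self.weight_source,
            "metadata": copy.deepcopy(self.metadata),
            "sites": {
                sid: {
                    "weight_source_count": s.weight_source_count,
                    "evidence_level": s.evidence_level,
                    "evidence_n": s.evidence_n,
                    "intervention": _arm_to_dict(s.intervention),
                    "comparator": _arm_to_dict(s.comparator),
                }
                for sid, s in sorted(self.sites.items())
            },
        }

    @classmethod
    def from_snapshot(cls, snap: dict) -> "MultiSiteModel":
        grid = TimeGrid(**snap["grid"])
        econ = EconomicParams(**snap["econ"])
        sites = [
            SiteSubmodel(
                site_id=sid,
                weight_source_count=s["weight_source_count"],
                evidence_level=s["evidence_level"],
                evidence_n=s["evidence_n"],
                intervention=_arm_from_dict(s["intervention"]),
                comparator=_arm_from_dict(s["comparator"]),
            )
            for sid, s in snap["sites"].items()
        ]
        return cls(sites, grid, econ, snap["wtp"],
                   weight_source=snap.get("weight_source",
                                          "biomarker_positive_counts"),
                   metadata=snap.get("metadata"))


_ARM_SCALARS = (
    "utility_pf", "utility_pd", "drug_cost_per_cycle", "admin_cost_per_cycle",
    "disease_mgmt_cost_pf", "disease_mgmt_cost_pd", "ae_cost_oneoff",
    "eol_cost_oneoff", "max_treatment_cycles",
)


def _arm_to_dict(arm: ArmInputs) -> dict:
    d = {k: getattr(arm, k) for k in _ARM_SCALARS}
    d["os_curve"] = {"times": arm.os_curve.times.tolist(),
                     "survival": arm.os_curve.survival.tolist()}
    d["pfs_curve"] = {"times": arm.pfs_curve.times.tolist(),
                      "survival": arm.pfs_curve.survival.tolist()}
    return d


def _arm_from_dict(d: dict) -> ArmInputs:
    kwargs = {k: d[k] for k in _ARM_SCALARS}
    kwargs["os_curve"] = TabulatedCurve(np.array(d["os_curve"]["times"]),
                                        np.array(d["os_curve"]["survival"]))
    kwargs["pfs_curve"] = TabulatedCurve(np.array(d["pfs_curve"]["times"]),
                                         np.array(d["pfs_curve"]["survival"]))
    return ArmInputs(**kwargs)


def check_reanalysis_triggers(model: MultiSiteModel,
                              registry_updates: dict[str, int],
                              thresholds: dict | None = None) -> list[str]:
    """Sites whose accumulated new evidence warrants a re-analysis.

    A site is due when its new evidence count exceeds the count at the last
    recorded version by at least ``min_new_n`` (boundary inclusive).  Pure
    function; the model is not mutated.
    """
    thresholds = thresholds or {}
    min_new_n = int(thresholds.get("min_new_n", 50))
    if min_new_n <= 0:
        raise ValueError("min_new_n must be positive")
    if model.versions:
        baseline = model.versions[-1].evidence_registry
    else:
        baseline = {sid: s.evidence_n for sid, s in model.sites.items()}
    due = []
    for sid, new_n in sorted(registry_updates.items()):
        if new_n < 0:
            raise ValueError(f"negative evidence count for site {sid!r}")
        if sid not in model.sites:
            raise KeyError(f"unknown site {sid!r}")
        if new_n - baseline.get(sid, 0) >= min_new_n:
            due.append(sid)
    return due


def _dict_diff(a, b, path="") -> list[str]:
    if isinstance(a, dict) and isinstance(b, dict):
        out = []
        for k in sorted(set(a) | set(b)):
            sub = f"{path}.{k}" if path else str(k)
            if k not in a or k not in b:
                out.append(sub)
            else:
                out.extend(_dict_diff(a[k], b[k], sub))
        return out
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        if len(a) != len(b) or any(
            not np.allclose(np.asarray(x, float), np.asarray(y, float))
            if isinstance(x, (int, float)) or isinstance(x, list)
            else x != y
            for x, y in zip(a, b)
        ):
            return [path]
        return []
    return [] if a == b else [path]


def diff_versions(v1: ModelVersion, v2: ModelVersion) -> dict:
    """Per-site and aggregate result deltas between two model versions."""
    if v1.version_id == v2.version_id:
        raise ValueError("versions are identical")
    if v1.version_id > v2.version_id:
        raise ValueError("v1 must be the older version")
    per_site = {}
    for sid in sorted(set(v1.results.per_site) | set(v2.results.per_site)):
        r1 = v1.results.per_site.get(sid)
        r2 = v2.results.per_site.get(sid)
        if r1 is None or r2 is None:
            per_site[sid] = {"status": "added" if r1 is None else "removed"}
            continue
        per_site[sid] = {
            "delta_cost_change": r2.delta_cost - r1.delta_cost,
            "delta_qaly_change": r2.delta_qaly - r1.delta_qaly,
            "icer_old": r1.icer,
            "icer_new": r2.icer,
        }
    agg = {
        "delta_cost_change": v2.results.delta_cost_agg - v1.results.delta_cost_agg,
        "delta_qaly_change": v2.results.delta_qaly_agg - v1.results.delta_qaly_agg,
        "icer_old": v1.results.icer_agg,
        "icer_new": v2.results.icer_agg,
    }
    return {
        "from_version": v1.version_id,
        "to_version": v2.version_id,
        "per_site": per_site,
        "aggregate": agg,
        "changed_fields": _dict_diff(v1.spec_snapshot, v2.spec_snapshot),
    }


# ---------------------------------------------------------------------------
# pooled-evidence model construction from IPD
# ---------------------------------------------------------------------------


def fit_best(ipd, families) -> FittedSurvival:
    """Fit each candidate family and return the best by AIC."""
    fits = []
    errors = []
    for fam in families:
        try:
            fits.append(fit_parametric(ipd, fam))
        except Exception as exc:  # keep going; a family may fail on odd data
            errors.append(f"{fam}: {exc}")
    if not fits:
        raise RuntimeError("all candidate fits failed: " + "; ".join(errors))
    return select_distribution(fits)[0]


def build_model_from_ipd(
    ipd: pd.DataFrame,
    site_meta: list[dict],
    cost_blocks: dict[str, dict],
    grid: TimeGrid,
    econ: EconomicParams,
    wtp: float,
    families: tuple[str, ...] = ("exponential", "weibull", "log_normal",
                                 "log_logistic", "gompertz",
                                 "generalized_gamma"),
    intervention_arm: str = "intervention",
    comparator_arm: str = "comparator",
) -> MultiSiteModel:
    """Assemble a multi-site model from basket-trial IPD.

    Sites flagged ``pooled`` share one survival curve per arm and endpoint,
    fitted to the stacked IPD of all pooled sites (evidence is pooled at the
    patient level, never by averaging fitted curves); ``site_specific``
    sites are fitted on their own records.  ``cost_blocks`` maps arm name to
    the cost/utility keyword arguments of :class:`ArmInputs` (optionally
    overridden per site via a ``cost_overrides`` entry in ``site_meta``).
    """
    pooled_ids = [m["site_id"] for m in site_meta
                  if m.get("evidence_level", "pooled") == "pooled"]
    pooled_fits: dict[tuple[str, str], FittedSurvival] = {}
    if pooled_ids:
        pooled_ipd = ipd[ipd["site"].isin(pooled_ids)]
        for arm in (intervention_arm, comparator_arm):
            for endpoint in ("OS", "PFS"):
                sub = pooled_ipd[(pooled_ipd["arm"] == arm)
                                 & (pooled_ipd["endpoint"] == endpoint)]
                pooled_fits[(arm, endpoint)] = fit_best(sub, families)

    sites = []
    for meta in site_meta:
        sid = meta["site_id"]
        level = meta.get("evidence_level", "pooled")
        fits = {}
        if level == "pooled":
            fits = dict(pooled_fits)
        else:
            own = ipd[ipd["site"] == sid]
            for arm in (intervention_arm, comparator_arm):
                for endpoint in ("OS", "PFS"):
                    sub = own[(own["arm"] == arm) & (own["endpoint"] == endpoint)]
                    fits[(arm, endpoint)] = fit_best(sub, families)
        overrides = meta.get("cost_overrides", {})
        arms = {}
        for role, arm in (("intervention", intervention_arm),
                          ("comparator", comparator_arm)):
            kwargs = dict(cost_blocks[role])
            kwargs.update(overrides.get(role, {}))
            arms[role] = ArmInputs(
                os_curve=tabulate(fits[(arm, "OS")], grid),
                pfs_curve=tabulate(fits[(arm, "PFS")], grid),
                **kwargs,
            )
        n_site = int(
            ipd[(ipd["site"] == sid) & (ipd["endpoint"] == "OS")].shape[0]
        )
        sites.append(
            SiteSubmodel(
                site_id=sid,
                weight_source_count=int(meta["weight_source_count"]),
                evidence_level=level,
                evidence_n=int(meta.get("evidence_n", n_site)),
                intervention=arms["intervention"],
                comparator=arms["comparator"],
                fits=fits,
            )
        )
    return MultiSiteModel(sites, grid, econ, wtp)
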