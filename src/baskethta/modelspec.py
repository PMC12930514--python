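"""Model specification schema, file formats and the persisted version log.

The whole model is described by one human-editable YAML (or JSON) document:
a global block (grid, discounting, willingness to pay, seed, units), one
block per tumour site, an optional uncertain-parameter list and scenario
overrides.  Adding a tumour site to the evaluation is just appending a site
block.  Survival evidence is given either inline (parametric family and
parameters) or as a reference to an IPD CSV file, in which case curves are
fitted at build time with pooled sites stacked at the patient level.

The version log is an append-only JSON-lines file; each record carries a
checksum so silent corruption is detected on load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .aggregation import (
    AggregatedResult,
    ModelVersion,
    MultiSiteModel,
    SiteSubmodel,
    build_model_from_ipd,
)
from .engine import ArmInputs, EconomicParams, IncrementalResult, TimeGrid
from .survival import FAMILIES, FittedSurvival, tabulate

logger = logging.getLogger("baskethta")

__all__ = [
    "ModelSpec",
    "load_spec",
    "save_spec",
    "build_model",
    "spec_hash",
    "read_ipd_csv",
    "read_km_csv",
    "read_risk_table_csv",
    "append_version",
    "load_versions",
    "VersionLogError",
]


class GlobalBlock(BaseModel):
    cycle_length: float = 1.0
    horizon: float = 480.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    half_cycle_correction: bool = True
    wtp: float = 100_000.0
    wtp_grid: list[float] | None = None
    seed: int = 0
    currency: str = "EUR"
    time_unit: str = "months"
    candidate_families: list[str] = Field(
        default_factory=lambda: list(FAMILIES)
    )

    @field_validator("candidate_families")
    @classmethod
    def _known_families(cls, v):
        unknown = [f for f in v if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown survival families: {unknown}")
        return v

    @field_validator("time_unit")
    @classmethod
    def _months_only(cls, v):
        if v != "months":
            raise ValueError("time_unit must be 'months' (no implicit conversion)")
        return v


class CurveSpec(BaseModel):
    family: str | None = None
    params: list[float] | None = None

    @model_validator(mode="after")
    def _complete(self):
        if self.family is None or self.params is None:
            raise ValueError("inline curve needs both family and params")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.params) != FAMILIES[self.family]:
            raise ValueError(
                f"{self.family} takes {FAMILIES[self.family]} parameters"
            )
        return self


class ArmSpec(BaseModel):
    os: CurveSpec
    pfs: CurveSpec
    utility_pf: float = 0.8
    utility_pd: float = 0.6
    drug_cost_per_cycle: float = 0.0
    admin_cost_per_cycle: float = 0.0
    disease_mgmt_cost_pf: float = 0.0
    disease_mgmt_cost_pd: float = 0.0
    ae_cost_oneoff: float = 0.0
    eol_cost_oneoff: float = 0.0
    max_treatment_cycles: int | None = None


class SiteSpec(BaseModel):
    site_id: str
    weight_source_count: int = Field(ge=0)
    evidence_level: str = "pooled"
    evidence_n: int = Field(default=0, ge=0)
    intervention: ArmSpec | None = None
    comparator: ArmSpec | None = None
    cost_overrides: dict = Field(default_factory=dict)

    @field_validator("evidence_level")
    @classmethod
    def _level(cls, v):
        if v not in ("pooled", "site_specific"):
            raise ValueError("evidence_level must be 'pooled' or 'site_specific'")
        return v


class ParameterBlock(BaseModel):
    name: str
    target: str
    distribution: str
    dist_params: dict
    scope: str = "shared"
    site_id: str | None = None
    dsa_low: float | None = None
    dsa_high: float | None = None


class ModelSpec(BaseModel):
    name: str = "model"
    global_block: GlobalBlock = Field(default_factory=GlobalBlock, alias="global")
    sites: list[SiteSpec]
    ipd_file: str | None = None
    cost_blocks: dict[str, dict] = Field(default_factory=dict)
    parameters: list[ParameterBlock] = Field(default_factory=list)
    scenarios: dict = Field(default_factory=dict)

    model_config = {"populate_by_name": True}

    @model_validator(mode="after")
    def _consistent(self):
        ids = [s.site_id for s in self.sites]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate site_id: {dupes}")
        known = set(ids)
        for p in self.parameters:
            if p.site_id is not None and p.site_id not in known:
                raise ValueError(
                    f"parameter {p.name!r} references unknown site {p.site_id!r}"
                )
        return self


def load_spec(path) -> ModelSpec:
    """Load and validate a YAML/JSON model specification.

    Defaults filled by the schema are logged; file references are resolved
    relative to the spec's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    spec = ModelSpec.model_validate(raw)
    filled = set(GlobalBlock.model_fields) - spec.global_block.model_fields_set
    for name in sorted(filled):
        logger.info("spec %s: default applied for global.%s = %r",
                    path.name, name, getattr(spec.global_block, name))
    if spec.ipd_file is not None and not Path(spec.ipd_file).is_absolute():
        spec.ipd_file = str((path.parent / spec.ipd_file).resolve())
    if spec.ipd_file is not None and not Path(spec.ipd_file).exists():
        raise FileNotFoundError(f"ipd_file not found: {spec.ipd_file}")
    return spec


def save_spec(spec: ModelSpec, path) -> None:
    doc = spec.model_dump(by_alias=True, exclude_none=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_hash(spec: ModelSpec | dict) -> str:
    """Stable content hash of a model specification."""
    doc = spec.model_dump(by_alias=True) if isinstance(spec, ModelSpec) else spec
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

_IPD_COLUMNS = ["site", "arm", "endpoint", "time", "event"]


def read_ipd_csv(path) -> pd.DataFrame:
    ipd = pd.read_csv(path)
    missing = [c for c in _IPD_COLUMNS if c not in ipd.columns]
    if missing:
        raise ValueError(f"IPD file {path} missing columns {missing}")
    if (ipd["time"] < 0).any():
        raise ValueError("IPD times must be non-negative")
    if not ipd["event"].isin((0, 1)).all():
        raise ValueError("IPD event indicator must be 0 or 1")
    return ipd


def read_km_csv(path):
    from .km import KMCoordinates

    df = pd.read_csv(path)
    return KMCoordinates(df["time"].to_numpy(float), df["survival"].to_numpy(float))


def read_risk_table_csv(path):
    from .km import RiskTable

    df = pd.read_csv(path)
    return RiskTable(df["time"].to_numpy(float), df["n_at_risk"].to_numpy(int))


# ---------------------------------------------------------------------------
# building the executable model
# ---------------------------------------------------------------------------


def build_model(spec: ModelSpec, ipd: pd.DataFrame | None = None) -> MultiSiteModel:
    """Turn a validated specification into an executable multi-site model."""
    g = spec.global_block
    grid = TimeGrid(cycle_length=g.cycle_length, horizon=g.horizon)
    econ = EconomicParams(
        discount_rate_costs=g.discount_rate_costs,
        discount_rate_effects=g.discount_rate_effects,
        half_cycle_correction=g.half_cycle_correction,
    )
    if ipd is None and spec.ipd_file is not None:
        ipd = read_ipd_csv(spec.ipd_file)
    needs_ipd = [s.site_id for s in spec.sites
                 if s.intervention is None or s.comparator is None]
    if needs_ipd and ipd is None:
        raise ValueError(
            f"sites without inline arm blocks need IPD (ipd_file): {needs_ipd}"
        )

    if ipd is not None and needs_ipd:
        site_meta = [
            {
                "site_id": s.site_id,
                "weight_source_count": s.weight_source_count,
                "evidence_level": s.evidence_level,
                "evidence_n": s.evidence_n or None,
                "cost_overrides": s.cost_overrides,
            }
            for s in spec.sites
        ]
        for m in site_meta:  # build_model_from_ipd defaults evidence_n to n
            if m["evidence_n"] is None:
                m.pop("evidence_n")
        model = build_model_from_ipd(
            ipd, site_meta, spec.cost_blocks, grid, econ, g.wtp,
            families=tuple(g.candidate_families),
        )
    else:
        sites = []
        for s in spec.sites:
            arms = {}
            for role in ("intervention", "comparator"):
                a: ArmSpec = getattr(s, role)
                fits = {
                    "OS": FittedSurvival(a.os.family, np.array(a.os.params)),
                    "PFS": FittedSurvival(a.pfs.family, np.array(a.pfs.params)),
                }
                arms[role] = ArmInputs(
                    os_curve=tabulate(fits["OS"], grid),
                    pfs_curve=tabulate(fits["PFS"], grid),
                    **{
                        k: getattr(a, k)
                        for k in (
                            "utility_pf", "utility_pd", "drug_cost_per_cycle",
                            "admin_cost_per_cycle", "disease_mgmt_cost_pf",
                            "disease_mgmt_cost_pd", "ae_cost_oneoff",
                            "eol_cost_oneoff", "max_treatment_cycles",
                        )
                    },
                )
            sites.append(SiteSubmodel(
                site_id=s.site_id,
                weight_source_count=s.weight_source_count,
                evidence_level=s.evidence_level,
                evidence_n=s.evidence_n,
                intervention=arms["intervention"],
                comparator=arms["comparator"],
            ))
        model = MultiSiteModel(sites, grid, econ, g.wtp)
    model.metadata.update({
        "spec_name": spec.name,
        "currency": g.currency,
        "time_unit": g.time_unit,
        "weight_source": "biomarker_positive_counts",
        "background_mortality": "hazard_max",
    })
    return model


# ---------------------------------------------------------------------------
# results serialisation and the version log
# ---------------------------------------------------------------------------


class VersionLogError(RuntimeError):
    """The version log is corrupt or inconsistent."""


def _incremental_to_dict(r: IncrementalResult) -> dict:
    return {
        "delta_cost": r.delta_cost, "delta_qaly": r.delta_qaly,
        "classification": r.classification, "icer": r.icer,
        "nmb": r.nmb, "wtp": r.wtp,
    }


def aggregated_to_dict(res: AggregatedResult) -> dict:
    return {
        "delta_cost_agg": res.delta_cost_agg,
        "delta_qaly_agg": res.delta_qaly_agg,
        "classification": res.classification,
        "icer_agg": res.icer_agg,
        "nmb_agg": res.nmb_agg,
        "wtp": res.wtp,
        "weights": res.weights,
        "per_site": {s: _incremental_to_dict(r) for s, r in
                     sorted(res.per_site.items())},
    }


def aggregated_from_dict(d: dict) -> AggregatedResult:
    return AggregatedResult(
        delta_cost_agg=d["delta_cost_agg"],
        delta_qaly_agg=d["delta_qaly_agg"],
        classification=d["classification"],
        icer_agg=d["icer_agg"],
        nmb_agg=d["nmb_agg"],
        wtp=d["wtp"],
        weights=d["weights"],
        per_site={s: IncrementalResult(**r) for s, r in d["per_site"].items()},
    )


def _record_checksum(record: dict) -> str:
    body = {k: v for k, v in record.items() if k != "checksum"}
    return hashlib.sha256(
        json.dumps(body, sort_keys=True, default=str).encode()
    ).hexdigest()


def append_version(path, version: ModelVersion) -> None:
    """Append one model version to the JSON-lines log (append-only)."""
    record = {
        "version_id": version.version_id,
        "timestamp": version.timestamp,
        "spec_snapshot": version.spec_snapshot,
        "evidence_registry": version.evidence_registry,
        "results": aggregated_to_dict(version.results),
    }
    record["checksum"] = _record_checksum(record)
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def load_versions(path) -> list[ModelVersion]:
    """Read the version log, verifying every record's checksum."""
    versions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            record = json.loads(line)
            if record.get("checksum") != _record_checksum(record):
                raise VersionLogError(
                    f"checksum mismatch at line {lineno} of {path}"
                )
            versions.append(ModelVersion(
                version_id=record["version_id"],
                timestamp=record["timestamp"],
                spec_snapshot=record["spec_snapshot"],
                evidence_registry=record["evidence_registry"],
                results=aggregated_from_dict(record["results"]),
            ))
    ids = [v.version_id for v in versions]
    if ids != sorted(ids):
        raise VersionLogError("version ids are not in ascending order")
    return versions
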