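"""Three-state partitioned survival model engine.

The cohort is partitioned at every time point directly from the two trial
endpoints: progression-free = PFS(t), progressed = OS(t) - PFS(t), dead =
1 - OS(t).  No transition probabilities are modelled; time in state is the
area under the curves.  Costs and QALYs accrue per cycle and are discounted
at annual rates with a monthly exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .survival import TabulatedCurve

__all__ = [
    "TimeGrid",
    "StateOccupancy",
    "ArmInputs",
    "EconomicParams",
    "ArmResult",
    "IncrementalResult",
    "GridMismatchError",
    "compute_occupancy",
    "discounted_sum",
    "evaluate_arm",
    "incremental",
    "classify",
]


class GridMismatchError(ValueError):
    """Curves tabulated on different grids cannot be combined."""


@dataclass(frozen=True)
class TimeGrid:
    """Model cycles: ``n_cycles`` cycles of ``cycle_length`` months."""

    cycle_length: float = 1.0
    horizon: float = 480.0

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon / self.cycle_length)

    @property
    def times(self) -> np.ndarray:
        """Cycle boundary times, length n_cycles + 1, starting at 0."""
        return np.arange(self.n_cycles + 1) * self.cycle_length


@dataclass
class StateOccupancy:
    """Point-in-time state membership at cycle boundaries.

    ``pf + pd + dead = 1`` at every boundary; ``crossings`` counts grid
    points where PFS exceeded OS and was clipped.
    """

    times: np.ndarray
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    crossings: int = 0

    def __post_init__(self):
        total = self.pf + self.pd + self.dead
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state occupancy does not sum to 1")


@dataclass
class ArmInputs:
    """Curves plus cost and utility parameters for one treatment arm.

    Drug and administration costs accrue while progression-free and on
    treatment (capped at ``max_treatment_cycles`` when set); disease
    management accrues by state; adverse-event cost is a one-off at model
    start; end-of-life cost is attached to incident deaths.
    """

    os_curve: TabulatedCurve
    pfs_curve: TabulatedCurve
    utility_pf: float = 0.8
    utility_pd: float = 0.6
    drug_cost_per_cycle: float = 0.0
    admin_cost_per_cycle: float = 0.0
    disease_mgmt_cost_pf: float = 0.0
    disease_mgmt_cost_pd: float = 0.0
    ae_cost_oneoff: float = 0.0
    eol_cost_oneoff: float = 0.0
    max_treatment_cycles: int | None = None

    def __post_init__(self):
        for u in (self.utility_pf, self.utility_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        for c in (
            self.drug_cost_per_cycle,
            self.admin_cost_per_cycle,
            self.disease_mgmt_cost_pf,
            self.disease_mgmt_cost_pd,
            self.ae_cost_oneoff,
            self.eol_cost_oneoff,
        ):
            if c < 0:
                raise ValueError("costs must be non-negative")

    def copy(self) -> "ArmInputs":
        return replace(self)


@dataclass(frozen=True)
class EconomicParams:
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    half_cycle_correction: bool = True

    def __post_init__(self):
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValueError("discount rates must be non-negative")


@dataclass
class ArmResult:
    total_cost: float
    life_years: float
    qalys: float
    cost_breakdown: dict = field(default_factory=dict)
    qaly_breakdown: dict = field(default_factory=dict)


@dataclass
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    classification: str  # dominant | dominated | icer_defined | zero_effect
    icer: float | None
    nmb: float
    wtp: float


def compute_occupancy(os_curve: TabulatedCurve, pfs_curve: TabulatedCurve,
                      grid: TimeGrid) -> StateOccupancy:
    """Partition the cohort from OS and PFS curves on a shared grid.

    Independently extrapolated curves can cross (PFS > OS); the crossing is
    repaired by clipping PFS to OS and reported via ``crossings``.
    """
    times = grid.times
    for curve in (os_curve, pfs_curve):
        if curve.times.shape != times.shape or np.any(np.abs(curve.times - times) > 1e-9):
            raise GridMismatchError("curves must be tabulated on the model grid")
    os_s = os_curve.survival
    pfs_s = pfs_curve.survival
    crossings = int(np.sum(pfs_s > os_s + 1e-12))
    pf = np.minimum(pfs_s, os_s)
    pd_ = os_s - pf
    dead = 1.0 - os_s
    return StateOccupancy(times, pf, pd_, dead, crossings)


def discounted_sum(values_per_cycle, annual_rate: float, grid: TimeGrid,
                   half_cycle_correction: bool = False) -> float:
    """Sum per-cycle values discounted at (1+r)^(-t/12).

    Discount times sit at cycle starts, or at cycle midpoints when the
    half-cycle correction is on.
    """
    v = np.asarray(values_per_cycle, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if annual_rate < 0:
        raise ValueError("rate must be non-negative")
    k = np.arange(len(v))
    t = k * grid.cycle_length
    if half_cycle_correction:
        t = t + grid.cycle_length / 2.0
    if annual_rate == 0:
        return float(v.sum())
    return float(np.sum(v * (1.0 + annual_rate) ** (-t / 12.0)))


def _cycle_means(x: np.ndarray) -> np.ndarray:
    """Trapezoidal per-cycle means from boundary values."""
    return 0.5 * (x[:-1] + x[1:])


def evaluate_arm(inputs: ArmInputs, grid: TimeGrid, econ: EconomicParams) -> ArmResult:
    """Discounted life-years, QALYs and costs for one arm."""
    occ = compute_occupancy(inputs.os_curve, inputs.pfs_curve, grid)
    mpf = _cycle_means(occ.pf)
    mpd = _cycle_means(occ.pd)
    hcc = econ.half_cycle_correction
    re, rc = econ.discount_rate_effects, econ.discount_rate_costs
    months_per_cycle = grid.cycle_length

    ly = discounted_sum((mpf + mpd) * months_per_cycle / 12.0, re, grid, hcc)
    q_pf = discounted_sum(mpf * inputs.utility_pf * months_per_cycle / 12.0, re, grid, hcc)
    q_pd = discounted_sum(mpd * inputs.utility_pd * months_per_cycle / 12.0, re, grid, hcc)

    n = grid.n_cycles
    treat = np.ones(n)
    if inputs.max_treatment_cycles is not None:
        treat[inputs.max_treatment_cycles:] = 0.0
    drug = discounted_sum(mpf * treat * inputs.drug_cost_per_cycle, rc, grid, hcc)
    admin = discounted_sum(mpf * treat * inputs.admin_cost_per_cycle, rc, grid, hcc)
    dm = discounted_sum(
        mpf * inputs.disease_mgmt_cost_pf + mpd * inputs.disease_mgmt_cost_pd,
        rc, grid, hcc,
    )
    ae_vec = np.zeros(n)
    ae_vec[0] = inputs.ae_cost_oneoff
    ae = discounted_sum(ae_vec, rc, grid, hcc)
    incident_deaths = np.diff(occ.dead)
    eol = discounted_sum(incident_deaths * inputs.eol_cost_oneoff, rc, grid, hcc)

    breakdown = {
        "drug": drug, "administration": admin, "disease_management": dm,
        "adverse_events": ae, "end_of_life": eol,
    }
    return ArmResult(
        total_cost=sum(breakdown.values()),
        life_years=ly,
        qalys=q_pf + q_pd,
        cost_breakdown=breakdown,
        qaly_breakdown={"progression_free": q_pf, "progressed": q_pd},
    )


def classify(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly == 0.0:
        return "zero_effect"
    if delta_qaly > 0 and delta_cost <= 0:
        return "dominant"
    if delta_qaly < 0 and delta_cost >= 0:
        return "dominated"
    return "icer_defined"


def incremental(intervention: ArmResult, comparator: ArmResult,
                wtp: float) -> IncrementalResult:
    """Incremental cost-effectiveness of intervention vs comparator.

    The ICER is only reported in the trade-off quadrants; dominance and
    zero-effect cases are flagged instead.  NMB = wtp * dE - dC always.
    """
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.qalys - comparator.qalys
    cls = classify(dc, de)
    icer = dc / de if cls == "icer_defined" else None
    return IncrementalResult(
        delta_cost=dc, delta_qaly=de, classification=cls,
        icer=icer, nmb=wtp * de - dc, wtp=wtp,
    )
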