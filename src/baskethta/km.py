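"""Pseudo-IPD reconstruction from published Kaplan-Meier curves.

Published survival figures report only the step coordinates of the KM
estimate and a numbers-at-risk table.  The iterative interval algorithm
implemented here allocates event and censoring times within each risk-table
interval so that the reconstructed individual patient data reproduce the
published steps and hit the published numbers at risk exactly at interval
boundaries.  A product-limit estimator is included as the round-trip
validation oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "KMCoordinates",
    "RiskTable",
    "ReconstructionError",
    "reconstruct_ipd",
    "kaplan_meier",
    "km_sup_distance",
]


class ReconstructionError(RuntimeError):
    """The curve and risk table cannot be reconciled."""


@dataclass
class KMCoordinates:
    """Step coordinates of a (published) KM curve, starting at (0, 1).

    Digitised survival values that wobble upwards are clipped to be
    non-increasing, with a warning.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.survival.shape:
            raise ValueError("times and survival must be 1-d and equal length")
        if self.times[0] != 0.0 or abs(self.survival[0] - 1.0) > 1e-9:
            raise ValueError("KM coordinates must start at (0, 1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("KM times must be strictly increasing")
        if np.any(self.survival < -1e-9) or np.any(self.survival > 1 + 1e-9):
            raise ValueError("survival must lie in [0, 1]")
        clipped = np.minimum.accumulate(np.clip(self.survival, 0.0, 1.0))
        if np.any(clipped < self.survival - 1e-9):
            warnings.warn(
                "non-monotone digitised survival clipped to non-increasing",
                stacklevel=3,
            )
        self.survival = clipped

    def step_at(self, t) -> np.ndarray:
        """Right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.times) - 1)]


@dataclass
class RiskTable:
    """Numbers at risk at published follow-up times; first entry is n."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times.shape != self.n_at_risk.shape:
            raise ValueError("times and n_at_risk must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(self.n_at_risk < 0):
            raise ValueError("n_at_risk must be non-negative")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("n_at_risk cannot increase over time")


def reconstruct_ipd(
    km: KMCoordinates,
    risk: RiskTable,
    total_events: int | None = None,
    site_id: str = "site",
    arm: str = "arm",
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Reconstruct pseudo individual patient data from KM steps.

    Interval by interval, the number censored is adjusted iteratively
    (censoring times spread uniformly within the interval) until the
    implied number at risk at the next boundary matches the risk table;
    events at each step are recovered from the survival drops.  When
    ``total_events`` is supplied the final interval's censoring is
    calibrated so the global event count matches it; otherwise subjects
    still at risk after the last step are censored there.

    Returns a DataFrame in the standard IPD schema
    (site, arm, endpoint, time, event).
    """
    if len(risk.times) < 2:
        raise ValueError("risk table needs at least 2 rows")
    if risk.times[0] != 0.0:
        raise ValueError("risk table must start at time 0")

    t_s = km.times.copy()        # click times, t_s[0] = 0
    s = km.survival.copy()       # survival at clicks, s[0] = 1
    n_click = len(t_s)
    trisk = risk.times.copy()
    nrisk = risk.n_at_risk.astype(float).copy()
    n_int = len(trisk)

    # first click index of each risk interval (may be past the last click)
    lower = np.searchsorted(t_s, trisk, side="left")
    upper = np.empty(n_int, dtype=int)
    upper[:-1] = lower[1:] - 1
    upper[-1] = n_click - 1

    n_hat = np.zeros(n_click + 1)
    n_event = np.zeros(n_click, dtype=float)
    n_cen_click = np.zeros(n_click, dtype=float)
    cen_times: list[float] = []
    km_hat = np.ones(n_click)
    n_hat[0] = nrisk[0]
    last_i = np.zeros(n_int, dtype=int)

    def _walk(i: int, ncen: int, phi: float, record: bool):
        """Process interval i with ncen censorings placed at offset phi.

        Returns (n at next boundary, max deviation of the running KM from
        the published steps inside the interval).
        """
        lo, up = lower[i], upper[i]
        span_start = t_s[lo] if lo < n_click else trisk[i]
        span_end = trisk[i + 1] if i + 1 < n_int else max(t_s[-1], span_start)
        if ncen > 0 and span_end > span_start:
            ct = span_start + ((np.arange(1, ncen + 1) - phi) / ncen) * (
                span_end - span_start
            )
        else:
            ct = np.array([])
        if up < lo:  # no published steps inside this interval
            if record:
                cen_times.extend(ct.tolist())
                if i + 1 < n_int:
                    last_i[i + 1] = last_i[i]
            return nrisk[i] - len(ct), 0.0
        # censorings binned to the click sub-intervals [t_k, t_{k+1})
        bins = np.append(t_s[lo: up + 1], max(span_end, t_s[up]) + 1e-9)
        counts, _ = np.histogram(ct, bins=bins)
        nh = nrisk[i]
        last = last_i[i]
        kmh = km_hat[last] if last > 0 else 1.0
        dev = 0.0
        for j, k in enumerate(range(lo, up + 1)):
            if k == 0:
                e = 0.0
            else:
                e = round(nh * (1.0 - s[k] / kmh)) if kmh > 0 else 0.0
                e = min(max(e, 0.0), nh)
                if e > 0 and nh > 0:
                    kmh = kmh * (1.0 - e / nh)
                dev = max(dev, abs(kmh - s[k]))
            if record:
                n_hat[k] = nh
                n_event[k] = e
                km_hat[k] = kmh if k > 0 else 1.0
                n_cen_click[k] = counts[j]
                if e > 0:
                    last = k
            nh = nh - e - counts[j]
        if record:
            cen_times.extend(ct.tolist())
            if i + 1 < n_int:
                last_i[i + 1] = last
        return nh, dev

    def _solve_censor(i: int, target: float, ncen0: int) -> tuple[int, float]:
        """Find the censor count whose walk lands closest to the target."""
        ncen = max(ncen0, 0)
        best: tuple[int, float] | None = None
        seen: set[int] = set()
        for _ in range(2 * int(nrisk[i]) + 20):
            nh_end, _ = _walk(i, ncen, 0.5, record=False)
            diff = nh_end - target
            if best is None or abs(diff) < abs(best[1]):
                best = (ncen, diff)
            if abs(diff) < 0.5 or (diff < 0 and ncen <= 0) or ncen in seen:
                break
            seen.add(ncen)
            ncen = max(int(round(ncen + diff)), 0)
        return best

    _PHI_GRID = (0.1, 0.25, 0.5, 0.75, 0.9)

    for i in range(n_int - 1):
        target = nrisk[i + 1]
        lo = lower[i]
        s_start = km_hat[last_i[i]] if last_i[i] > 0 else 1.0
        s_end = s[min(lower[i + 1], n_click) - 1]  # survival just before boundary
        guess = int(round(nrisk[i] * (s_end / max(s_start, 1e-12)) - target))
        ncen0, diff = _solve_censor(i, target, guess)
        # refine censor count and placement to best match the published
        # steps among allocations that still hit the risk-table boundary
        candidates = []
        for nc in range(max(ncen0 - 2, 0), ncen0 + 3):
            for phi in _PHI_GRID:
                nh_end, dev = _walk(i, nc, phi, record=False)
                candidates.append((round(abs(nh_end - target)), dev, nc, phi))
        candidates.sort()
        _, _, ncen, phi = candidates[0]
        nh_end, _ = _walk(i, ncen, phi, record=True)
        if nh_end < target - 0.5 and ncen == 0:
            raise ReconstructionError(
                f"risk table implies more departures than the curve permits in "
                f"interval {i} (t = {trisk[i]:g}..{trisk[i + 1]:g})"
            )
        if abs(nh_end - target) > max(2.0, 0.02 * nrisk[0]):
            raise ReconstructionError(
                f"cannot match number at risk at interval {i} "
                f"(t = {trisk[i]:g}..{trisk[i + 1]:g}): reached {nh_end:g}, "
                f"table says {target:g}"
            )
        nrisk[i + 1] = nh_end  # carry small rounding residue forward

    # final interval
    i = n_int - 1
    if total_events is not None:
        events_so_far = n_event[: lower[i]].sum()
        needed = total_events - events_so_far
        best = None
        ncen = 0
        for _ in range(int(nrisk[i]) + 10):
            nh_end, _ = _walk(i, ncen, 0.5, record=False)
            ev_total = nrisk[i] - nh_end - ncen
            diff = ev_total - needed
            if best is None or abs(diff) < abs(best[1]):
                best = (ncen, diff)
            if abs(diff) < 0.5:
                break
            if diff > 0:
                ncen += max(int(round(diff)), 1)
            elif ncen > 0:
                ncen = max(ncen + int(round(diff)), 0)
            else:
                break
        ncen = best[0]
    else:
        ncen = 0
    nh_end, _ = _walk(i, ncen, 0.5, record=True)
    # survivors at the end of the curve are administratively censored there
    residual = int(round(nh_end))
    if residual > 0:
        cen_times.extend([float(t_s[-1])] * residual)

    times = np.concatenate(
        [np.repeat(t_s[n_event > 0], n_event[n_event > 0].astype(int)), np.array(cen_times)]
    )
    events = np.concatenate(
        [np.ones(int(n_event.sum()), dtype=int), np.zeros(len(cen_times), dtype=int)]
    )
    out = pd.DataFrame(
        {
            "site": site_id,
            "arm": arm,
            "endpoint": endpoint,
            "time": times,
            "event": events,
        }
    ).sort_values("time", kind="stable", ignore_index=True)
    if len(out) != int(risk.n_at_risk[0]):
        raise ReconstructionError(
            f"reconstructed cohort size {len(out)} != initial number at risk "
            f"{int(risk.n_at_risk[0])}"
        )
    return out


def kaplan_meier(ipd) -> KMCoordinates:
    """Product-limit estimate; steps only at event times, starting at (0,1)."""
    if isinstance(ipd, pd.DataFrame):
        times = ipd["time"].to_numpy(float)
        events = ipd["event"].to_numpy(int)
    else:
        rows = list(ipd)
        times = np.asarray([r["time"] if isinstance(r, dict) else r.time for r in rows], float)
        events = np.asarray([r["event"] if isinstance(r, dict) else r.event for r in rows], int)
    if len(times) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    t = sf.index.to_numpy(float)
    v = sf.to_numpy(float)
    drops = np.concatenate([[True], np.diff(v) < -1e-12])
    drops[0] = t[0] == 0.0  # keep the origin
    keep_t, keep_v = t[drops], v[drops]
    if keep_t.size == 0 or keep_t[0] != 0.0:
        keep_t = np.concatenate([[0.0], keep_t])
        keep_v = np.concatenate([[1.0], keep_v])
    return KMCoordinates(keep_t, keep_v)


def km_sup_distance(a: KMCoordinates, b: KMCoordinates) -> float:
    """Sup-norm distance between two KM step functions on their union grid."""
    upto = min(a.times[-1], b.times[-1])
    grid = np.union1d(a.times, b.times)
    grid = grid[grid <= upto + 1e-12]
    return float(np.max(np.abs(a.step_at(grid) - b.step_at(grid))))
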