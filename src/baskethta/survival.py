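"""Parametric survival distributions for extrapolating trial time-to-event data.

Six families commonly used in health-technology assessment are supported:
exponential, Weibull, Gompertz, log-normal, log-logistic and generalized
gamma.  Each is parameterised on its natural scale (rates, shapes and scales
in per-month / month units) and fitted to right-censored individual patient
data by maximum likelihood.  Fitted objects carry the log-likelihood, AIC,
BIC and a covariance matrix on the estimation (log-transformed) scale, which
is what probabilistic sensitivity analysis samples from.

Time is measured in months throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "FAMILIES",
    "FittedSurvival",
    "LifeTable",
    "TabulatedCurve",
    "ParamDomainError",
    "FittingError",
    "survival_at",
    "fit_parametric",
    "select_distribution",
    "tabulate",
    "apply_background_mortality",
]

#: family name -> number of parameters
FAMILIES: dict[str, int] = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "log_normal": 2,
    "log_logistic": 2,
    "generalized_gamma": 3,
}

# which parameters are strictly positive (estimated on the log scale);
# the remaining parameters are unconstrained reals
_POSITIVE = {
    "exponential": (True,),
    "weibull": (True, True),
    "gompertz": (False, True),          # shape may be negative, rate > 0
    "log_normal": (False, True),        # mu real, sigma > 0
    "log_logistic": (True, True),
    "generalized_gamma": (False, True, False),  # mu, sigma > 0, Q real
}

_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "log_normal": ("mu", "sigma"),
    "log_logistic": ("shape", "scale"),
    "generalized_gamma": ("mu", "sigma", "Q"),
}


class ParamDomainError(ValueError):
    """Parameter vector outside the family's domain."""


class FittingError(RuntimeError):
    """Maximum-likelihood fitting failed (no events, non-convergence...)."""


def _check_params(family: str, params: np.ndarray) -> np.ndarray:
    if family not in FAMILIES:
        raise ParamDomainError(f"unknown family {family!r}")
    params = np.asarray(params, dtype=float)
    if params.shape != (FAMILIES[family],):
        raise ParamDomainError(
            f"{family} takes {FAMILIES[family]} parameters, got {params.shape}"
        )
    if not np.all(np.isfinite(params)):
        raise ParamDomainError(f"non-finite parameters for {family}: {params}")
    for value, positive in zip(params, _POSITIVE[family]):
        if positive and value <= 0:
            raise ParamDomainError(
                f"{family} requires positive parameters where applicable, got {params}"
            )
    return params


def _log_sf(family: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """log S(t); t >= 0."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return -rate * t
    if family == "weibull":
        shape, scale = params
        return -((t / scale) ** shape)
    if family == "gompertz":
        shape, rate = params
        if abs(shape) < 1e-12:
            return -rate * t
        return -(rate / shape) * np.expm1(shape * t)
    if family == "log_normal":
        mu, sigma = params
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sigma
        return stats.norm.logsf(z)
    if family == "log_logistic":
        shape, scale = params
        with np.errstate(divide="ignore", over="ignore"):
            return -np.log1p((t / scale) ** shape)
    if family == "generalized_gamma":
        return _gengamma_logsf(params, t)
    raise ParamDomainError(f"unknown family {family!r}")


def _log_pdf(family: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """log f(t); t > 0."""
    t = np.asarray(t, dtype=float)
    logt = np.log(t)
    if family == "exponential":
        (rate,) = params
        return np.log(rate) - rate * t
    if family == "weibull":
        shape, scale = params
        return (
            np.log(shape / scale)
            + (shape - 1.0) * (logt - np.log(scale))
            - (t / scale) ** shape
        )
    if family == "gompertz":
        shape, rate = params
        return np.log(rate) + shape * t + _log_sf(family, params, t)
    if family == "log_normal":
        mu, sigma = params
        z = (logt - mu) / sigma
        return stats.norm.logpdf(z) - np.log(sigma) - logt
    if family == "log_logistic":
        shape, scale = params
        u = shape * (logt - np.log(scale))
        return np.log(shape) - logt + u - 2.0 * np.logaddexp(0.0, u)
    if family == "generalized_gamma":
        return _gengamma_logpdf(params, t)
    raise ParamDomainError(f"unknown family {family!r}")


def _gengamma_logsf(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    # (mu, sigma, Q) parameterisation; Q -> 0 reduces to the log-normal
    mu, sigma, q = params
    if abs(q) < 1e-8:
        return stats.norm.logsf((np.log(t) - mu) / sigma)
    with np.errstate(divide="ignore", over="ignore"):
        w = (np.log(t) - mu) / sigma
        a = q ** -2
        u = a * np.exp(q * w)
        if q > 0:
            p = special.gammaincc(a, u)
        else:
            p = special.gammainc(a, u)
    with np.errstate(divide="ignore"):
        out = np.log(np.clip(p, 0.0, 1.0))
    return np.where(np.asarray(t) <= 0, 0.0, out)


def _gengamma_logpdf(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    mu, sigma, q = params
    logt = np.log(t)
    if abs(q) < 1e-8:
        z = (logt - mu) / sigma
        return stats.norm.logpdf(z) - np.log(sigma) - logt
    a = q ** -2
    w = (logt - mu) / sigma
    return (
        np.log(abs(q))
        + a * np.log(a)
        - special.gammaln(a)
        - np.log(sigma)
        - logt
        + a * (q * w - np.exp(q * w))
    )


@dataclass
class FittedSurvival:
    """A fitted (or directly specified) parametric survival distribution.

    ``params`` are on the natural scale; ``cov`` is the covariance of the
    estimates on the transformed scale (log for positive parameters), which
    is what :func:`sample_params` draws from.
    """

    family: str
    params: np.ndarray
    log_likelihood: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    n_subjects: int = 0
    n_events: int = 0
    cov: np.ndarray | None = None
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = _check_params(self.family, self.params)

    @property
    def n_params(self) -> int:
        return FAMILIES[self.family]

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.family]

    def survival(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        out = np.exp(_log_sf(self.family, self.params, np.maximum(t, 0.0)))
        out = np.where(t == 0.0, 1.0, out)
        return float(out) if out.ndim == 0 else out

    def cumulative_hazard(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return -_log_sf(self.family, self.params, t)

    def params_se(self) -> np.ndarray:
        """Natural-scale standard errors (delta method on log-scale params)."""
        if self.cov is None:
            raise ValueError("fit has no covariance")
        se_t = np.sqrt(np.diag(self.cov))
        scale = np.where(_positive_mask(self.family), np.abs(self.params), 1.0)
        return se_t * scale

    def sample_params(self, rng: np.random.Generator, size: int | None = None):
        """Draw parameter vectors from the asymptotic MVN on the fit scale."""
        if self.cov is None:
            raise ValueError("fit has no covariance")
        theta = _transform(self.family, self.params)
        draws = rng.multivariate_normal(theta, self.cov, size=size)
        if size is None:
            return _untransform(self.family, draws)
        return np.apply_along_axis(lambda d: _untransform(self.family, d), 1, draws)


def _positive_mask(family: str) -> np.ndarray:
    return np.array(_POSITIVE[family], dtype=bool)


def _transform(family: str, params: np.ndarray) -> np.ndarray:
    mask = _positive_mask(family)
    out = np.array(params, dtype=float)
    out[mask] = np.log(out[mask])
    return out


def _untransform(family: str, theta: np.ndarray) -> np.ndarray:
    mask = _positive_mask(family)
    out = np.array(theta, dtype=float)
    out[mask] = np.exp(out[mask])
    return out


def survival_at(fit: FittedSurvival, t) -> np.ndarray | float:
    """S(t) for a fitted distribution; S(0)=1 and S is non-increasing."""
    return fit.survival(t)


def _extract_times_events(ipd) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ipd, pd.DataFrame):
        times = ipd["time"].to_numpy(dtype=float)
        events = ipd["event"].to_numpy(dtype=int)
    else:
        rows = list(ipd)
        times = np.array([getattr(r, "time", None) or r["time"] for r in rows], float)
        events = np.array(
            [r.event if hasattr(r, "event") else r["event"] for r in rows], int
        )
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("event indicator must be 0 or 1")
    return times, events


def _neg_loglik(family: str, theta: np.ndarray, times, events) -> float:
    params = _untransform(family, theta)
    try:
        ll = np.sum(
            events * _log_pdf(family, params, times)
            + (1 - events) * _log_sf(family, params, times)
        )
    except FloatingPointError:
        return np.inf
    if not np.isfinite(ll):
        return np.inf
    return -ll


def _starting_points(family: str, times, events) -> list[np.ndarray]:
    """Natural-scale starting values (several for the hard families)."""
    d = events.sum()
    exposure = times.sum()
    rate0 = d / max(exposure, 1e-12)
    et = times[events == 1]
    et = et[et > 0]
    if et.size == 0:
        et = times[times > 0]
    mu0 = float(np.mean(np.log(et)))
    sig0 = float(np.std(np.log(et))) or 1.0
    if family == "exponential":
        return [np.array([rate0])]
    if family == "weibull":
        return [np.array([1.0, 1.0 / rate0])]
    if family == "gompertz":
        return [np.array([s, rate0]) for s in (1e-3, 0.05, -0.02)]
    if family == "log_normal":
        return [np.array([mu0, sig0])]
    if family == "log_logistic":
        return [np.array([1.5, float(np.median(times[times > 0]))])]
    if family == "generalized_gamma":
        return [np.array([mu0, sig0, q]) for q in (1.0, 0.5, -0.5)]
    raise ParamDomainError(f"unknown family {family!r}")


def fit_parametric(ipd, family: str) -> FittedSurvival:
    """Maximum-likelihood fit of ``family`` to right-censored data.

    ``ipd`` is a DataFrame (or record sequence) with ``time`` (months) and
    ``event`` (1 = observed, 0 = censored) columns; all records should come
    from one arm and endpoint.  Raises :class:`FittingError` when there are
    no events (the likelihood is then unbounded as the hazard tends to 0)
    or when the optimiser fails to converge.
    """
    if family not in FAMILIES:
        raise ParamDomainError(f"unknown family {family!r}")
    times, events = _extract_times_events(ipd)
    n = len(times)
    if n < 2:
        raise FittingError("need at least 2 records")
    d = int(events.sum())
    if d == 0:
        raise FittingError("no events observed; likelihood unbounded")
    # zero survival times break the log-time families; nudge them
    times = np.where(times <= 0, 1e-8, times)

    if family == "exponential":
        # closed-form MLE: rate = events / total exposure
        rate = d / times.sum()
        ll = d * np.log(rate) - rate * times.sum()
        cov = np.array([[1.0 / d]])  # var(log rate) = 1/d
        return _finish(family, np.array([rate]), ll, n, d, cov, {"method": "closed_form"})

    best = None
    for start in _starting_points(family, times, events):
        theta0 = _transform(family, start)
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                lambda th: _neg_loglik(family, th, times, events),
                theta0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
        if best is None or (res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FittingError(f"{family} fit failed to converge")
    if not best.success and best.fun == np.inf:
        raise FittingError(f"{family} fit failed: {best.message}")

    theta_hat = best.x
    with np.errstate(all="ignore"):
        hess = approx_hess(theta_hat, lambda th: _neg_loglik(family, th, times, events))
    try:
        cov = np.linalg.inv(hess)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    params = _untransform(family, theta_hat)
    return _finish(
        family, params, -best.fun, n, d, cov,
        {"method": "nelder-mead", "converged": bool(best.success)},
    )


def _finish(family, params, ll, n, d, cov, info) -> FittedSurvival:
    k = FAMILIES[family]
    return FittedSurvival(
        family=family,
        params=np.asarray(params, float),
        log_likelihood=float(ll),
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n),
        n_subjects=int(n),
        n_events=int(d),
        cov=np.asarray(cov, float),
        fit_info=info,
    )


_FAMILY_ORDER = list(FAMILIES)


def select_distribution(fits) -> list[FittedSurvival]:
    """Rank candidate fits by AIC (ascending).

    Ties are broken by fewer parameters, then by family-name order.  The
    ranking is advisory: goodness of fit never replaces visual inspection
    and clinical plausibility, so callers may override it.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(
        fits,
        key=lambda f: (f.aic, f.n_params, _FAMILY_ORDER.index(f.family)),
    )


# ---------------------------------------------------------------------------
# tabulated curves, life tables and background mortality
# ---------------------------------------------------------------------------


@dataclass
class TabulatedCurve:
    """A survival curve tabulated on grid boundary times (months)."""

    times: np.ndarray
    survival: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have equal length")
        if self.times[0] != 0.0 or abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("curve must start at (0, 1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1 + 1e-12):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        self.survival = np.clip(self.survival, 0.0, 1.0)


def tabulate(fit: FittedSurvival, grid) -> TabulatedCurve:
    """Evaluate a fitted distribution on a model time grid."""
    times = grid.times if hasattr(grid, "times") else np.asarray(grid, float)
    return TabulatedCurve(times, fit.survival(times), {"family": fit.family})


class LifeTable:
    """General-population annual mortality by age and sex.

    Built from rows of (age in whole years, sex, qx = annual probability of
    death).  Ages must be contiguous within each sex.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required.issubset(table.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        t = table.copy()
        if ((t["qx"] < 0) | (t["qx"] > 1)).any():
            raise ValueError("qx must lie in [0, 1]")
        for sex, sub in t.groupby("sex"):
            ages = np.sort(sub["age"].to_numpy())
            if np.any(np.diff(ages) != 1):
                raise ValueError(f"ages not contiguous for sex {sex!r}")
        self._qx = {
            sex: sub.set_index("age")["qx"].sort_index() for sex, sub in t.groupby("sex")
        }
        self.sexes = tuple(self._qx)
        self.age_range = (
            int(min(s.index.min() for s in self._qx.values())),
            int(max(s.index.max() for s in self._qx.values())),
        )

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def monthly_hazard(self, age_years: float, sex_mix: dict) -> float:
        """Cohort-average monthly mortality hazard at an attained age.

        Annual probabilities convert via h = -ln(1 - qx) / 12; the sex mix
        collapses the sexes into one cohort-level hazard.
        """
        age = int(np.floor(age_years))
        total_w = sum(sex_mix.values())
        h = 0.0
        for sex, w in sex_mix.items():
            if sex not in self._qx:
                raise KeyError(f"life table has no sex {sex!r}")
            col = self._qx[sex]
            if age not in col.index:
                raise ValueError(
                    f"life table does not cover age {age} for sex {sex!r}"
                )
            q = float(col.loc[age])
            h += (w / total_w) * (-np.log1p(-min(q, 1 - 1e-12)) / 12.0)
        return h


def apply_background_mortality(
    fit_or_curve,
    life_table: LifeTable,
    start_age: float,
    sex_mix: dict,
    grid,
) -> TabulatedCurve:
    """Constrain extrapolated survival by general-population mortality.

    At every cycle the applied hazard is max(model hazard, cohort-average
    general-population hazard at the attained age), so the adjusted curve
    never exceeds the unadjusted curve nor the general-population survivor
    curve from ``start_age``.  The hazard-max convention is recorded in the
    output metadata.  Applying the adjustment twice is a no-op.
    """
    times = grid.times if hasattr(grid, "times") else np.asarray(grid, float)
    if isinstance(fit_or_curve, TabulatedCurve):
        if fit_or_curve.times.shape != times.shape or np.any(
            np.abs(fit_or_curve.times - times) > 1e-9
        ):
            raise ValueError("curve is tabulated on a different grid")
        s = fit_or_curve.survival
    else:
        s = np.asarray(fit_or_curve.survival(times), float)

    horizon_age = start_age + times[-1] / 12.0
    missing = [
        a
        for a in range(int(np.floor(start_age)), int(np.floor(horizon_age)) + 1)
        if any(a not in life_table._qx[sex].index for sex in sex_mix)
    ]
    if missing:
        raise ValueError(
            f"life table does not cover attained ages {missing} over the horizon"
        )

    dt = np.diff(times)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s[:-1] > 0, s[1:] / np.maximum(s[:-1], 1e-300), 0.0)
        h_model = np.where(ratio > 0, -np.log(ratio), np.inf)  # per-cycle cum. hazard
    mid_ages = start_age + (times[:-1] + dt / 2.0) / 12.0
    h_pop = np.array([life_table.monthly_hazard(a, sex_mix) for a in mid_ages]) * dt
    h_adj = np.maximum(h_model, h_pop)
    s_adj = np.empty_like(s)
    s_adj[0] = 1.0
    s_adj[1:] = np.exp(-np.cumsum(h_adj))
    return TabulatedCurve(
        times,
        np.minimum.accumulate(np.clip(s_adj, 0.0, 1.0)),
        {"background_mortality": "hazard_max", "start_age": start_age},
    )
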