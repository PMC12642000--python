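"""Drug-parameter estimation by naive-pooled nonlinear least squares.

The free parameters (any subset of sigma_tight, sigma_leaky, clearance,
ka) are fitted to plasma concentration-time observations by minimising an
error-model objective, by default the log-additive sum of squared
log(obs/pred) residuals, which matches the multiplicative structure of the
fold-error statistics used for validation.  Asymptotic 95% confidence
intervals and %CV come from the Gauss-Newton approximation to the Hessian
at the optimum.  Optimisation restarts from several jittered initial
points and keeps the best objective; results are deterministic for a given
seed.

:class:`MPBPKRegressor` exposes the fit through the scikit-learn estimator
protocol (``fit(X, y)`` on times/concentrations, ``predict``,
``get_params``/``set_params``), so it composes with sklearn tooling; the
module-level :func:`fit` is a thin wrapper over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .model import simulate
from .params import DoseEvent, DrugParams, PhysiologyParams

__all__ = ["FitSpec", "FitResult", "MPBPKRegressor", "fit", "profile_sensitivity"]

_FITTABLE = ("sigma_tight", "sigma_leaky", "clearance", "ka")

_DEFAULT_BOUNDS = {
    "sigma_tight": (0.5, 1.0),
    "sigma_leaky": (0.5, 1.0),
    "clearance": (1e-4, 1.0),
    "ka": (1e-3, 50.0),
}


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and how.

    ``error_model`` is one of ``log_additive`` (residual log(obs) -
    log(pred)), ``proportional`` ((obs - pred)/pred) or ``additive``
    (obs - pred).
    """

    free_parameters: tuple[str, ...] = ("sigma_tight", "sigma_leaky", "clearance")
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    error_model: str = "log_additive"
    initial_values: dict[str, float] = field(default_factory=dict)
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.free_parameters:
            if p not in _FITTABLE:
                raise ValueError(f"cannot fit parameter {p!r}")
        if self.error_model not in ("log_additive", "proportional", "additive"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def bound(self, p: str) -> tuple[float, float]:
        return self.bounds.get(p, _DEFAULT_BOUNDS[p])


@dataclass
class FitResult:
    """Point estimates with asymptotic uncertainty."""

    estimates: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    cv_percent: dict[str, float]
    objective_value: float
    converged: bool
    residuals: np.ndarray
    n_obs: int
    error_model: str
    free_parameters: tuple[str, ...]


class MPBPKRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator fitting mPBPK drug parameters to plasma data.

    Parameters
    ----------
    physio : PhysiologyParams
        Subject physiology held fixed during estimation.
    doses : sequence of DoseEvent
        Administered doses generating the observed profile.
    drug : DrugParams
        Starting drug parameters; fixed parameters keep these values.
    free : tuple of str
        Subset of ``{sigma_tight, sigma_leaky, clearance, ka}`` to estimate.
    error_model, bounds, initial_values, n_starts, random_state
        See :class:`FitSpec`.
    superpose_baseline : bool
        Whether observations include the endogenous baseline.
    sim_rtol : float
        Relative tolerance of the inner ODE solves.

    Attributes (after ``fit``)
    --------------------------
    params_, ci95_, cv_percent_, objective_, converged_, result_
    """

    def __init__(
        self,
        physio: PhysiologyParams = None,
        doses: Sequence[DoseEvent] = (),
        drug: DrugParams = None,
        free: tuple[str, ...] = ("sigma_tight", "sigma_leaky", "clearance"),
        error_model: str = "log_additive",
        bounds: dict | None = None,
        initial_values: dict | None = None,
        n_starts: int = 5,
        random_state: int = 0,
        superpose_baseline: bool = False,
        sim_rtol: float = 1e-8,
    ):
        self.physio = physio
        self.doses = doses
        self.drug = drug
        self.free = free
        self.error_model = error_model
        self.bounds = bounds
        self.initial_values = initial_values
        self.n_starts = n_starts
        self.random_state = random_state
        self.superpose_baseline = superpose_baseline
        self.sim_rtol = sim_rtol

    # -- internals ---------------------------------------------------------

    def _spec(self) -> FitSpec:
        return FitSpec(
            free_parameters=tuple(self.free),
            bounds=self.bounds or {},
            error_model=self.error_model,
            initial_values=self.initial_values or {},
            n_starts=self.n_starts,
            seed=self.random_state,
        )

    def _drug_with(self, theta: np.ndarray) -> DrugParams:
        return self.drug.model_copy(update=dict(zip(self.free, (float(v) for v in theta))))

    def _predict_theta(self, theta: np.ndarray, times: np.ndarray) -> np.ndarray:
        prof = simulate(
            self.physio,
            self._drug_with(theta),
            self.doses,
            times,
            superpose_baseline=self.superpose_baseline,
            rtol=self.sim_rtol,
        )
        return prof.plasma

    def _residuals(self, theta: np.ndarray, times: np.ndarray, y: np.ndarray) -> np.ndarray:
        pred = self._predict_theta(theta, times)
        if self.error_model == "additive":
            return y - pred
        if self.error_model == "proportional":
            return (y - pred) / pred
        bad = np.flatnonzero(pred <= 0)
        if bad.size:
            raise ValueError(
                f"prediction is non-positive at t={times[bad[0]]:g} day; "
                "log-additive error model undefined there"
            )
        return np.log(y) - np.log(pred)

    # -- sklearn protocol --------------------------------------------------

    def fit(self, X, y) -> "MPBPKRegressor":
        """Fit free parameters to observations ``y`` at times ``X`` (days)."""
        if self.physio is None or self.drug is None:
            raise ValueError("physio and drug must be provided")
        spec = self._spec()
        times = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if times.shape != y.shape:
            raise ValueError("X and y must have equal length")
        order = np.argsort(times)
        times, y = times[order], y[order]
        if len(y) < len(self.free) + 1:
            raise ValueError("need at least n_free + 1 observations")
        if self.error_model == "log_additive" and np.any(y <= 0):
            raise ValueError("log-additive error model requires positive observations")

        lo = np.array([spec.bound(p)[0] for p in self.free])
        hi = np.array([spec.bound(p)[1] for p in self.free])
        x0 = np.array(
            [
                spec.initial_values.get(p, getattr(self.drug, p) or 0.1)
                for p in self.free
            ],
            dtype=float,
        )
        x0 = np.clip(x0, lo, hi)

        rng = np.random.default_rng(spec.seed)
        best = None
        n_ok = 0
        for k in range(spec.n_starts):
            start = x0 if k == 0 else np.clip(x0 * rng.uniform(0.8, 1.2, len(x0)), lo, hi)
            try:
                res = optimize.least_squares(
                    self._residuals,
                    start,
                    args=(times, y),
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except (ValueError, RuntimeError):
                continue
            if not res.success:
                continue
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res

        if best is None:
            self.converged_ = False
            self.params_ = {p: float(v) for p, v in zip(self.free, x0)}
            self.ci95_ = {p: (np.nan, np.nan) for p in self.free}
            self.cv_percent_ = {p: np.nan for p in self.free}
            self.objective_ = np.nan
            self.residuals_ = np.full_like(y, np.nan)
        else:
            self.converged_ = True
            self.params_ = {p: float(v) for p, v in zip(self.free, best.x)}
            self.objective_ = float(2.0 * best.cost)  # sum of squared residuals
            self.residuals_ = best.fun
            self.ci95_, self.cv_percent_ = self._uncertainty(best, len(y))

        self.n_obs_ = len(y)
        self.times_ = times
        self.result_ = FitResult(
            estimates=dict(self.params_),
            ci95=dict(self.ci95_),
            cv_percent=dict(self.cv_percent_),
            objective_value=self.objective_,
            converged=self.converged_,
            residuals=self.residuals_,
            n_obs=self.n_obs_,
            error_model=self.error_model,
            free_parameters=tuple(self.free),
        )
        return self

    def _uncertainty(self, res, n: int) -> tuple[dict, dict]:
        """Gauss-Newton covariance: s^2 (J'J)^-1 with s^2 = SSR/(n-p)."""
        p = len(res.x)
        dof = max(n - p, 1)
        s2 = 2.0 * res.cost / dof
        JtJ = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.inv(JtJ)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        tq = stats.t.ppf(0.975, dof)
        ci = {}
        cv = {}
        for name, est, s in zip(self.free, res.x, se):
            ci[name] = (float(est - tq * s), float(est + tq * s))
            cv[name] = float(100.0 * s / abs(est)) if est != 0 else np.inf
        return ci, cv

    def predict(self, X) -> np.ndarray:
        """Predicted plasma concentrations at times ``X`` (days)."""
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        times = np.asarray(X, dtype=float).reshape(-1)
        order = np.argsort(times)
        inv = np.argsort(order)
        theta = np.array([self.params_[p] for p in self.free])
        return self._predict_theta(theta, times[order])[inv]

    def objective_at(self, overrides: dict[str, float], X, y) -> float:
        """Objective value (SSR of the error model) at given parameter values."""
        theta = np.array([overrides.get(p, self.params_[p]) for p in self.free])
        r = self._residuals(theta, np.asarray(X, float).reshape(-1), np.asarray(y, float).reshape(-1))
        return float(np.sum(r**2))


def fit(
    data_times: np.ndarray,
    data_conc: np.ndarray,
    physio: PhysiologyParams,
    drug: DrugParams,
    doses: Sequence[DoseEvent],
    spec: FitSpec | None = None,
    superpose_baseline: bool = False,
) -> FitResult:
    """Functional front end over :class:`MPBPKRegressor`."""
    spec = spec or FitSpec()
    est = MPBPKRegressor(
        physio=physio,
        doses=list(doses),
        drug=drug,
        free=spec.free_parameters,
        error_model=spec.error_model,
        bounds=spec.bounds,
        initial_values=spec.initial_values,
        n_starts=spec.n_starts,
        random_state=spec.seed,
        superpose_baseline=superpose_baseline,
    )
    est.fit(data_times, data_conc)
    return est.result_


def profile_sensitivity(
    estimator: MPBPKRegressor,
    parameter: str,
    X,
    y,
    span: float = 0.5,
    n_points: int = 21,
) -> tuple[np.ndarray, np.ndarray]:
    """Objective value along a +/-span sweep of one fitted parameter.

    Other parameters stay at their estimates.  Documents the (weak)
    identifiability of the reflection coefficients from plasma-only data.
    Returns (parameter values, objective values).
    """
    if not hasattr(estimator, "params_"):
        raise ValueError("estimator is not fitted")
    if not estimator.converged_:
        raise ValueError("sweep requires a converged fit")
    if parameter not in estimator.free:
        raise ValueError(f"parameter {parameter!r} was fixed in the fit")
    center = estimator.params_[parameter]
    values = center * np.linspace(1.0 - span, 1.0 + span, n_points)
    spec = estimator._spec()
    lo, hi = spec.bound(parameter)
    values = np.clip(values, lo, hi)
    obj = np.array([estimator.objective_at({parameter: v}, X, y) for v in values])
    return values, obj
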