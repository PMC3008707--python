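"""Parameter estimation: fit selected model parameters to measurements.

The user names free parameters (global, or reaction-local as
``reaction_id.parameter_id``) with bounds; the fitter minimises the
weighted sum of squared residuals between simulated trajectories sampled
at the measurement time points and the measured values, over the entities
the result set binds.

The optimiser is a reproducible two-stage default: a seeded bounded
stochastic global search (differential evolution) followed by a
derivative-free local polish (Nelder-Mead).  The best point ever seen —
including the starting point — is kept, so the final objective never
exceeds the initial one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .model import Model, Parameter
from .ode import SimulationError, build_rate_system, integrate_grid
from .sbrml import ResultSet

__all__ = ["FitParameter", "FitSpec", "FitReport", "objective", "calibrate"]

PENALTY = 1e12  # objective value charged to a failed simulation


@dataclass(frozen=True)
class FitParameter:
    locator: str  # global parameter id, or "reaction_id.local_id"
    lower: float
    upper: float
    initial: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.locator}: lower bound {self.lower} not below "
                f"upper bound {self.upper}")


@dataclass
class FitSpec:
    parameters: list[FitParameter]
    weighting: str = "none"  # none | per_column_std
    method: str = "de+nm"
    max_evaluations: int = 2000
    seed: int = 0
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-9


@dataclass
class FitReport:
    fitted: dict[str, float]
    bounds_hit: dict[str, bool]
    initial_objective: float
    final_objective: float
    objective_trace: list[float]
    residuals: list[dict]
    evaluations: int
    seed: int
    penalised_evaluations: int = 0

    def to_dict(self) -> dict:
        return dict(vars(self))


def _resolve_locator(model: Model, locator: str) -> Parameter:
    if "." in locator:
        rid, pid = locator.split(".", 1)
        rxn = model.reaction_by_id(rid)
        if rxn.kinetic_law is None:
            raise KeyError(f"{locator}: reaction has no kinetic law")
        for p in rxn.kinetic_law.local_parameters:
            if p.id == pid:
                return p
        raise KeyError(f"{locator}: no local parameter {pid!r}")
    for p in model.global_parameters:
        if p.id == locator:
            return p
    raise KeyError(f"no global parameter {locator!r}")


def _set_theta(model: Model, spec: FitSpec, theta: np.ndarray) -> None:
    for fp, value in zip(spec.parameters, theta):
        _resolve_locator(model, fp.locator).value = float(value)


def _simulate_at(model: Model, times: np.ndarray, rtol: float,
                 atol: float) -> dict[str, np.ndarray]:
    system = build_rate_system(model)
    x0 = np.array([s.initial_concentration for s in model.species], dtype=float)
    sol = integrate_grid(system, x0, np.asarray(times, dtype=float),
                         rtol=rtol, atol=atol)
    return {sid: sol.y[i] for i, sid in enumerate(system.species_ids)}


def _column_weights(data: ResultSet, weighting: str) -> np.ndarray:
    if weighting == "per_column_std":
        stds = data.values.std(axis=0, ddof=0)
        return 1.0 / np.where(stds > 0, stds, 1.0) ** 2
    return np.ones(len(data.columns))


def objective(
    model: Model,
    data: ResultSet,
    spec: FitSpec,
    theta: np.ndarray,
    _bindings: Optional[dict[str, str]] = None,
) -> float:
    """Weighted sum of squared residuals at parameter vector *theta*.

    A failed simulation is charged a large finite penalty so the optimiser
    stays total.
    """
    model = copy.deepcopy(model)
    _set_theta(model, spec, theta)
    bindings = _bindings or data.resolve(model)
    weights = _column_weights(data, spec.weighting)
    try:
        traj = _simulate_at(model, data.times, spec.sim_rtol, spec.sim_atol)
    except SimulationError:
        return PENALTY
    total = 0.0
    for j, cb in enumerate(data.columns):
        resid = traj[bindings[cb.column]] - data.values[:, j]
        total += weights[j] * float(resid @ resid)
    return total


def calibrate(model: Model, data: ResultSet,
              spec: FitSpec) -> tuple[Model, FitReport]:
    """Fit the free parameters; return the calibrated model and report.

    Reproducible for a fixed seed.  Raises if the spec names no free
    parameters or any data column fails to resolve against the model.
    """
    if not spec.parameters:
        raise ValueError("fit spec names no free parameters")
    for fp in spec.parameters:
        _resolve_locator(model, fp.locator)  # raises on a bad locator
    bindings = data.resolve(model)  # raises listing unresolved columns

    base = copy.deepcopy(model)
    lower = np.array([fp.lower for fp in spec.parameters])
    upper = np.array([fp.upper for fp in spec.parameters])
    x0 = np.array([
        fp.initial if fp.initial is not None
        else np.clip(_resolve_locator(base, fp.locator).value,
                     fp.lower, fp.upper)
        for fp in spec.parameters
    ])

    state = {"best_x": x0.copy(), "best_f": np.inf, "evals": 0,
             "penalised": 0, "trace": []}

    # one working copy, locators resolved once: evaluations just poke values
    work = copy.deepcopy(base)
    targets = [_resolve_locator(work, fp.locator) for fp in spec.parameters]
    weights = _column_weights(data, spec.weighting)

    def f(theta: np.ndarray) -> float:
        for target, value in zip(targets, theta):
            target.value = float(value)
        try:
            traj = _simulate_at(work, data.times, spec.sim_rtol, spec.sim_atol)
            value = 0.0
            for j, cb in enumerate(data.columns):
                resid = traj[bindings[cb.column]] - data.values[:, j]
                value += weights[j] * float(resid @ resid)
        except SimulationError:
            value = PENALTY
        state["evals"] += 1
        if value >= PENALTY:
            state["penalised"] += 1
        if value < state["best_f"]:
            state["best_f"] = value
            state["best_x"] = np.array(theta, dtype=float)
            state["trace"].append(value)
        return value

    initial_objective = f(x0)

    n = len(spec.parameters)
    de_budget = max(spec.max_evaluations // 2, 20 * n)
    popsize = min(15, max(5, de_budget // (10 * n)))
    maxiter = max(1, de_budget // (popsize * n))
    differential_evolution(
        f, bounds=list(zip(lower, upper)), seed=spec.seed,
        maxiter=maxiter, popsize=popsize, tol=1e-10, polish=False,
        init="sobol", updating="deferred")

    res = minimize(
        f, np.clip(state["best_x"], lower, upper), method="Nelder-Mead",
        bounds=list(zip(lower, upper)),
        options={"maxfev": max(spec.max_evaluations // 4, 50 * n),
                 "xatol": 1e-10, "fatol": 1e-12})
    f(np.clip(res.x, lower, upper))

    best_x, best_f = state["best_x"], state["best_f"]
    fitted_model = copy.deepcopy(base)
    _set_theta(fitted_model, spec, best_x)

    span = upper - lower
    bounds_hit = {
        fp.locator: bool(best_x[i] - lower[i] <= 1e-6 * span[i]
                         or upper[i] - best_x[i] <= 1e-6 * span[i])
        for i, fp in enumerate(spec.parameters)
    }
    residuals: list[dict] = []
    try:
        traj = _simulate_at(fitted_model, data.times, spec.sim_rtol,
                            spec.sim_atol)
        for j, cb in enumerate(data.columns):
            sim = traj[bindings[cb.column]]
            for i, t in enumerate(data.times):
                residuals.append({
                    "time": float(t), "column": cb.column,
                    "measured": float(data.values[i, j]),
                    "simulated": float(sim[i]),
                    "residual": float(sim[i] - data.values[i, j])})
    except SimulationError:  # pragma: no cover - best point simulated before
        pass

    report = FitReport(
        fitted={fp.locator: float(best_x[i])
                for i, fp in enumerate(spec.parameters)},
        bounds_hit=bounds_hit,
        initial_objective=float(initial_objective),
        final_objective=float(best_f),
        objective_trace=[float(v) for v in state["trace"]],
        residuals=residuals,
        evaluations=int(state["evals"]),
        seed=spec.seed,
        penalised_evaluations=int(state["penalised"]),
    )
    return fitted_model, report
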