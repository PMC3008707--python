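"""ODE derivation and time-course simulation.

A quantitative model induces the coupled system dx/dt = N v(x), with N the
species-by-reactions stoichiometry matrix (reactants negative, products
positive) and v the vector of kinetic-law rates.  Boundary species and
species appearing only as modifiers (enzymes) are held constant.

Integration uses an adaptive stiff-capable solver (LSODA) with tight
default tolerances, since metabolic networks are routinely stiff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .expr import BinOp, MathExpression, Name, Neg, Num
from .model import Model, validate_model

__all__ = ["RateSystem", "TimeCourse", "build_rate_system", "simulate",
           "plot_timecourse", "SimulationError"]


class SimulationError(RuntimeError):
    """Integration failed; the message carries the solver diagnostic."""


class _Diverged(Exception):
    pass


def _compile(expr: MathExpression, species_index: dict[str, int],
             constants: dict[str, float]) -> Callable[[np.ndarray], float]:
    """Compile an expression tree to a closure over the state vector."""
    if isinstance(expr, Num):
        v = expr.value
        return lambda x: v
    if isinstance(expr, Name):
        if expr.ident in species_index:
            i = species_index[expr.ident]
            return lambda x: x[i]
        c = constants[expr.ident]
        return lambda x: c
    if isinstance(expr, Neg):
        f = _compile(expr.operand, species_index, constants)
        return lambda x: -f(x)
    a = _compile(expr.left, species_index, constants)
    b = _compile(expr.right, species_index, constants)
    op = expr.op
    if op == "+":
        return lambda x: a(x) + b(x)
    if op == "-":
        return lambda x: a(x) - b(x)
    if op == "*":
        return lambda x: a(x) * b(x)
    if op == "/":
        return lambda x: a(x) / b(x)
    if op == "^":
        return lambda x: a(x) ** b(x)
    raise ValueError(f"unknown operator {op!r}")  # pragma: no cover


@dataclass
class RateSystem:
    species_ids: list[str]
    stoichiometry: np.ndarray  # species x reactions
    rates: list[Callable[[np.ndarray], float]]
    fixed_mask: np.ndarray  # True where the species is clamped
    reaction_ids: list[str]

    def rate_vector(self, x: np.ndarray) -> np.ndarray:
        return np.array([f(x) for f in self.rates])

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        dx = self.stoichiometry @ self.rate_vector(x)
        dx[self.fixed_mask] = 0.0
        return dx


def build_rate_system(model: Model) -> RateSystem:
    """Derive the stoichiometry matrix and compiled rate functions.

    Deterministic: species and reactions keep model order.  Enzymes that
    appear only as modifiers get all-zero stoichiometry rows and therefore
    stay constant; boundary species are explicitly clamped.
    """
    violations = validate_model(model)
    if violations:
        raise ValueError(f"model invalid: {violations[0]}")
    if not model.is_quantitative():
        raise ValueError("model is qualitative: reactions lack kinetic laws")

    species_ids = [s.id for s in model.species]
    index = {sid: i for i, sid in enumerate(species_ids)}
    n_s, n_r = len(species_ids), len(model.reactions)
    N = np.zeros((n_s, n_r))
    rates: list[Callable[[np.ndarray], float]] = []
    global_consts = {p.id: p.value for p in model.global_parameters}

    for j, rxn in enumerate(model.reactions):
        for sid, stoich in rxn.reactants:
            N[index[sid], j] -= float(stoich)
        for sid, stoich in rxn.products:
            N[index[sid], j] += float(stoich)
        constants = dict(global_consts)
        constants.update({p.id: p.value
                          for p in rxn.kinetic_law.local_parameters})
        rates.append(_compile(rxn.kinetic_law.expression, index, constants))

    fixed = np.array([s.boundary for s in model.species], dtype=bool)
    return RateSystem(species_ids, N, rates, fixed,
                      [r.id for r in model.reactions])


def integrate_grid(system: RateSystem, x0: np.ndarray, t_eval: np.ndarray,
                   rtol: float, atol: float, method: str = "LSODA"):
    """solve_ivp wrapper with a divergence guard.

    Aborts with :class:`SimulationError` on finite-time blow-up instead of
    letting the step-size control grind to a halt.
    """

    if float(t_eval[-1]) <= 0.0:
        # degenerate grid at the origin: the state is the initial condition
        from types import SimpleNamespace
        return SimpleNamespace(y=np.repeat(np.asarray(x0, float)[:, None],
                                           len(t_eval), axis=1),
                               success=True, message="degenerate grid")

    def guarded_rhs(t, x):
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e12:
            raise _Diverged(t)
        return system.rhs(t, x)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            # initial state applies at t=0 even when sampling starts later
            sol = solve_ivp(guarded_rhs,
                            (min(0.0, float(t_eval[0])), float(t_eval[-1])),
                            x0, method=method, t_eval=t_eval,
                            rtol=rtol, atol=atol)
    except _Diverged as e:
        raise SimulationError(
            f"integration failed: state diverged near t={e.args[0]:.3g}s"
        ) from None
    if not sol.success or sol.y.shape[1] != len(t_eval):
        raise SimulationError(f"integration failed: {sol.message}")
    return sol


@dataclass
class TimeCourse:
    times: np.ndarray  # seconds, strictly increasing
    species_ids: list[str]
    values: np.ndarray  # len(times) x len(species_ids)
    provenance: dict = field(default_factory=dict)

    def series(self, sid: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(sid)]


def simulate(
    model: Model,
    t_end: float,
    n_points: int = 101,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TimeCourse:
    """Integrate the model from its initial concentrations.

    Trajectories dipping below -atol trigger a warning and outputs are
    floored at zero, never silently.
    """
    unset = [s.id for s in model.species if s.initial_concentration is None]
    if unset:
        raise ValueError(f"species without initial concentration: {unset}")
    system = build_rate_system(model)
    x0 = np.array([s.initial_concentration for s in model.species], dtype=float)
    t_eval = np.linspace(0.0, float(t_end), int(n_points))

    sol = integrate_grid(system, x0, t_eval, rtol=rtol, atol=atol,
                         method=method)
    values = sol.y.T.copy()
    if values.min() < -atol:
        warnings.warn(
            f"trajectory dipped to {values.min():.3e}; flooring at zero")
    np.clip(values, 0.0, None, out=values)
    # clamped species are emitted bit-identical to their initial value
    values[:, system.fixed_mask] = x0[system.fixed_mask]
    return TimeCourse(
        times=t_eval, species_ids=system.species_ids, values=values,
        provenance={"model_id": model.id, "method": method,
                    "rtol": rtol, "atol": atol})


def plot_timecourse(tc: TimeCourse, path: str,
                    species: Optional[Sequence[str]] = None) -> str:
    """Plot one labelled line per species; time on the abscissa."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = list(species) if species is not None else list(tc.species_ids)
    if not ids:
        raise ValueError("no species selected for plotting")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid in ids:
        ax.plot(tc.times, tc.series(sid), label=sid)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("concentration (mM)")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
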