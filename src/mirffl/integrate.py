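"""Deterministic trajectory simulation over the cell cycle.

The default protocol integrates from half the mechanism-specific steady
state over 5000 s — one cell cycle — with output every second.  The
system is non-stiff at the default rates (time constants of a few hundred
seconds), so an adaptive Runge-Kutta method with tight tolerances is used;
a fixed-step RK4 mode on the output grid exists so that the TF-noise
experiment can compare perturbed and unperturbed runs step for step.

Nonnegativity of molecule counts is a monitored property of the solution,
not enforced by projection, so that model errors are not masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    ConfigurationError,
    Mechanism,
    ParameterSet,
    SPECIES,
    State,
    Topology,
    rhs,
)
from .steady import steady_state

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "initial_state",
    "initial_condition_grid",
    "simulate",
    "IntegrationError",
    "rk4_fixed_step",
]

DEFAULT_MULTIPLIERS = (0.0, 0.25, 0.5, 2.0, 4.0)


class IntegrationError(RuntimeError):
    """The ODE solver failed to advance the solution."""


@dataclass(frozen=True)
class SimulationSettings:
    """Solver configuration.

    ``t_end`` is the simulated horizon in seconds (default one 5000 s cell
    cycle), ``dt_out`` the output spacing.  ``solver`` is "adaptive"
    (RK45 with dense output) or "rk4" (fixed step of ``dt_out``).
    """

    t_end: float = 5000.0
    dt_out: float = 1.0
    solver: str = "adaptive"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ConfigurationError(f"t_end must be > 0, got {self.t_end}")
        if self.dt_out <= 0:
            raise ConfigurationError(f"dt_out must be > 0, got {self.dt_out}")
        n = self.t_end / self.dt_out
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"dt_out={self.dt_out} must divide t_end={self.t_end} evenly"
            )
        if self.solver not in ("adaptive", "rk4"):
            raise ConfigurationError(f"solver must be 'adaptive' or 'rk4', got {self.solver!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt_out))

    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_steps + 1)


@dataclass
class Trajectory:
    """Solution sampled on a regular time grid.

    ``states`` has one row per grid point, columns ordered (w, q, s, r, p).
    ``meta`` records mechanism, topology, parameters, initial condition and
    solver settings, sufficient to regenerate the run.
    """

    times: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"({self.times.size}, {len(SPECIES)})"
            )

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{n: self.species(n) for n in SPECIES}}
        )


def initial_state(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    fraction: float = 0.5,
    overrides: Mapping[str, float] | None = None,
) -> State:
    """Initial condition as a fraction of the mechanism-specific steady state.

    The default (fraction 0.5) models molecule counts halved at cell
    division.  ``overrides`` maps species names to multipliers applied to
    the *steady-state* value (not the half-steady default), for the
    initial-value variation studies.
    """
    if fraction < 0:
        raise ConfigurationError("fraction must be >= 0")
    star = steady_state(mechanism, topology, params).state.as_array()
    init = fraction * star
    if overrides:
        for name, mult in overrides.items():
            if name not in SPECIES:
                raise ConfigurationError(f"unknown species {name!r} in overrides")
            if mult < 0:
                raise ConfigurationError(f"override multiplier for {name} must be >= 0")
            init[SPECIES.index(name)] = mult * star[SPECIES.index(name)]
    return State.from_array(init)


def initial_condition_grid(
    base: State,
    species: str,
    steady: State,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
) -> list[State]:
    """One initial state per multiplier, varying a single species.

    The varied species is set to ``multiplier * steady-state value`` (the
    grid spans 0 to four times the steady level); all other components are
    taken from ``base`` unchanged.
    """
    if species not in SPECIES:
        raise ConfigurationError(f"unknown species {species!r}")
    idx = SPECIES.index(species)
    out = []
    for m in multipliers:
        arr = base.as_array().copy()
        arr[idx] = m * steady.as_array()[idx]
        out.append(State.from_array(arr))
    return out


def rk4_fixed_step(f, y0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Classical RK4 on a fixed grid; ``f(t, y) -> dy``.  Returns (n, dim)."""
    y = np.asarray(y0, dtype=float)
    out = np.empty((times.size, y.size))
    out[0] = y
    for i in range(times.size - 1):
        t, h = times[i], times[i + 1] - times[i]
        k1 = f(t, y)
        k2 = f(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = f(t + 0.5 * h, y + 0.5 * h * k2)
        k4 = f(t + h, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = y
    return out


def simulate(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    settings: SimulationSettings | None = None,
    init: State | None = None,
) -> Trajectory:
    """Integrate one FFL variant and sample it on the output grid.

    ``init`` defaults to half the steady state.  The adaptive solver (RK45,
    rel_tol 1e-8 / abs_tol 1e-10 by default) is recommended for all
    deterministic studies; "rk4" runs a fixed step of ``dt_out``.
    """
    settings = settings or SimulationSettings()
    if init is None:
        init = initial_state(mechanism, topology, params)
    if any(v < 0 for v in init):
        raise ConfigurationError("initial state components must be >= 0")
    times = settings.time_grid()
    y0 = init.as_array()

    def f(t: float, y: np.ndarray) -> np.ndarray:
        w, q, s, r, p = y
        # molecule counts can transiently dip below 0 by solver error;
        # clip only inside Hill terms via max with 0 to stay in-domain
        st = State(max(w, 0.0), max(q, 0.0), max(s, 0.0), max(r, 0.0), max(p, 0.0))
        return rhs(mechanism, topology, params, st).as_array()

    if settings.solver == "rk4":
        states = rk4_fixed_step(f, y0, times)
    else:
        sol = solve_ivp(
            f,
            (0.0, settings.t_end),
            y0,
            method="RK45",
            t_eval=times,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed at t={sol.t[-1] if sol.t.size else 0.0}: {sol.message}"
            )
        states = sol.y.T
    meta = {
        "mechanism": mechanism.name,
        "topology": topology.label,
        "params": params.as_dict(),
        "init": list(init),
        "settings": {
            "t_end": settings.t_end,
            "dt_out": settings.dt_out,
            "solver": settings.solver,
            "rel_tol": settings.rel_tol,
            "abs_tol": settings.abs_tol,
        },
    }
    return Trajectory(times=times, states=states, meta=meta)
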