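"""Algebraic steady states of the FFL models.

The TF subsystem (w, q) is linear and decouples from the rest, so its fixed
point and full time course are available in closed form; the downstream
fixed points follow by substitution.  Only the dual-degradation mechanism
needs real algebra: eliminating the miRNA count from the two coupled
balance equations leaves a quadratic in the target-mRNA count with exactly
one nonnegative root.

Steady states are computed algebraically rather than by long integration so
that "half of steady state" initial conditions are exact and
mechanism-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import (
    ConfigurationError,
    DomainError,
    Mechanism,
    ParameterSet,
    State,
    Topology,
    effective_mrna_degradation,
    hill,
    production_rates,
    rhs,
)

__all__ = [
    "SteadyStateResult",
    "tf_steady",
    "linear_subsystem_solution",
    "steady_state",
    "calibrate_parameter_for_protein_ss",
    "CalibrationError",
]

#: parameters eligible for protein-level calibration, and the sign of dp*/dparam
_CALIBRATABLE = {"gr": -1, "gp": -1, "kp": +1, "krs": -1, "gmax": -1}

# relative difference below which gw and gq are treated as confluent
_CONFLUENT_RTOL = 1e-12


class CalibrationError(ValueError):
    """The requested steady-state protein level is not reachable."""


@dataclass(frozen=True)
class SteadyStateResult:
    """A fixed point together with its certificate.

    ``residual`` is the largest absolute derivative of the five equations
    evaluated at the returned state; ``branch`` records which algebraic
    root was taken (only the dual-degradation quadratic has two).
    """

    state: State
    residual: float
    branch: str = "unique"


def tf_steady(params: ParameterSet) -> tuple[float, float]:
    """Fixed point (w*, q*) of the linear TF subsystem.

    w* = kw/gw and q* = kq*w*/gq; requires both degradation rates > 0.
    """
    if params.gw <= 0 or params.gq <= 0:
        raise DomainError("gw and gq must be > 0 for a finite TF steady state")
    w_star = params.kw / params.gw
    q_star = params.kq * w_star / params.gq
    return w_star, q_star


def linear_subsystem_solution(params: ParameterSet, w0: float, q0: float, t):
    """Closed-form solution (w(t), q(t)) of the TF subsystem from (w0, q0).

    For distinct degradation rates,

        w(t) = w* + (w0 - w*) e^{-gw t}
        q(t) = q* + (q0 - q*) e^{-gq t}
               + kq (w0 - w*) (e^{-gw t} - e^{-gq t}) / (gq - gw)

    with the confluent ``t e^{-g t}`` form when gw == gq.  Vectorized in t.
    """
    w_star, q_star = tf_steady(params)
    t = np.asarray(t, dtype=float)
    dw0 = w0 - w_star
    dq0 = q0 - q_star
    w_t = w_star + dw0 * np.exp(-params.gw * t)
    denom = params.gq - params.gw
    scale = max(abs(params.gq), abs(params.gw), 1e-300)
    if abs(denom) < _CONFLUENT_RTOL * scale:
        cross = params.kq * dw0 * t * np.exp(-params.gq * t)
    else:
        cross = params.kq * dw0 * (np.exp(-params.gw * t) - np.exp(-params.gq * t)) / denom
    q_t = q_star + dq0 * np.exp(-params.gq * t) + cross
    if np.ndim(t) == 0:
        return float(w_t), float(q_t)
    return w_t, q_t


def _dual_deg_sr(ks_q: float, kr_q: float, params: ParameterSet) -> tuple[float, float, str]:
    """Nonnegative root of the dual-degradation (s*, r*) balance.

    Eliminating s = ks(q*)/(gs + krs*r) from the mRNA balance gives

        gr*krs * r^2 + (gr*gs + krs*(ks(q*) - kr(q*))) * r - kr(q*)*gs = 0,

    whose constant term is <= 0: there is exactly one nonnegative root.
    """
    if params.krs == 0.0:
        return ks_q / params.gs, kr_q / params.gr, "linear(krs=0)"
    a = params.gr * params.krs
    b = params.gr * params.gs + params.krs * (ks_q - kr_q)
    c0 = -kr_q * params.gs
    disc = b * b - 4.0 * a * c0
    assert disc >= 0.0, "dual-degradation quadratic must have real roots for nonnegative rates"
    sqrt_disc = math.sqrt(disc)
    # numerically stable positive root: c0 <= 0 guarantees exactly one sign change
    if b >= 0:
        r = 2.0 * (-c0) / (b + sqrt_disc) if (b + sqrt_disc) > 0 else 0.0
    else:
        r = (-b + sqrt_disc) / (2.0 * a)
    s = ks_q / (params.gs + params.krs * r)
    return s, r, "positive-root"


def steady_state(
    mechanism: Mechanism, topology: Topology, params: ParameterSet
) -> SteadyStateResult:
    """Algebraic fixed point of the chosen mechanism x topology.

    All five derivatives vanish at the returned state; the residual of the
    full right-hand side is evaluated as a certificate.
    """
    for name in ("gw", "gq", "gs", "gr", "gp"):
        if getattr(params, name) <= 0:
            raise DomainError(f"degradation rate {name} must be > 0 for a steady state")
    w_star, q_star = tf_steady(params)
    ks_q, kr_q = production_rates(topology, params, q_star)
    branch = "unique"
    if mechanism is Mechanism.STOP:
        s_star = ks_q / params.gs
        r_star = kr_q / params.gr
        p_star = hill(s_star, params.kp, params.hp, -1, params.c) * r_star / params.gp
    elif mechanism is Mechanism.TARGET_DEG:
        s_star = ks_q / params.gs
        r_star = kr_q / effective_mrna_degradation(s_star, params)
        p_star = params.kp * r_star / params.gp
    elif mechanism is Mechanism.DUAL_DEG:
        s_star, r_star, branch = _dual_deg_sr(ks_q, kr_q, params)
        p_star = params.kp * r_star / params.gp
    else:
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    state = State(w_star, q_star, s_star, r_star, p_star)
    residual = float(np.max(np.abs(rhs(mechanism, topology, params, state).as_array())))
    return SteadyStateResult(state=state, residual=residual, branch=branch)


def calibrate_parameter_for_protein_ss(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    free_param: str,
    target_p: float,
    rtol: float = 1e-8,
) -> float:
    """Value of one coefficient that places the steady-state protein at ``target_p``.

    The steady-state protein count is monotone in each eligible coefficient
    (kp raises it; gr, gp, krs and gmax lower it), so a bracketed 1-D root
    find suffices.  Used to match steady-state levels across mechanisms
    with different degradation coefficients.
    """
    if free_param not in _CALIBRATABLE:
        raise ConfigurationError(
            f"free_param must be one of {sorted(_CALIBRATABLE)}, got {free_param!r}"
        )
    if target_p <= 0:
        raise CalibrationError("target_p must be > 0")

    def p_at(value: float) -> float:
        return steady_state(mechanism, topology, params.replace(**{free_param: value})).state.p

    default = getattr(params, free_param)
    lo_seed = default if default > 0 else 1e-8
    # geometric bracket expansion around the current value
    lo, hi = lo_seed, lo_seed
    for _ in range(80):
        lo /= 4.0
        hi *= 4.0
        f_lo = p_at(lo) - target_p
        f_hi = p_at(hi) - target_p
        if f_lo == 0.0:
            return lo
        if f_hi == 0.0:
            return hi
        if f_lo * f_hi < 0:
            break
    else:
        p_lo, p_hi = sorted((p_at(lo), p_at(hi)))
        raise CalibrationError(
            f"target_p={target_p} not reachable by varying {free_param}; "
            f"achievable range is about [{p_lo:.6g}, {p_hi:.6g}]"
        )
    root = brentq(lambda v: p_at(v) - target_p, lo, hi, rtol=1e-14, maxiter=200)
    achieved = p_at(root)
    if not math.isclose(achieved, target_p, rel_tol=rtol):
        raise CalibrationError(
            f"calibration of {free_param} converged to p*={achieved}, not {target_p}"
        )
    return float(root)
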