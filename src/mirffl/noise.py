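"""TF-noise injection and the epsilon noise-buffering statistic.

The experiment asks whether an FFL attenuates fluctuations of its upstream
transcription factor.  A stationary Ornstein-Uhlenbeck sequence z (unit
variance, per-step decay e^{-0.1}) is added — scaled to a chosen amplitude
— to the TF count *as seen by the miRNA and target promoters only*: the
TF's own dynamics are never perturbed.  Paired perturbed/unperturbed runs
then yield

    NA = max_t |q(t) - q_n(t)|,   NB = max_t |p(t) - p_n(t)|,
    epsilon = (NB - NA) / NA,

with epsilon < 0 meaning the loop leaves less noise on the target protein
than was present on the TF (buffering) and epsilon > 0 amplification.  By
default each species' deviation is normalized by its steady-state count so
NA and NB are relative noise powers; a raw-counts mode exists for
sensitivity analysis.

Both members of a pair are integrated with the same fixed-step RK4 scheme
on the noise grid (zero-order hold of z within a step) so they are
numerically comparable point by point.  Replicate ensembles are integrated
as a single vectorized batch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .integrate import SimulationSettings, Trajectory, initial_state
from .models import (
    ConfigurationError,
    DomainError,
    Mechanism,
    ParameterSet,
    State,
    Topology,
    effective_mrna_degradation,
    hill,
)
from .steady import steady_state

__all__ = [
    "NoiseSeries",
    "EpsilonResult",
    "EpsilonSummary",
    "WilcoxonReport",
    "ou_series",
    "simulate_with_tf_noise",
    "epsilon",
    "run_noise_experiment",
    "wilcoxon_compare",
    "DEFAULT_DECAY",
]

logger = logging.getLogger(__name__)

#: per-step autoregression coefficient of the discretized OU process
DEFAULT_DECAY = math.exp(-0.1)


@dataclass(frozen=True)
class NoiseSeries:
    """A discretized OU sequence z_0..z_n on a regular grid of step ``dt``.

    ``decay`` is the lag-1 autocorrelation; the sequence is constructed
    stationary (z_0 drawn from the stationary unit-variance law).
    """

    dt: float
    values: np.ndarray
    seed: int | None
    decay: float = DEFAULT_DECAY

    @property
    def n_steps(self) -> int:
        return self.values.size - 1


@dataclass(frozen=True)
class EpsilonResult:
    """NA, NB and epsilon for one perturbed/unperturbed pair."""

    NA: float
    NB: float
    epsilon: float


@dataclass
class EpsilonSummary:
    """Replicate ensemble of epsilon values with its summary columns.

    ``mean`` and ``n_positive`` are the two cell entries of the
    noise-buffering tables: the average epsilon and the number of
    replicates in which the loop failed to buffer (epsilon > 0).
    """

    epsilons: np.ndarray
    mean: float
    n_positive: int
    config: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WilcoxonReport:
    """Two-sided rank-based comparison of two epsilon ensembles."""

    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    method: str
    degenerate: bool = False


def ou_series(
    n_steps: int,
    dt: float = 1.0,
    seed: int | None = None,
    decay: float = DEFAULT_DECAY,
    innovation: str = "sqrt",
) -> NoiseSeries:
    """Stationary Gaussian AR(1) sequence of ``n_steps + 1`` values.

    z_i = a z_{i-1} + sqrt(1 - a^2) xi_i with a = ``decay`` and xi standard
    normal; z_0 is drawn from the stationary law, so the sequence has mean
    0, variance 1 and lag-1 autocorrelation a throughout.

    ``innovation="linear"`` instead scales xi by (1 - a^2) — an alternative
    reading of the recursion whose stationary variance is below 1; it is
    provided for sensitivity analysis only.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    if not (0.0 <= decay < 1.0):
        raise ConfigurationError("decay must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal()
    xi = rng.standard_normal(n_steps)
    if innovation == "sqrt":
        b = math.sqrt(1.0 - decay * decay)
    elif innovation == "linear":
        b = 1.0 - decay * decay
    else:
        raise ConfigurationError("innovation must be 'sqrt' or 'linear'")
    # z = lfilter of the driven recursion with exact initial condition
    drive = np.concatenate(([z0], b * xi))
    z = _signal.lfilter([1.0], [1.0, -decay], drive)
    return NoiseSeries(dt=dt, values=z, seed=seed, decay=decay)


def _batch_derivative(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    Y: np.ndarray,
    pert: np.ndarray,
) -> np.ndarray:
    """RHS over a replicate batch; ``Y`` is (m, 5), ``pert`` is (m,).

    The perturbation enters only the TF count used by the miRNA/target
    promoters, clamped at zero (counts cannot be negative).
    """
    w, q, s, r, p = (Y[:, j] for j in range(5))
    s_pos = np.maximum(s, 0.0)
    q_reg = np.maximum(q + pert, 0.0)
    ks_q = hill(q_reg, params.ks, params.hs, topology.sign_mirna, params.c)
    kr_q = hill(q_reg, params.kr, params.hr, topology.sign_target, params.c)
    out = np.empty_like(Y)
    out[:, 0] = params.kw - params.gw * w
    out[:, 1] = params.kq * w - params.gq * q
    if mechanism is Mechanism.STOP:
        out[:, 2] = ks_q - params.gs * s
        out[:, 3] = kr_q - params.gr * r
        out[:, 4] = hill(s_pos, params.kp, params.hp, -1, params.c) * r - params.gp * p
    elif mechanism is Mechanism.TARGET_DEG:
        out[:, 2] = ks_q - params.gs * s
        out[:, 3] = kr_q - effective_mrna_degradation(s_pos, params) * r
        out[:, 4] = params.kp * r - params.gp * p
    else:
        out[:, 2] = ks_q - params.gs * s - params.krs * r * s
        out[:, 3] = kr_q - params.gr * r - params.krs * r * s
        out[:, 4] = params.kp * r - params.gp * p
    return out


def _integrate_tf_noise_batch(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    init: State,
    times: np.ndarray,
    z: np.ndarray,
    amplitude: float,
) -> tuple[np.ndarray, int]:
    """Fixed-step RK4 over a batch of noise realizations.

    ``z`` has shape (m, len(times)); the perturbation amplitude*z_i is held
    constant over step i.  Returns (states of shape (m, n, 5), number of
    grid points at which the perturbed TF was clamped at zero).
    """
    m, n = z.shape
    if n != times.size:
        raise ConfigurationError(
            f"noise length {n} does not match time grid length {times.size}"
        )
    Y = np.tile(init.as_array()[None, :], (m, 1))
    out = np.empty((m, n, 5))
    out[:, 0] = Y
    n_clamped = 0
    for i in range(n - 1):
        h = times[i + 1] - times[i]
        pert = amplitude * z[:, i]
        n_clamped += int(np.count_nonzero(Y[:, 1] + pert < 0.0))
        k1 = _batch_derivative(mechanism, topology, params, Y, pert)
        k2 = _batch_derivative(mechanism, topology, params, Y + 0.5 * h * k1, pert)
        k3 = _batch_derivative(mechanism, topology, params, Y + 0.5 * h * k2, pert)
        k4 = _batch_derivative(mechanism, topology, params, Y + h * k3, pert)
        Y = Y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[:, i + 1] = Y
    return out, n_clamped


def simulate_with_tf_noise(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    settings: SimulationSettings | None = None,
    noise: NoiseSeries | None = None,
    amplitude: float = 0.0,
    init: State | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Paired unperturbed ("clean") and TF-perturbed ("noisy") runs.

    Both runs share the initial state (half steady state by default) and
    the fixed-step RK4 grid; the noisy run sees q + amplitude*z (clamped at
    0) inside the miRNA/target production terms only, so its w and q
    components are identical to the clean run's.
    """
    settings = settings or SimulationSettings(solver="rk4")
    if noise is None:
        raise ConfigurationError("a NoiseSeries is required")
    if amplitude < 0:
        raise ConfigurationError("amplitude must be >= 0")
    times = settings.time_grid()
    if noise.values.size != times.size or not math.isclose(noise.dt, settings.dt_out):
        raise ConfigurationError(
            f"noise grid (dt={noise.dt}, n={noise.values.size}) does not match "
            f"integration grid (dt={settings.dt_out}, n={times.size})"
        )
    if init is None:
        init = initial_state(mechanism, topology, params)
    star = steady_state(mechanism, topology, params).state
    z = noise.values[None, :]
    zero = np.zeros_like(z)
    clean_states, _ = _integrate_tf_noise_batch(
        mechanism, topology, params, init, times, zero, 0.0
    )
    noisy_states, n_clamped = _integrate_tf_noise_batch(
        mechanism, topology, params, init, times, z, amplitude
    )
    if n_clamped:
        logger.info("perturbed TF clamped at zero on %d grid points", n_clamped)
    meta = {
        "mechanism": mechanism.name,
        "topology": topology.label,
        "params": params.as_dict(),
        "init": list(init),
        "steady_state": list(star),
        "amplitude": amplitude,
        "noise_seed": noise.seed,
        "noise_decay": noise.decay,
        "n_clamped": n_clamped,
        "settings": {"t_end": settings.t_end, "dt_out": settings.dt_out, "solver": "rk4"},
    }
    clean = Trajectory(times=times, states=clean_states[0], meta=dict(meta, amplitude=0.0))
    noisy = Trajectory(times=times, states=noisy_states[0], meta=meta)
    return clean, noisy


def epsilon(
    clean: Trajectory,
    noisy: Trajectory,
    noise: NoiseSeries,
    amplitude: float,
    normalization: str = "steady_state",
    steady: State | None = None,
) -> EpsilonResult:
    """The buffering statistic for one perturbed/unperturbed pair.

    NA is the largest TF deviation (q_n = q + amplitude*z by definition),
    NB the largest target-protein deviation.  With
    ``normalization="steady_state"`` each deviation is divided by that
    species' steady-state count, making NA and NB relative noise powers;
    ``"raw"`` compares absolute molecule counts.
    """
    if clean.times.size != noisy.times.size or not np.array_equal(clean.times, noisy.times):
        raise ConfigurationError("clean and noisy trajectories must share a time grid")
    if normalization not in ("steady_state", "raw"):
        raise ConfigurationError("normalization must be 'steady_state' or 'raw'")
    dq = amplitude * np.abs(noise.values)
    dp = np.abs(clean.species("p") - noisy.species("p"))
    if normalization == "steady_state":
        if steady is None:
            meta = clean.meta
            if "steady_state" in meta:
                steady = State.from_array(meta["steady_state"])
            else:
                steady = steady_state(
                    Mechanism[meta["mechanism"]],
                    Topology.from_name(meta["topology"]),
                    ParameterSet(**meta["params"]),
                ).state
        na = float(dq.max() / steady.q)
        nb = float(dp.max() / steady.p)
    else:
        na = float(dq.max())
        nb = float(dp.max())
    if na == 0.0:
        raise DomainError("epsilon is undefined when the TF deviation NA is zero")
    return EpsilonResult(NA=na, NB=nb, epsilon=(nb - na) / na)


def replicate_seeds(master_seed: int, n_rep: int) -> list[int]:
    """Deterministic per-replicate RNG seeds derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n_rep)]


def run_noise_experiment(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    n_rep: int = 100,
    amplitude: float = 0.10,
    amplitude_mode: str = "relative",
    master_seed: int = 0,
    settings: SimulationSettings | None = None,
    normalization: str = "steady_state",
    decay: float = DEFAULT_DECAY,
    innovation: str = "sqrt",
) -> EpsilonSummary:
    """Replicate ensemble of the noise-buffering experiment.

    ``amplitude_mode="relative"`` scales the unit-variance noise by
    ``amplitude * q*`` (default 10% of the steady-state TF count — a small
    perturbation that does not overwhelm the signal); ``"absolute"`` uses
    ``amplitude`` molecules directly.  Replicate seeds derive
    deterministically from ``master_seed``, so a fixed master seed gives a
    bitwise-identical summary.  All replicates are integrated as one
    vectorized RK4 batch against a single shared clean run.
    """
    if n_rep < 1:
        raise ConfigurationError("n_rep must be >= 1")
    if amplitude_mode not in ("relative", "absolute"):
        raise ConfigurationError("amplitude_mode must be 'relative' or 'absolute'")
    settings = settings or SimulationSettings(solver="rk4")
    star = steady_state(mechanism, topology, params).state
    amp = amplitude * star.q if amplitude_mode == "relative" else amplitude
    if amp <= 0:
        raise DomainError("noise amplitude must be > 0 for the epsilon statistic")
    times = settings.time_grid()
    seeds = replicate_seeds(master_seed, n_rep)
    z = np.empty((n_rep, times.size))
    for j, seed in enumerate(seeds):
        z[j] = ou_series(
            settings.n_steps, settings.dt_out, seed, decay=decay, innovation=innovation
        ).values
    init = initial_state(mechanism, topology, params)
    clean_states, _ = _integrate_tf_noise_batch(
        mechanism, topology, params, init, times, np.zeros((1, times.size)), 0.0
    )
    noisy_states, n_clamped = _integrate_tf_noise_batch(
        mechanism, topology, params, init, times, z, amp
    )
    if n_clamped:
        logger.info("perturbed TF clamped at zero on %d grid points", n_clamped)
    dq = amp * np.abs(z).max(axis=1)
    dp = np.abs(noisy_states[:, :, 4] - clean_states[0, :, 4]).max(axis=1)
    if normalization == "steady_state":
        na = dq / star.q
        nb = dp / star.p
    elif normalization == "raw":
        na, nb = dq, dp
    else:
        raise ConfigurationError("normalization must be 'steady_state' or 'raw'")
    eps = (nb - na) / na
    config = {
        "mechanism": mechanism.name,
        "topology": topology.label,
        "params": params.as_dict(),
        "n_rep": n_rep,
        "amplitude": amp,
        "amplitude_mode": amplitude_mode,
        "amplitude_spec": amplitude,
        "master_seed": master_seed,
        "seeds": seeds,
        "dt": settings.dt_out,
        "t_end": settings.t_end,
        "normalization": normalization,
        "decay": decay,
        "innovation": innovation,
        "n_clamped": n_clamped,
        "steady_state": list(star),
    }
    return EpsilonSummary(
        epsilons=eps,
        mean=float(eps.mean()),
        n_positive=int(np.count_nonzero(eps > 0)),
        config=config,
    )


def wilcoxon_compare(a: EpsilonSummary, b: EpsilonSummary) -> WilcoxonReport:
    """Two-sided rank comparison of two epsilon ensembles.

    Uses the paired signed-rank test when the two summaries share the same
    replicate seed list (paired noise realizations), the rank-sum test
    otherwise.  Degenerate inputs (identical paired samples, or zero
    variance) are reported as such rather than raising.
    """
    x = np.asarray(a.epsilons, dtype=float)
    y = np.asarray(b.epsilons, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both summaries must be nonempty")
    paired = x.size == y.size and a.config.get("seeds") == b.config.get("seeds") \
        and a.config.get("seeds") is not None
    if paired:
        diffs = x - y
        if np.all(diffs == 0.0):
            return WilcoxonReport(
                n_a=x.size, n_b=y.size, statistic=0.0, pvalue=1.0,
                method="wilcoxon-signed-rank", degenerate=True,
            )
        res = _stats.wilcoxon(x, y, zero_method="zsplit")
        return WilcoxonReport(
            n_a=x.size, n_b=y.size, statistic=float(res.statistic),
            pvalue=float(res.pvalue), method="wilcoxon-signed-rank",
        )
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0 and x[0] == y[0]:
        return WilcoxonReport(
            n_a=x.size, n_b=y.size, statistic=0.0, pvalue=1.0,
            method="wilcoxon-rank-sum", degenerate=True,
        )
    res = _stats.ranksums(x, y)
    return WilcoxonReport(
        n_a=x.size, n_b=y.size, statistic=float(res.statistic),
        pvalue=float(res.pvalue), method="wilcoxon-rank-sum",
    )
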