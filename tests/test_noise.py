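"""The OU noise generator, paired noisy/clean runs, and the epsilon statistic."""

import math

import numpy as np
import pytest

from mirffl import (
    ConfigurationError,
    DomainError,
    Mechanism,
    NoiseSeries,
    SimulationSettings,
    State,
    Topology,
    Trajectory,
    epsilon,
    ou_series,
    run_noise_experiment,
    simulate_with_tf_noise,
    wilcoxon_compare,
)
from mirffl.noise import DEFAULT_DECAY, replicate_seeds

A = math.exp(-0.1)


class TestOuSeries:
    def test_recursion_identity(self):
        """z exactly satisfies z_i = a z_{i-1} + sqrt(1-a^2) xi_i with white xi."""
        z = ou_series(50_000, seed=7).values
        resid = z[1:] - A * z[:-1]
        b = math.sqrt(1 - A * A)
        assert np.std(resid) == pytest.approx(b, rel=0.02)
        lag1 = np.corrcoef(resid[1:], resid[:-1])[0, 1]
        assert abs(lag1) < 0.02

    def test_stationary_statistics(self):
        z = ou_series(200_000, seed=11).values
        assert z.var() == pytest.approx(1.0, abs=0.02)
        assert z.mean() == pytest.approx(0.0, abs=0.02)
        lag1 = np.corrcoef(z[1:], z[:-1])[0, 1]
        assert lag1 == pytest.approx(A, abs=0.005)

    def test_determinism_and_length(self):
        z1 = ou_series(100, seed=3)
        z2 = ou_series(100, seed=3)
        assert np.array_equal(z1.values, z2.values)
        assert z1.values.size == 101
        assert z1.n_steps == 100

    def test_linear_innovation_understates_variance(self):
        z = ou_series(200_000, seed=11, innovation="linear").values
        assert z.var() < 0.5  # (1-a^2) scaling cannot sustain unit variance

    def test_invalid_arguments(self):
        with pytest.raises(ConfigurationError):
            ou_series(0)
        with pytest.raises(ConfigurationError):
            ou_series(10, dt=0.0)
        with pytest.raises(ConfigurationError):
            ou_series(10, innovation="quadratic")


@pytest.fixture(scope="module")
def short_settings():
    return SimulationSettings(t_end=500.0, dt_out=1.0, solver="rk4")


class TestSimulateWithNoise:
    def test_zero_amplitude_is_bitwise_clean(self, params, short_settings):
        noise = ou_series(500, seed=5)
        clean, noisy = simulate_with_tf_noise(
            Mechanism.STOP, Topology.IN1, params, short_settings, noise, amplitude=0.0
        )
        assert np.array_equal(clean.states, noisy.states)

    def test_zero_noise_vector_is_bitwise_clean(self, params, short_settings):
        noise = NoiseSeries(dt=1.0, values=np.zeros(501), seed=None)
        clean, noisy = simulate_with_tf_noise(
            Mechanism.STOP, Topology.IN1, params, short_settings, noise, amplitude=30.0
        )
        assert np.array_equal(clean.states, noisy.states)

    def test_tf_equations_unperturbed(self, params, short_settings):
        noise = ou_series(500, seed=5)
        clean, noisy = simulate_with_tf_noise(
            Mechanism.STOP, Topology.IN1, params, short_settings, noise, amplitude=30.0
        )
        assert np.array_equal(clean.species("w"), noisy.species("w"))
        assert np.array_equal(clean.species("q"), noisy.species("q"))
        assert not np.array_equal(clean.species("s"), noisy.species("s"))

    def test_grid_mismatch_rejected(self, params, short_settings):
        with pytest.raises(ConfigurationError):
            simulate_with_tf_noise(
                Mechanism.STOP, Topology.IN1, params, short_settings,
                ou_series(400, seed=5), amplitude=30.0,
            )


def _toy_pair(p_clean, p_noisy, q_star=300.0, p_star=600.0):
    times = np.arange(3, dtype=float)
    mk = lambda p: Trajectory(
        times=times,
        states=np.column_stack(
            [np.full(3, 15.0), np.full(3, q_star), np.zeros(3), np.zeros(3), p]
        ),
    )
    return mk(np.asarray(p_clean, float)), mk(np.asarray(p_noisy, float))


class TestEpsilonStatistic:
    def test_perfect_buffering_gives_minus_one(self):
        clean, noisy = _toy_pair([600, 600, 600], [600, 600, 600])
        noise = NoiseSeries(dt=1.0, values=np.array([0.0, 1.0, -0.5]), seed=None)
        res = epsilon(clean, noisy, noise, amplitude=30.0,
                      steady=State(15, 300, 0, 0, 600))
        assert res.epsilon == -1.0

    def test_pass_through_and_amplification(self):
        # NB set equal to NA, then to twice NA (in normalized units)
        noise = NoiseSeries(dt=1.0, values=np.array([0.0, 1.0, -0.5]), seed=None)
        na_norm = 30.0 / 300.0
        clean, noisy = _toy_pair([600, 600, 600], [600, 600 + 600 * na_norm, 600])
        res = epsilon(clean, noisy, noise, 30.0, steady=State(15, 300, 0, 0, 600))
        assert res.epsilon == pytest.approx(0.0, abs=1e-12)
        clean, noisy = _toy_pair([600, 600, 600], [600, 600 + 2 * 600 * na_norm, 600])
        res = epsilon(clean, noisy, noise, 30.0, steady=State(15, 300, 0, 0, 600))
        assert res.epsilon == pytest.approx(1.0, abs=1e-12)

    def test_zero_amplitude_undefined(self):
        clean, noisy = _toy_pair([600, 600, 600], [600, 600, 600])
        noise = NoiseSeries(dt=1.0, values=np.array([0.0, 1.0, -0.5]), seed=None)
        with pytest.raises(DomainError):
            epsilon(clean, noisy, noise, 0.0, steady=State(15, 300, 0, 0, 600))


class TestRunNoiseExperiment:
    def test_determinism(self, params, short_settings):
        kw = dict(n_rep=4, master_seed=42, settings=short_settings)
        a = run_noise_experiment(Mechanism.STOP, Topology.IN1, params, **kw)
        b = run_noise_experiment(Mechanism.STOP, Topology.IN1, params, **kw)
        assert np.array_equal(a.epsilons, b.epsilons)
        assert a.mean == b.mean and a.n_positive == b.n_positive

    def test_summary_consistency_and_bounds(self, params, short_settings):
        s = run_noise_experiment(
            Mechanism.TARGET_DEG, Topology.C2, params, n_rep=6,
            master_seed=1, settings=short_settings,
        )
        assert s.epsilons.size == 6
        assert s.mean == pytest.approx(s.epsilons.mean())
        assert s.n_positive == int((s.epsilons > 0).sum())
        assert np.all(s.epsilons >= -1.0)
        assert s.epsilons.min() <= s.mean <= s.epsilons.max()

    def test_batch_matches_single_replicate_path(self, params, short_settings):
        """The vectorized ensemble and the paired-run API agree replicate by
        replicate."""
        summary = run_noise_experiment(
            Mechanism.STOP, Topology.IN1, params, n_rep=2,
            master_seed=9, settings=short_settings,
        )
        seeds = replicate_seeds(9, 2)
        amp = summary.config["amplitude"]
        for j, seed in enumerate(seeds):
            noise = ou_series(short_settings.n_steps, 1.0, seed)
            clean, noisy = simulate_with_tf_noise(
                Mechanism.STOP, Topology.IN1, params, short_settings, noise, amp
            )
            res = epsilon(clean, noisy, noise, amp)
            assert res.epsilon == pytest.approx(summary.epsilons[j], rel=1e-12)

    def test_amplitude_near_linearity(self, params, short_settings):
        full = run_noise_experiment(
            Mechanism.STOP, Topology.IN1, params, n_rep=4, amplitude=0.10,
            master_seed=3, settings=short_settings,
        )
        half = run_noise_experiment(
            Mechanism.STOP, Topology.IN1, params, n_rep=4, amplitude=0.05,
            master_seed=3, settings=short_settings,
        )
        assert np.max(np.abs(full.epsilons - half.epsilons)) < 0.05

    def test_zero_amplitude_rejected(self, params, short_settings):
        with pytest.raises(DomainError):
            run_noise_experiment(
                Mechanism.STOP, Topology.IN1, params, n_rep=2, amplitude=0.0,
                master_seed=0, settings=short_settings,
            )


class TestWilcoxon:
    def _summary(self, eps, seeds):
        from mirffl import EpsilonSummary

        eps = np.asarray(eps, float)
        return EpsilonSummary(
            epsilons=eps, mean=float(eps.mean()),
            n_positive=int((eps > 0).sum()), config={"seeds": seeds},
        )

    def test_identical_paired_samples(self):
        eps = [-0.5, -0.6, -0.7, -0.4]
        rep = wilcoxon_compare(self._summary(eps, [1, 2, 3, 4]),
                               self._summary(eps, [1, 2, 3, 4]))
        assert rep.pvalue == 1.0
        assert rep.degenerate
        assert rep.n_a == rep.n_b == 4

    def test_separated_samples(self):
        rng = np.random.default_rng(0)
        x = rng.normal(-0.8, 0.02, 60)
        rep = wilcoxon_compare(self._summary(x, list(range(60))),
                               self._summary(x + 10.0, list(range(100, 160))))
        assert rep.pvalue < 1e-6
        assert rep.method == "wilcoxon-rank-sum"

    def test_paired_shift_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(-0.8, 0.05, 50)
        seeds = list(range(50))
        rep = wilcoxon_compare(self._summary(x, seeds),
                               self._summary(x + 0.5, seeds))
        assert rep.method == "wilcoxon-signed-rank"
        assert rep.pvalue < 1e-6
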