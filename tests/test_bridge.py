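"""Bridge dynamics: drift laws, conditioned moments, endpoint pinning."""

import numpy as np
import pytest

import knotbridge as kb
from knotbridge.bridge import (
    _cyclic_mode_targets,
    _log_weights_raw,
    _normalize_log_weights,
    bridge_gains,
    permutation_log_weights,
    run,
    step_bridge,
    step_bridge_permuted,
    step_free,
)
from knotbridge.modes import ModeState, relaxation_rates, to_modes


def _ou_bridge_moments(x0, xf, omega, c, t, tf):
    """Closed-form conditioned mean/variance of an OU bridge.

    OU process dX = -omega X dt + noise of variance rate c, pinned at x0 and
    xf; omega = 0 reduces to the Brownian bridge.
    """
    if omega == 0:
        mean = x0 + (xf - x0) * t / tf
        var = c * t * (tf - t) / tf
        return mean, var
    mean = (x0 * np.sinh(omega * (tf - t)) + xf * np.sinh(omega * t)) / np.sinh(
        omega * tf
    )
    v = lambda s: c * (1 - np.exp(-2 * omega * s)) / (2 * omega)
    var = v(t) * (1 - np.exp(-2 * omega * (tf - t)) * v(t) / v(tf))
    return mean, var


class TestGains:
    def test_brownian_limit(self):
        g_f, g_c = bridge_gains(np.array([0.0, 1e-8]), 0.5)
        assert g_f[0] == pytest.approx(2.0)
        assert g_c[0] == pytest.approx(2.0)
        assert g_f[1] == pytest.approx(2.0, rel=1e-6)
        assert g_c[1] == pytest.approx(2.0, rel=1e-6)

    def test_stiff_limit_stable(self):
        om = np.array([1e4, 1e8])
        g_f, g_c = bridge_gains(om, 1.0)
        assert np.all(np.isfinite(g_f)) and np.all(np.isfinite(g_c))
        assert g_f[0] == pytest.approx(0.0, abs=1e-300)
        assert g_c[0] == pytest.approx(om[0])

    def test_matches_naive_formula(self):
        om = np.array([0.5, 3.0, 20.0])
        tau = 0.37
        g_f, g_c = bridge_gains(om, tau)
        assert np.allclose(g_f, om / np.sinh(om * tau), rtol=1e-12)
        assert np.allclose(g_c, om / np.tanh(om * tau), rtol=1e-12)

    def test_requires_positive_tau(self):
        with pytest.raises(ValueError):
            bridge_gains(np.array([1.0]), 0.0)


class TestFreeDynamics:
    def test_noise_free_exponential_decay(self, rng):
        # with D -> 0 each step multiplies mode p by (1 - Omega_p dt)
        a8, K8 = kb.solve_chain_parameters(8, 1.0, 1.0)
        pars = kb.ChainParameters(N=8, b=1.0, lP=1.0, a=a8, K=K8, D=1e-30)
        om = relaxation_rates(pars)
        pos = rng.standard_normal((8, 3))
        ms = to_modes(pos)
        out = step_free(ms, pars, 1e-3, rng)
        expect = ms.amplitudes * (1 - om[:, None] * 1e-3)
        assert np.allclose(out.amplitudes, expect, atol=1e-12)

    def test_com_diffusion_variance(self, rng):
        # p = 0 diffuses freely: Var grows as 2 D t / N per component
        pars = kb.ChainParameters.from_targets(8, 1.0, 0.5)
        n_rep, n_steps, dt = 3000, 40, 1e-2
        coms = []
        for k in range(n_rep):
            ms = ModeState(np.zeros((8, 3), dtype=complex))
            for _ in range(n_steps):
                ms = step_free(ms, pars, dt, rng)
            coms.append(ms.amplitudes[0].real)
        var = np.var(np.array(coms), axis=0).mean()
        expect = 2 * pars.D * n_steps * dt / pars.N
        assert abs(var - expect) < 4 * expect * np.sqrt(2 / n_rep)

    def test_ou_stationary_variance(self, rng):
        # long free evolution: Re/Im of mode p each reach (D/N) / (2 Omega_p)
        pars = kb.ChainParameters.from_targets(8, 1.0, 0.5)
        om = relaxation_rates(pars)
        dt = 2e-3
        ms = ModeState(np.zeros((8, 3), dtype=complex))
        samples = []
        for k in range(30000):
            ms = step_free(ms, pars, dt, rng)
            if k > 3000 and k % 10 == 0:
                samples.append(ms.amplitudes.copy())
        arr = np.array(samples)
        p = 2
        got = arr[:, p, :].real.var()
        expect = (pars.D / pars.N) / (2 * om[p])
        assert got == pytest.approx(expect, rel=0.15)


class TestBridgeMoments:
    @pytest.mark.parametrize("omega,c", [(0.0, 0.25), (3.0, 0.125)])
    def test_scalar_bridge_matches_conditioned_law(self, omega, c, rng):
        """Replicated scalar bridges vs closed-form OU/Brownian bridge moments."""
        x0, xf, tf, dt = 0.0, 0.7, 0.5, 2.5e-4
        n_rep = 4000
        n_steps = int(round(tf / dt))
        om = np.array([omega])
        x = np.full(n_rep, x0)
        checkpoints = {int(n_steps * f / 11): [] for f in range(1, 11)}
        snaps = {}
        for k in range(n_steps - 1):
            tau = tf - k * dt
            g_f, g_c = bridge_gains(om, tau)
            x = x + (g_f[0] * xf - g_c[0] * x) * dt + rng.normal(
                0.0, np.sqrt(c * dt), n_rep
            )
            if k + 1 in checkpoints:
                snaps[(k + 1) * dt] = x.copy()
        for t, vals in snaps.items():
            mean, var = _ou_bridge_moments(x0, xf, omega, c, t, tf)
            se_mean = np.sqrt(var / n_rep)
            se_var = var * np.sqrt(2 / (n_rep - 1))
            assert abs(vals.mean() - mean) < 3 * se_mean, f"mean off at t={t}"
            assert abs(vals.var() - var) < 4 * se_var, f"variance off at t={t}"

    def test_deterministic_bridge_follows_conditioned_mean(self, rng):
        pars = _quiet_params(16, 2.0)
        r0 = rng.standard_normal((16, 3))
        rf = rng.standard_normal((16, 3))
        traj = run(
            r0, rf, params=pars, dt=1e-4, tf=1.0, conditioning="bridge", seed=0,
            frame_stride=2000,
        )
        om = relaxation_rates(pars)
        m0 = np.fft.fft(r0, axis=0) / 16
        mf = np.fft.fft(rf, axis=0) / 16
        for idx in (1, 3):
            t = traj.times[idx]
            mean = np.empty_like(m0)
            for p in range(16):
                if om[p] == 0:
                    mean[p] = m0[p] + (mf[p] - m0[p]) * t / 1.0
                else:
                    mean[p] = (
                        m0[p] * np.sinh(om[p] * (1.0 - t)) + mf[p] * np.sinh(om[p] * t)
                    ) / np.sinh(om[p])
            expect = np.fft.ifft(mean * 16, axis=0).real
            assert np.max(np.abs(traj.frames[idx] - expect)) < 5e-4

    def test_dt_convergence_first_order(self, rng):
        pars = _quiet_params(12, 1.5)
        r0 = rng.standard_normal((12, 3))
        rf = rng.standard_normal((12, 3))
        errs = []
        for dt in (2e-3, 1e-3):
            traj = run(
                r0, rf, params=pars, dt=dt, tf=1.0, conditioning="bridge", seed=0,
                frame_stride=int(0.5 / dt),
            )
            om = relaxation_rates(pars)
            m0 = np.fft.fft(r0, axis=0) / 12
            mf = np.fft.fft(rf, axis=0) / 12
            t = 0.5
            mean = np.empty_like(m0)
            for p in range(12):
                if om[p] == 0:
                    mean[p] = m0[p] + (mf[p] - m0[p]) * t
                else:
                    mean[p] = (
                        m0[p] * np.sinh(om[p] * (1 - t)) + mf[p] * np.sinh(om[p] * t)
                    ) / np.sinh(om[p])
            expect = np.fft.ifft(mean * 12, axis=0).real
            k = int(np.argmin(np.abs(traj.times - t)))
            errs.append(np.max(np.abs(traj.frames[k] - expect)))
        ratio = errs[1] / errs[0]
        assert 0.3 < ratio < 0.8  # halving dt roughly halves the error


def _quiet_params(N, lP):
    """Chain parameters with (numerically) zero noise for deterministic runs."""
    a, K = kb.solve_chain_parameters(N, 1.0, lP)
    return kb.ChainParameters(N=N, b=1.0, lP=lP, a=a, K=K, D=1e-24)


class TestPermutationWeights:
    def test_naive_oracle_small_chain(self, rng):
        """Log-space weights equal direct evaluation of the Boltzmann-like
        permutation factors at moderate exponents."""
        pars = kb.ChainParameters.from_targets(8, 1.0, 1.0)
        om = relaxation_rates(pars)
        rho = to_modes(rng.standard_normal((8, 3)) * 0.1)
        fin = to_modes(rng.standard_normal((8, 3)) * 0.1)
        perms = [ModeState(t) for t in _cyclic_mode_targets(fin.amplitudes)]
        t, tf = 0.3, 0.5
        w = permutation_log_weights(rho, perms, t, tf, pars)
        # naive direct evaluation, no log-sum-exp
        tau = tf - t
        naive = []
        for pm in perms:
            s = 0.0
            for p in range(1, 8):
                diff = pm.amplitudes[p] - rho.amplitudes[p] * np.exp(-om[p] * tau)
                s += om[p] * np.sum(np.abs(diff) ** 2) / (1 - np.exp(-2 * om[p] * tau))
            naive.append(np.exp(-(8 / pars.D) * s))
        naive = np.array(naive) / np.sum(naive)
        assert np.allclose(w, naive, rtol=1e-10)
        assert w.sum() == pytest.approx(1.0)

    def test_concentration_near_final_time(self, rng):
        pars = kb.ChainParameters.from_targets(8, 1.0, 1.0)
        fin = to_modes(rng.standard_normal((8, 3)))
        perms = [ModeState(t) for t in _cyclic_mode_targets(fin.amplitudes)]
        k = 3
        state = ModeState(perms[k].amplitudes.copy())
        w = permutation_log_weights(state, perms, 0.999, 1.0, pars)
        assert w[k] > 1 - 1e-9

    def test_symmetric_ring_uniform_weights(self):
        # a perfectly cyclically symmetric target: all permutations equivalent
        th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        circ = np.column_stack([np.cos(th), np.sin(th), 0 * th])
        pars = kb.ChainParameters.from_targets(8, 1.0, 1.0)
        fin = to_modes(circ)
        perms = [ModeState(t) for t in _cyclic_mode_targets(fin.amplitudes)]
        # a state equidistant (in mode space) from every cyclic shift: all
        # beads at the origin
        state = to_modes(np.zeros((8, 3)))
        w = permutation_log_weights(state, perms, 0.2, 1.0, pars)
        assert np.allclose(w, 1 / 8, atol=1e-12)

    def test_single_permutation_bit_identical_to_plain_bridge(self, rng):
        pars = kb.ChainParameters.from_targets(16, 1.0, 2.0)
        ms = to_modes(rng.standard_normal((16, 3)))
        fin = to_modes(rng.standard_normal((16, 3)))
        r1 = np.random.default_rng(99)
        r2 = np.random.default_rng(99)
        s1 = step_bridge(ms, fin, 0.3, 1.0, pars, 1e-3, r1)
        s2 = step_bridge_permuted(ms, [fin], 0.3, 1.0, pars, 1e-3, r2)
        assert np.array_equal(s1.amplitudes, s2.amplitudes)

    def test_fast_cyclic_path_matches_general_stepper(self, rng):
        """run()'s FFT weight evaluation equals the explicit permuted stepper."""
        pars = kb.ChainParameters.from_targets(12, 1.0, 1.5)
        r0 = rng.standard_normal((12, 3))
        rf = rng.standard_normal((12, 3))
        dt, tf = 1e-3, 30e-3
        traj = run(
            r0, rf, params=pars, dt=dt, tf=tf, conditioning="bridge_permuted",
            seed=5, frame_stride=1,
        )
        ms = to_modes(r0)
        perms = [ModeState(t) for t in _cyclic_mode_targets(to_modes(rf).amplitudes)]
        r = np.random.default_rng(5)
        for k in range(int(tf / dt) - 1):
            ms = step_bridge_permuted(ms, perms, k * dt, tf, pars, dt, r)
            from knotbridge.modes import from_modes

            assert np.allclose(
                from_modes(ms).positions, traj.frames[k + 1], atol=1e-9
            )


class TestRunner:
    def test_step_count_and_times(self, params_small, rng):
        r0 = rng.standard_normal((16, 3))
        rf = rng.standard_normal((16, 3))
        traj = run(
            r0, rf, params=params_small, dt=1e-3, tf=2.0, conditioning="bridge",
            seed=1, frame_stride=100,
        )
        assert traj.times[-1] == pytest.approx(2.0)
        assert traj.n_frames == 2000 // 100 + 1
        assert np.array_equal(traj.frames[0], r0)
        assert np.allclose(traj.frames[-1], rf, atol=1e-12)

    def test_swapped_endpoints_give_valid_bridge(self, params_small, rng):
        r0 = rng.standard_normal((16, 3))
        rf = rng.standard_normal((16, 3))
        fwd = run(r0, rf, params=params_small, dt=1e-3, tf=1.0,
                  conditioning="bridge", seed=2)
        rev = run(rf, r0, params=params_small, dt=1e-3, tf=1.0,
                  conditioning="bridge", seed=3)
        assert np.allclose(fwd.frames[-1], rf, atol=1e-9)
        assert np.allclose(rev.frames[-1], r0, atol=1e-9)

    def test_permuted_run_lands_on_a_cyclic_shift(self, params_small, rng):
        r0 = rng.standard_normal((16, 3))
        rf = rng.standard_normal((16, 3))
        traj = run(r0, rf, params=params_small, dt=1e-3, tf=1.0,
                   conditioning="bridge_permuted", seed=4, frame_stride=1)
        s = traj.landed_shift
        assert np.allclose(traj.frames[-1], np.roll(rf, -s, axis=0), atol=1e-9)
        # the state one dt before the regularized last step is already close
        assert np.max(np.abs(traj.frames[-2] - traj.frames[-1])) < 0.5

    def test_free_run_com_statistics(self):
        # flexible chain, K = 0: the centre of mass diffuses with D/N
        pars = kb.ChainParameters.from_targets(8, 1.0, 0.0)
        coms = []
        for seed in range(400):
            traj = run(
                np.zeros((8, 3)), None, params=pars, dt=5e-3, tf=1.0,
                conditioning="free", seed=seed, frame_stride=200,
            )
            coms.append(traj.frames[-1].mean(axis=0))
        var = np.array(coms).var(axis=0).mean()
        expect = 2 * pars.D * 1.0 / pars.N
        assert var == pytest.approx(expect, rel=0.25)

    def test_input_validation(self, params_small, rng):
        r0 = rng.standard_normal((16, 3))
        with pytest.raises(ValueError):
            run(r0, None, params=params_small, conditioning="bridge")
        with pytest.raises(ValueError):
            run(r0, r0, params=params_small, dt=0.3, tf=1.0, conditioning="bridge")
        with pytest.raises(ValueError):
            run(r0, r0, params=params_small, conditioning="nonsense")
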