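"""Free and conditioned (bridge) Langevin dynamics in mode space.

Every Fourier mode of the ring is an independent Ornstein-Uhlenbeck process
(rate Omega_p, mode-noise variances of :func:`knotbridge.modes.noise_variances`);
the centre-of-mass mode p = 0 diffuses freely.  Conditioning the dynamics to
reach a prescribed final state ``rho^f`` at time ``tf`` adds an exact drift:
with ``tau = tf - t`` and ``x = Omega_p tau``,

    p = 0:    drift = (rho0^f - rho0) / tau                      (Brownian bridge)
    p != 0:   drift = -Omega rho
                      + Omega/sinh(x) * (rho^f - rho e^{-x})
            = Omega [ rho^f csch(x) - rho coth(x) ]              (OU bridge)

which reduces continuously to the Brownian-bridge drift as Omega -> 0.  The
two hyperbolic gains are evaluated with expm1-based forms that are stable
from x ~ 1e-12 up to arguments where csch underflows harmlessly to zero.

Circular-permutation conditioning replaces the single final state by the set
of its N cyclic relabellings; the drift then pulls towards the weighted
average of the permuted targets, with log-weights

    log P1(n0) = -(N/D) sum_{p>=1} Omega_p |rho_p(n0) - rho_p e^{-x}|^2
                                   / (1 - e^{-2x})

normalized by log-sum-exp.  A cyclic shift of the final ring by n0 beads
multiplies mode p by a phase: ``rho_p(n0) = exp(+i w_p n0) rho_p^f``, so the
full weight vector costs one FFT per step.

Integration is Euler-Maruyama.  The conditional drift is formally singular
as t -> tf; the last step instead sets the final frame exactly to the target
(for permuted runs: the cyclic shift with maximal weight at the penultimate
step), an O(dt) endpoint regularization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chain import ChainParameters, RingConformation, _as_positions
from .modes import ModeState, relaxation_rates, sample_mode_noise

__all__ = [
    "BridgeTrajectory",
    "bridge_gains",
    "step_free",
    "step_bridge",
    "step_bridge_permuted",
    "permutation_log_weights",
    "run",
]

_CONDITIONINGS = ("free", "bridge", "bridge_permuted")


# ---------------------------------------------------------------------------
# array-level core (operates on raw complex mode arrays; column count free)
# ---------------------------------------------------------------------------

def bridge_gains(omega: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Stable bridge-drift gains (g_f, g_c): drift = g_f rho^f - g_c rho.

    g_f = Omega csch(Omega tau), g_c = Omega coth(Omega tau); both tend to
    1/tau as Omega -> 0 (Brownian bridge) and g_c -> Omega, g_f -> 0 for
    Omega tau >> 1.
    """
    if tau <= 0:
        raise ValueError("bridge gains need tau = tf - t > 0")
    om = np.asarray(omega, dtype=float)
    x = om * tau
    with np.errstate(over="ignore", invalid="ignore"):
        den = -np.expm1(-2.0 * x)  # 1 - e^{-2x}, exact for small x
        e = np.exp(-x)
        g_f = np.where(x > 0, 2.0 * om * e / np.where(den > 0, den, 1.0), 1.0 / tau)
        g_c = np.where(x > 0, om * (1.0 + e * e) / np.where(den > 0, den, 1.0), 1.0 / tau)
    return g_f, g_c


def _log_weights_raw(
    targets: np.ndarray, rho: np.ndarray, omega: np.ndarray, tau: float, N: int, D: float
) -> np.ndarray:
    """Unnormalized log P1 for a stack of targets, shape (M, N, C)."""
    x = omega * tau
    e = np.exp(-x)
    den = -np.expm1(-2.0 * x)
    coef = np.zeros_like(omega)
    nz = omega > 0
    coef[nz] = omega[nz] / den[nz]
    diff = targets - rho[None, :, :] * e[None, :, None]
    sq = np.abs(diff) ** 2
    return -(N / D) * np.einsum("p,mpc->m", coef, sq).real


def _normalize_log_weights(logw: np.ndarray) -> np.ndarray:
    m = np.max(logw)
    if not np.isfinite(m):
        raise FloatingPointError(
            "all permutation log-weights are -inf: the conditioned state is "
            "numerically unreachable from the current one"
        )
    w = np.exp(logw - m)
    return w / w.sum()


# ---------------------------------------------------------------------------
# public steppers (ModeState in, ModeState out)
# ---------------------------------------------------------------------------

def step_free(
    modes: ModeState, params: ChainParameters, dt: float, rng: np.random.Generator
) -> ModeState:
    """One Euler-Maruyama step of the unconditioned dynamics."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    om = relaxation_rates(params)
    rho = modes.amplitudes
    eta = sample_mode_noise(params, dt, rng, n_cols=rho.shape[1])
    return ModeState(rho - om[:, None] * rho * dt + eta)


def step_bridge(
    modes: ModeState,
    final: ModeState,
    t: float,
    tf: float,
    params: ChainParameters,
    dt: float,
    rng: np.random.Generator,
) -> ModeState:
    """One Euler-Maruyama step of the single-endpoint bridge."""
    if t >= tf:
        raise ValueError("bridge stepping requires t < tf")
    om = relaxation_rates(params)
    rho = modes.amplitudes
    g_f, g_c = bridge_gains(om, tf - t)
    drift = g_f[:, None] * final.amplitudes - g_c[:, None] * rho
    eta = sample_mode_noise(params, dt, rng, n_cols=rho.shape[1])
    return ModeState(rho + drift * dt + eta)


def permutation_log_weights(
    modes: ModeState,
    final_perms: Sequence[ModeState],
    t: float,
    tf: float,
    params: ChainParameters,
) -> np.ndarray:
    """Normalized weights P1(n0)/Q over the supplied permutation targets.

    Computed in log space and normalized with a log-sum-exp reduction; the
    weights sum to 1 and are all finite.
    """
    if t >= tf:
        raise ValueError("weights require t < tf")
    targets = np.stack([fp.amplitudes for fp in final_perms])
    om = relaxation_rates(params)
    logw = _log_weights_raw(
        targets, modes.amplitudes, om, tf - t, params.N, params.D
    )
    return _normalize_log_weights(logw)


def step_bridge_permuted(
    modes: ModeState,
    final_perms: Sequence[ModeState],
    t: float,
    tf: float,
    params: ChainParameters,
    dt: float,
    rng: np.random.Generator,
) -> ModeState:
    """One step of the circular-permutation-conditioned bridge.

    The drift is that of :func:`step_bridge` with the target replaced by the
    P1-weighted average of the permuted targets; with a single permutation it
    collapses exactly onto the plain bridge.
    """
    w = permutation_log_weights(modes, final_perms, t, tf, params)
    targets = np.stack([fp.amplitudes for fp in final_perms])
    eff = np.einsum("m,mpc->pc", w, targets)
    om = relaxation_rates(params)
    rho = modes.amplitudes
    g_f, g_c = bridge_gains(om, tf - t)
    drift = g_f[:, None] * eff - g_c[:, None] * rho
    eta = sample_mode_noise(params, dt, rng, n_cols=rho.shape[1])
    return ModeState(rho + drift * dt + eta)


# ---------------------------------------------------------------------------
# trajectory runner
# ---------------------------------------------------------------------------

@dataclass
class BridgeTrajectory:
    """Time-ordered frames of one (conditioned) Langevin run.

    ``frames`` has shape (n_frames, N, 3); ``times`` matches its first axis.
    ``top_weights`` (permuted runs) holds, per stored frame, the largest
    normalized permutation weight; ``landed_shift`` is the cyclic shift the
    run terminated on (0 for a plain bridge).
    """

    frames: np.ndarray
    times: np.ndarray
    dt: float
    tf: float
    seed: Optional[int]
    conditioning: str
    top_weights: Optional[np.ndarray] = None
    landed_shift: Optional[int] = None

    def __post_init__(self) -> None:
        if self.conditioning not in _CONDITIONINGS:
            raise ValueError(f"conditioning must be one of {_CONDITIONINGS}")
        if len(self.frames) != len(self.times):
            raise ValueError("frames/times length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> RingConformation:
        return RingConformation(self.frames[i])

    def __iter__(self):
        return (RingConformation(f) for f in self.frames)


def _cyclic_mode_targets(final_modes: np.ndarray) -> np.ndarray:
    """Stack of mode targets for all N cyclic shifts (shift n0 along axis 0)."""
    N = final_modes.shape[0]
    phases = np.exp(
        2j * np.pi * np.outer(np.arange(N), np.arange(N)) / N
    )  # [n0, p]
    return phases[:, :, None] * final_modes[None, :, :]


def run(
    initial,
    final=None,
    *,
    params: ChainParameters,
    dt: float = 1e-4,
    tf: float = 2.0,
    conditioning: str = "bridge_permuted",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    frame_stride: int = 100,
) -> BridgeTrajectory:
    """Integrate one full trajectory.

    Parameters
    ----------
    initial, final : ring conformations (``final`` may be None for free runs).
    params : chain parameters.
    dt, tf : time step and total time span; tf must be an integer number of
        steps to within one part in 1e-9.
    conditioning : 'free', 'bridge' (fixed bead correspondence) or
        'bridge_permuted' (any cyclic relabelling of the final ring).
    seed / rng : reproducibility; pass exactly one of them.
    frame_stride : store every ``frame_stride``-th frame; the exact first and
        last frames are always stored.
    """
    if conditioning not in _CONDITIONINGS:
        raise ValueError(f"conditioning must be one of {_CONDITIONINGS}")
    pos0 = _as_positions(initial)
    if pos0.shape[0] != params.N:
        raise ValueError("initial ring size does not match parameters")
    n_steps = int(round(tf / dt))
    if n_steps < 2 or abs(n_steps * dt - tf) > 1e-9 * tf:
        raise ValueError("dt must divide tf (to within one step)")
    if rng is None:
        rng = np.random.default_rng(seed)

    om = relaxation_rates(params)
    rho = np.fft.fft(pos0, axis=0) / params.N

    conditioned = conditioning != "free"
    if conditioned:
        if final is None:
            raise ValueError(f"conditioning={conditioning!r} requires a final ring")
        posf = _as_positions(final)
        if posf.shape != pos0.shape:
            raise ValueError("initial and final rings must have the same size")
        rho_f = np.fft.fft(posf, axis=0) / params.N

    frames = [pos0.copy()]
    times = [0.0]
    top_w = [1.0]
    sqrt_amp = np.sqrt(2.0 * params.D * dt)
    w = None

    for k in range(n_steps - 1):
        t = k * dt
        tau = tf - t
        eta = np.fft.fft(rng.standard_normal((params.N, 3)) * sqrt_amp, axis=0) / params.N
        if not conditioned:
            drift = -om[:, None] * rho
        elif conditioning == "bridge":
            g_f, g_c = bridge_gains(om, tau)
            drift = g_f[:, None] * rho_f - g_c[:, None] * rho
        else:
            # cyclic shifts only multiply mode p by a phase, so the weight
            # vector over all N shifts is a circular correlation: O(N log N)
            # via FFT instead of the O(N^2) general-target reduction.
            x = om * tau
            e = np.exp(-x)
            den = -np.expm1(-2.0 * x)
            coef = np.zeros_like(om)
            coef[1:] = om[1:] / den[1:]
            s_fin = float(np.sum(coef[:, None] * np.abs(rho_f) ** 2))
            s_cur = float(np.sum((coef * e * e)[:, None] * np.abs(rho) ** 2))
            h = coef * e * (rho_f.conj() * rho).sum(axis=1)
            cross = np.fft.fft(h)  # F(n0) = sum_p h_p exp(-i w_p n0)
            logw = -(params.N / params.D) * (s_fin + s_cur - 2.0 * cross.real)
            w = _normalize_log_weights(logw)
            phi = params.N * np.fft.ifft(w)  # sum_{n0} w(n0) exp(+i w_p n0)
            eff = phi[:, None] * rho_f
            g_f, g_c = bridge_gains(om, tau)
            drift = g_f[:, None] * eff - g_c[:, None] * rho
        rho = rho + drift * dt + eta
        step_index = k + 1
        if step_index % frame_stride == 0 and step_index < n_steps:
            frames.append(np.fft.ifft(rho * params.N, axis=0).real)
            times.append(step_index * dt)
            top_w.append(float(w.max()) if w is not None else 1.0)

    landed = None
    if conditioning == "bridge":
        last = posf
        landed = 0
    elif conditioning == "bridge_permuted":
        landed = int(np.argmax(w)) if w is not None else 0
        last = np.roll(posf, -landed, axis=0)
    else:
        last = np.fft.ifft(rho * params.N, axis=0).real

    if times[-1] >= tf:
        frames[-1], times[-1] = last, tf
    else:
        frames.append(last)
        times.append(tf)
        top_w.append(float(w.max()) if w is not None else 1.0)

    return BridgeTrajectory(
        frames=np.array(frames),
        times=np.array(times),
        dt=dt,
        tf=tf,
        seed=seed,
        conditioning=conditioning,
        top_weights=np.array(top_w) if conditioning == "bridge_permuted" else None,
        landed_shift=landed,
    )
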