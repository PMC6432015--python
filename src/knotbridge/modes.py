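"""Fourier (Rouse) mode representation of the ring.

The transform convention is fixed once for the whole package:

    rho_p = (1/N) sum_{n=0}^{N-1} exp(-i w_p n) r_n ,   w_p = 2 pi p / N,
    r_n   =       sum_{p=0}^{N-1} exp(+i w_p n) rho_p .

With this normalization

* ``rho_0`` is the centre of mass of the ring;
* a real-valued ring corresponds to Hermitian-symmetric amplitudes,
  ``rho_{N-p} = conj(rho_p)`` (the pair (p, N-p) is one complex degree of
  freedom);
* the mode noises inherited from independent bead noises of variance ``2 D``
  per component have per-component variance ``2 D / N`` for the purely real
  modes (p = 0 and, for even N, p = N/2) and ``D / N`` for each of the real
  and imaginary parts of every other mode.

Each mode relaxes independently under the quadratic ring potential with rate

    Omega_p = (3 / a^2) (1 - cos w_p) + 2 K (1 - cos w_p)^2 .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainParameters, RingConformation, _as_positions

__all__ = [
    "ModeState",
    "to_modes",
    "from_modes",
    "relaxation_rate",
    "relaxation_rates",
    "noise_variances",
    "sample_mode_noise",
    "mode_potential_energy",
]


@dataclass(frozen=True)
class ModeState:
    """Complex mode amplitudes rho_p, p = 0..N-1, one 3-vector per mode."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex)
        if amp.ndim != 2 or amp.shape[1] != 3:
            raise ValueError(f"amplitudes must have shape (N, 3), got {amp.shape}")
        object.__setattr__(self, "amplitudes", amp)

    @property
    def N(self) -> int:
        return self.amplitudes.shape[0]

    def hermitian_defect(self) -> float:
        """Max deviation from rho_{N-p} = conj(rho_p) (0 for a real ring)."""
        amp = self.amplitudes
        flipped = np.roll(amp[::-1], 1, axis=0)  # index p -> N-p
        return float(np.max(np.abs(amp - flipped.conj())))

    def copy(self) -> "ModeState":
        return ModeState(self.amplitudes.copy())


def to_modes(ring) -> ModeState:
    """Forward transform of bead positions; rho_0 is the centre of mass."""
    pos = _as_positions(ring)
    return ModeState(np.fft.fft(pos, axis=0) / pos.shape[0])


def from_modes(modes: ModeState, tol: float = 1e-9) -> RingConformation:
    """Inverse transform.  Raises if the amplitudes are not Hermitian.

    ``tol`` bounds the tolerated imaginary remainder per coordinate,
    relative to the coordinate scale.
    """
    amp = modes.amplitudes
    x = np.fft.ifft(amp * amp.shape[0], axis=0)
    scale = max(1.0, float(np.max(np.abs(x.real))))
    if np.max(np.abs(x.imag)) > tol * scale:
        raise ValueError(
            "mode amplitudes violate Hermitian symmetry: "
            f"imaginary remainder {np.max(np.abs(x.imag)):.3e}"
        )
    return RingConformation(x.real)


def relaxation_rates(params: ChainParameters) -> np.ndarray:
    """Vector of per-mode relaxation rates Omega_p, p = 0..N-1.

    Omega_0 = 0 (free diffusion of the centre of mass) and
    Omega_p = Omega_{N-p}.
    """
    w = 2.0 * np.pi * np.arange(params.N) / params.N
    x = 1.0 - np.cos(w)
    return (3.0 / params.a**2) * x + 2.0 * params.K * x * x


def relaxation_rate(p: int, params: ChainParameters) -> float:
    if not 0 <= p < params.N:
        raise ValueError(f"mode index p must be in [0, {params.N}), got {p}")
    return float(relaxation_rates(params)[p])


def noise_variances(params: ChainParameters, dt: float) -> np.ndarray:
    """Per-degree-of-freedom Gaussian increment variances over a step dt.

    Entry p is the variance, per Cartesian component, of each *real* degree
    of freedom of mode p over a step of length ``dt``: the purely real modes
    (p = 0 and p = N/2 for even N) get ``2 D dt / N``; for every other mode
    the real and the imaginary part each get ``D dt / N``.  Summing the two
    halves of a generic mode reproduces the total complex variance
    ``2 D dt / N``, so the reconstructed real-space noise has per-bead
    variance ``2 D dt`` per component.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    N = params.N
    v = np.full(N, params.D * dt / N)
    v[0] = 2.0 * params.D * dt / N
    if N % 2 == 0:
        v[N // 2] = 2.0 * params.D * dt / N
    return v


def sample_mode_noise(
    params: ChainParameters, dt: float, rng: np.random.Generator, n_cols: int = 3
) -> np.ndarray:
    """One Hermitian-symmetric mode-noise increment with the exact moments.

    Drawn by transforming independent real-space bead noises of variance
    ``2 D dt`` per component, which realizes the mode moments (including the
    purely real p = 0 and p = N/2 modes) with no case analysis.
    """
    eta = rng.standard_normal((params.N, n_cols)) * np.sqrt(2.0 * params.D * dt)
    return np.fft.fft(eta, axis=0) / params.N


def mode_potential_energy(modes: ModeState, params: ChainParameters) -> float:
    """Ring potential U/kBT expressed in mode space.

    The quadratic potential is diagonal in the modes:
    ``U = N sum_p Omega_p |rho_p|^2 / D``-independent form (kB*T = 1 and the
    rates carry units 1/length^2), i.e. ``U = N sum_p Omega_p |rho_p|^2``.
    """
    if modes.N != params.N:
        raise ValueError("mode count does not match parameters")
    om = relaxation_rates(params)
    return float(params.N * np.sum(om[:, None] * np.abs(modes.amplitudes) ** 2))
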