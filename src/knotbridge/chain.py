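"""Discrete semiflexible Gaussian ring model.

The ring of ``N`` beads evolves under the quadratic potential (in units of
``kB*T``)

    U = sum_n  3/(2 a^2) |r_{n+1} - r_n|^2  +  K/2 |r_{n+1} - 2 r_n + r_{n-1}|^2

with periodic indexing (``r_N = r_0``).  The first term is the entropic
elasticity of a Gaussian chain with bare bond parameter ``a``; the second is
a mean-field bending rigidity ``K`` (units 1/length^2).  Bond lengths are not
fixed, so both the root-mean-square bond length ``b`` and the persistence
length ``lP`` of the equilibrium ensemble are emergent quantities that must
be calibrated by choosing ``(a, K)``.

Calibration
-----------
Write ``kappa = K a^2 / 3`` for the dimensionless stiffness and
``w_p = 2 pi p / N``.  The exact equilibrium statistics of the quadratic
model give

* mean-square bond length:  ``b^2 = a^2 S(kappa, N)`` with
  ``S = (1/N) sum_{p=1}^{N-1} [1 + 2 kappa (1 - cos w_p)]^{-1}``
  (the p = 0 centre-of-mass mode does not contribute to bond vectors);
* bond-direction correlation: ``<u_n . u_{n+s}> / <|u|^2> = z^s`` exactly
  (for N >> decay length), with ``z = exp(-mu)`` and
  ``cosh(mu) = 1 + 1/(2 kappa)``.

The persistence length of the model is therefore ``lP = b / mu``, which for
stiff chains behaves as ``lP ~ sqrt(kappa) b``.  :func:`solve_chain_parameters`
inverts these two relations in closed form: given targets ``(b, lP)`` it sets
``kappa = 1 / (2 (cosh(b/lP) - 1))``, then ``a = b / sqrt(S)`` and
``K = 3 kappa / a^2``.

Units: ``b`` is the unit of length and ``b^2/D`` the unit of time (``D = 1``,
``b = 1`` internally); ``kB*T = 1`` so the friction is ``gamma = 1/D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingConformation",
    "ChainParameters",
    "solve_chain_parameters",
    "stiffness_from_persistence",
    "persistence_from_stiffness",
    "gaussian_bond_sum",
    "potential_energy",
    "persistence_length_estimate",
]


class CalibrationError(ValueError):
    """Raised when chain parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class RingConformation:
    """An ordered cycle of N bead positions in 3D.

    Indexing is periodic: ``ring[N] == ring[0]`` and ``ring[N+1] == ring[1]``.
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must have shape (N, 3), got {pos.shape}")
        if pos.shape[0] < 3:
            raise ValueError("a ring needs at least 3 beads")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions contain non-finite coordinates")
        object.__setattr__(self, "positions", pos)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_beads

    def __getitem__(self, n: int) -> np.ndarray:
        return self.positions[n % self.n_beads]

    def bond_vectors(self) -> np.ndarray:
        """Bond vectors u_n = r_{n+1} - r_n, n = 0..N-1 (periodic wrap)."""
        return np.roll(self.positions, -1, axis=0) - self.positions

    def contour_length(self) -> float:
        return float(np.linalg.norm(self.bond_vectors(), axis=1).sum())

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, d) -> "RingConformation":
        return RingConformation(self.positions + np.asarray(d, dtype=float))

    def rotated(self, R) -> "RingConformation":
        return RingConformation(self.positions @ np.asarray(R, dtype=float).T)

    def reindexed(self, shift: int) -> "RingConformation":
        """Cyclic relabelling: bead n of the result is bead n+shift of self."""
        return RingConformation(np.roll(self.positions, -shift, axis=0))

    def mirrored(self) -> "RingConformation":
        """Mirror image (reflection through the xy plane)."""
        out = self.positions.copy()
        out[:, 2] *= -1.0
        return RingConformation(out)


def _as_positions(ring) -> np.ndarray:
    if isinstance(ring, RingConformation):
        return ring.positions
    pos = np.asarray(ring, dtype=float)
    return RingConformation(pos).positions  # reuse validation


def stiffness_from_persistence(lP: float, b: float = 1.0) -> float:
    """Dimensionless stiffness kappa = K a^2 / 3 for a target persistence length.

    Inverts the exact pole condition of the bond-correlation decay,
    ``cosh(b/lP) = 1 + 1/(2 kappa)``; for ``lP >> b`` this is
    ``kappa ~ (lP/b)^2``.  ``lP = 0`` maps to the fully flexible chain
    (kappa = 0).
    """
    if lP < 0 or b <= 0:
        raise CalibrationError("need lP >= 0 and b > 0")
    if lP == 0:
        return 0.0
    return 1.0 / (2.0 * (math.cosh(b / lP) - 1.0))


def persistence_from_stiffness(kappa: float, b: float = 1.0) -> float:
    """Persistence length implied by kappa (inverse of stiffness_from_persistence)."""
    if kappa < 0:
        raise CalibrationError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return b / math.acosh(1.0 + 1.0 / (2.0 * kappa))


def gaussian_bond_sum(kappa: float, N: int) -> float:
    """S(kappa, N) = (1/N) sum_{p=1}^{N-1} [1 + 2 kappa (1 - cos w_p)]^{-1}.

    Equals <|u|^2> / a^2 in equilibrium.  The centre-of-mass mode p = 0 is
    excluded: it carries no bond-vector content.
    """
    if N < 3:
        raise CalibrationError("N must be >= 3")
    p = np.arange(1, N)
    w = 2.0 * np.pi * p / N
    return float(np.sum(1.0 / (1.0 + 2.0 * kappa * (1.0 - np.cos(w)))) / N)


def solve_chain_parameters(N: int, b: float, lP: float) -> tuple[float, float]:
    """Closed-form calibration of the bare parameters (a, K).

    Parameters
    ----------
    N : chain length (beads), >= 3.
    b : target root-mean-square bond length, > 0.
    lP : target persistence length (tangent-correlation decay length), >= 0.

    Returns
    -------
    (a, K) such that the equilibrium ensemble of the quadratic ring potential
    has mean-square bond length ``b^2`` and bond-direction correlations
    decaying over ``lP``.
    """
    if not (isinstance(N, (int, np.integer)) and N >= 3):
        raise CalibrationError(f"N must be an integer >= 3, got {N!r}")
    if not (np.isfinite(b) and b > 0):
        raise CalibrationError(f"b must be finite and > 0, got {b!r}")
    if not (np.isfinite(lP) and lP >= 0):
        raise CalibrationError(f"lP must be finite and >= 0, got {lP!r}")
    kappa = stiffness_from_persistence(lP, b)
    S = gaussian_bond_sum(kappa, N)
    a = b / math.sqrt(S)
    K = 3.0 * kappa / a**2
    return a, K


@dataclass(frozen=True)
class ChainParameters:
    """Parameters of the semiflexible Gaussian ring.

    Attributes
    ----------
    N : number of beads.
    b : target RMS bond length (unit of length).
    lP : target persistence length.
    a : bare Gaussian bond parameter (length).
    K : bare bending rigidity (1/length^2).
    D : bead diffusion coefficient (b^2 per unit time); kB*T = 1 so the
        friction is ``gamma = 1/D``.
    """

    N: int
    b: float
    lP: float
    a: float
    K: float
    D: float = 1.0

    _RTOL = 1e-10

    def __post_init__(self) -> None:
        if self.N < 3:
            raise CalibrationError("N must be >= 3")
        for name in ("b", "a", "D"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise CalibrationError(f"{name} must be finite and > 0, got {v!r}")
        if not (np.isfinite(self.lP) and self.lP >= 0):
            raise CalibrationError("lP must be finite and >= 0")
        if not (np.isfinite(self.K) and self.K >= 0):
            raise CalibrationError("K must be finite and >= 0")
        a_ref, K_ref = solve_chain_parameters(self.N, self.b, self.lP)
        if not math.isclose(self.a, a_ref, rel_tol=self._RTOL):
            raise CalibrationError(
                f"a = {self.a} inconsistent with targets (expected {a_ref})"
            )
        if not math.isclose(self.K, K_ref, rel_tol=self._RTOL, abs_tol=self._RTOL):
            raise CalibrationError(
                f"K = {self.K} inconsistent with targets (expected {K_ref})"
            )

    @property
    def gamma(self) -> float:
        """Friction coefficient, from the Einstein relation D = kB*T/gamma."""
        return 1.0 / self.D

    @property
    def kappa(self) -> float:
        """Dimensionless stiffness K a^2 / 3."""
        return self.K * self.a**2 / 3.0

    @classmethod
    def from_targets(
        cls, N: int, b: float = 1.0, lP: float = 0.0, D: float = 1.0
    ) -> "ChainParameters":
        a, K = solve_chain_parameters(N, b, lP)
        return cls(N=N, b=b, lP=lP, a=a, K=K, D=D)


def potential_energy(ring, params: ChainParameters) -> float:
    """Ring potential U in units of kB*T (exact double sum, periodic wrap)."""
    pos = _as_positions(ring)
    if pos.shape[0] != params.N:
        raise ValueError(f"ring has {pos.shape[0]} beads, parameters say {params.N}")
    u = np.roll(pos, -1, axis=0) - pos  # r_{n+1} - r_n
    curv = np.roll(pos, -1, axis=0) - 2.0 * pos + np.roll(pos, 1, axis=0)
    spring = 3.0 / (2.0 * params.a**2) * float(np.sum(u * u))
    bend = 0.5 * params.K * float(np.sum(curv * curv))
    return spring + bend


def _bond_correlation(pos: np.ndarray, s_max: int, normalize: bool) -> np.ndarray:
    """Circular correlation C(s) = mean_n u_n . u_{n+s} for s = 0..s_max.

    With ``normalize`` the bonds are replaced by unit tangents first.
    Computed with FFTs, O(N log N) per ring.
    """
    u = np.roll(pos, -1, axis=0) - pos
    if normalize:
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
    f = np.fft.rfft(u, axis=0)
    c = np.fft.irfft((f * f.conj()).real.sum(axis=1), n=u.shape[0]) / u.shape[0]
    return c[: s_max + 1]


def persistence_length_estimate(
    rings,
    b: float = 1.0,
    normalize: bool = False,
    n_blocks: int = 20,
) -> tuple[float, float]:
    """Estimate the persistence length from an equilibrium sample of rings.

    Fits the bond-direction correlation ``C(s) = <u_n . u_{n+s}> / <|u|^2>``
    to ``A exp(-s b / lP) + c`` over ``0 <= s <= N/2``.  The additive constant
    is required on a ring: closure enforces the exact sum rule
    ``sum_{s=0}^{N-1} C(s) = 0``, which shifts the whole correlation by a
    small negative offset ~ -1/N; ignoring it biases the decay length low.
    By default ``C(s)`` uses raw bond vectors, whose decay is exactly
    exponential (plus the closure offset) for the Gaussian model;
    ``normalize=True`` uses unit tangents instead (same asymptotic decay, a
    mildly separation-dependent amplitude for extensible bonds).

    Returns ``(lP, stderr)`` where the standard error comes from splitting
    the sample into ``n_blocks`` groups and re-estimating per group.
    """
    from scipy.optimize import curve_fit

    positions = [
        r.positions if isinstance(r, RingConformation) else np.asarray(r, float)
        for r in rings
    ]
    if len(positions) < 100:
        raise ValueError(f"need at least 100 rings, got {len(positions)}")
    N = positions[0].shape[0]
    s_max = N // 2
    corrs = np.array([_bond_correlation(p, s_max, normalize) for p in positions])
    s = np.arange(s_max + 1, dtype=float)

    def _model(ss, amp, xi, c0):
        return amp * np.exp(-ss / xi) + c0

    def _fit(c_mean: np.ndarray) -> float:
        c = c_mean / c_mean[0]
        if c[1] <= c[2:].mean():  # no correlation beyond one bond
            return 0.0
        try:
            popt, _ = curve_fit(
                _model,
                s,
                c,
                p0=(1.0, max(1.0, -1.0 / np.log(max(c[1], 1e-6))), -1.0 / N),
                bounds=([0.0, 1e-3, -0.5], [2.0, 10.0 * N, 0.5]),
                maxfev=10000,
            )
        except RuntimeError:
            return 0.0
        return b * popt[1]

    lp_full = _fit(corrs.mean(axis=0))
    blocks = np.array_split(corrs, n_blocks)
    lp_blocks = np.array([_fit(blk.mean(axis=0)) for blk in blocks])
    stderr = float(lp_blocks.std(ddof=1) / math.sqrt(len(blocks)))
    return float(lp_full), stderr
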