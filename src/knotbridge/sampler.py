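"""Generation of ring conformations of prescribed knot type.

Three sources of endpoints are provided:

* :func:`parametric_knot` -- clean parametric polygons of prescribed topology
  (torus curves for 0_1/3_1/5_1, the standard figure-eight curve for 4_1 and
  a braid-closure polygon for 5_2), either chirality on request;
* :func:`mc_equilibrate` -- fixed-topology Metropolis Monte Carlo of
  self-avoiding semiflexible cylinder rings (crankshaft moves, overlap
  rejection), to turn a parametric seed into an equilibrated conformation;
* :func:`sample_gaussian_equilibrium` -- exact equilibrium draws of the
  *phantom* quadratic model in mode space (equipartition), used to validate
  the (a, K) calibration.

Every sampled self-avoiding ring keeps the cylinder-overlap constraint
(axis-to-axis distance of non-adjacent segments >= sigma), which together
with bounded move amplitudes preserves the knot type; the knot label of the
output is re-verified by the topology layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .chain import ChainParameters, RingConformation, _as_positions
from .modes import relaxation_rates
from .topology import KnotID, knot_type, writhe

__all__ = [
    "CylinderRing",
    "parametric_knot",
    "mc_equilibrate",
    "sample_gaussian_equilibrium",
    "self_avoiding",
    "min_nonadjacent_distance",
]


# ---------------------------------------------------------------------------
# segment-segment distances / self-avoidance
# ---------------------------------------------------------------------------

def _segment_distances(P1, D1, P2, D2, eps: float = 1e-12) -> np.ndarray:
    """Minimum distances between segment batches P1+s*D1 and P2+t*D2."""
    r = P1 - P2
    a = (D1 * D1).sum(axis=-1)
    e = (D2 * D2).sum(axis=-1)
    b = (D1 * D2).sum(axis=-1)
    c = (D1 * r).sum(axis=-1)
    f = (D2 * r).sum(axis=-1)
    denom = a * e - b * b
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    redo = t != t_cl
    s = np.where(redo, np.clip((b * t_cl - c) / np.where(a > eps, a, 1.0), 0, 1), s)
    diff = P1 + s[..., None] * D1 - (P2 + t_cl[..., None] * D2)
    return np.linalg.norm(diff, axis=-1)


def min_nonadjacent_distance(positions) -> float:
    """Smallest axis-to-axis distance between non-adjacent ring segments."""
    pos = _as_positions(positions)
    N = pos.shape[0]
    iu, ju = np.triu_indices(N, 1)
    adj = (ju - iu == 1) | ((iu == 0) & (ju == N - 1))
    iu, ju = iu[~adj], ju[~adj]
    d1 = pos[(iu + 1) % N] - pos[iu]
    d2 = pos[(ju + 1) % N] - pos[ju]
    return float(_segment_distances(pos[iu], d1, pos[ju], d2).min())


def self_avoiding(positions, sigma: float) -> bool:
    """True if no two non-adjacent cylinder segments approach closer than sigma."""
    return min_nonadjacent_distance(positions) >= sigma


@dataclass(frozen=True)
class CylinderRing:
    """A self-avoiding ring of cylinders with verified knot type."""

    ring: RingConformation
    sigma: float
    knot: KnotID

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma > 0 and not self_avoiding(self.ring, self.sigma):
            raise ValueError("ring violates the cylinder self-avoidance constraint")


# ---------------------------------------------------------------------------
# parametric initializers
# ---------------------------------------------------------------------------

def _torus_curve(p: int, q: int, N: int, R: float = 2.0, r: float = 1.0) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, N, endpoint=False)
    rad = R + r * np.cos(q * th)
    return np.column_stack([rad * np.cos(p * th), rad * np.sin(p * th), r * np.sin(q * th)])


def _figure_eight_curve(N: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, N, endpoint=False)
    return np.column_stack(
        [(2 + np.cos(2 * t)) * np.cos(3 * t), (2 + np.cos(2 * t)) * np.sin(3 * t), np.sin(4 * t)]
    )


def _densify(polygon: np.ndarray, N: int) -> np.ndarray:
    """Subdivide polygon edges (keeping every original vertex) to N vertices.

    The output traces exactly the same closed polygonal curve, so the knot
    type is unchanged.
    """
    M = len(polygon)
    if N < M:
        raise ValueError(f"need at least {M} beads for this initializer")
    seg = np.roll(polygon, -1, axis=0) - polygon
    lengths = np.linalg.norm(seg, axis=1)
    extra = N - M
    # distribute subdivision points proportionally to edge length
    alloc = np.floor(extra * lengths / lengths.sum()).astype(int)
    short = extra - alloc.sum()
    if short > 0:
        order = np.argsort(-(extra * lengths / lengths.sum() - alloc))
        alloc[order[:short]] += 1
    pts = []
    for k in range(M):
        m = alloc[k] + 1
        frac = np.arange(m) / m
        pts.append(polygon[k] + frac[:, None] * seg[k])
    return np.vstack(pts)


def _braid_closure_polygon(
    word: tuple[int, ...], n_strands: int, h: float = 0.6, closure_gap: float = 1.2
) -> np.ndarray:
    """Stick polygon of the trace closure of a braid word.

    Strands run along y at integer x positions; the letter ``+i`` crosses the
    strand at position i *over* the one at position i+1 (``-i``: under) by a
    z-excursion of ``+-h``.  The closure returns each top position to the
    same bottom position through an arc at its own depth below the braid
    plane, so closure arcs intersect nothing.  The word's permutation must be
    a single N-cycle (a knot, not a link).
    """
    L = len(word)
    paths = [[np.array([float(i), 0.0, 0.0])] for i in range(n_strands)]
    at = list(range(n_strands))  # at[pos] = strand index currently there
    for step, letter in enumerate(word):
        y1 = float(step + 1)
        i = abs(letter) - 1
        if not 0 <= i < n_strands - 1:
            raise ValueError(f"braid letter {letter} out of range")
        za = h if letter > 0 else -h
        pa, pb = at[i], at[i + 1]
        paths[pa].append(np.array([i + 0.5, y1 - 0.5, za]))
        paths[pa].append(np.array([float(i + 1), y1, 0.0]))
        paths[pb].append(np.array([i + 0.5, y1 - 0.5, -za]))
        paths[pb].append(np.array([float(i), y1, 0.0]))
        at[i], at[i + 1] = pb, pa
        for pos in range(n_strands):
            if pos not in (i, i + 1):
                paths[at[pos]].append(np.array([float(pos), y1, 0.0]))
    top_pos = {s: i for i, s in enumerate(at)}
    pts: list[np.ndarray] = []
    cur, visited = 0, 0
    while True:
        pts.extend(paths[cur])
        visited += 1
        i = top_pos[cur]
        d = closure_gap * (i + 1)
        pts.append(np.array([float(i), L + 0.8, -d]))
        pts.append(np.array([float(i), -0.8, -d]))
        if i == 0:
            break
        pts.append(np.array([float(i), 0.0, 0.0]))
        cur = i
    if visited != n_strands:
        raise ValueError("braid word closes into a link, not a knot")
    out = [pts[0]]
    for p in pts[1:]:
        if np.linalg.norm(p - out[-1]) > 1e-9:
            out.append(p)
    if np.linalg.norm(out[-1] - out[0]) < 1e-9:
        out.pop()
    return np.array(out)


_TORUS_LABELS = {"0_1": (1, 0), "3_1": (2, 3), "5_1": (2, 5)}
#: standard braid words (strand count, word) for knots without a smooth curve
_BRAID_LABELS = {"5_2": (3, (1, 1, 1, 2, -1, 2))}


def parametric_knot(
    label: str,
    N: int = 240,
    bond_length: float = 1.0,
    chirality: str = "right",
    verify: bool = True,
) -> RingConformation:
    """N-bead polygon of prescribed knot type.

    Supported labels: 0_1, 3_1, 4_1, 5_1, 5_2 (and 6_1).  The polygon is
    uniformly scaled so the mean bond length equals ``bond_length`` and
    mirrored if needed so the Gauss writhe sign matches the requested
    chirality ('right' = positive writhe; ignored for achiral types).
    The resulting knot label is verified unless ``verify=False``.
    """
    if chirality not in ("right", "left"):
        raise ValueError("chirality must be 'right' or 'left'")
    if label == "0_1":
        th = np.linspace(0.0, 2.0 * np.pi, N, endpoint=False)
        pos = np.column_stack([np.cos(th), np.sin(th), np.zeros(N)])
    elif label in _TORUS_LABELS:
        p, q = _TORUS_LABELS[label]
        pos = _torus_curve(p, q, N)
    elif label == "4_1":
        pos = _figure_eight_curve(N)
    elif label in _BRAID_LABELS:
        n_strands, word = _BRAID_LABELS[label]
        pos = _densify(_braid_closure_polygon(word, n_strands), N)
    else:
        raise ValueError(f"unknown knot label {label!r}")

    if label not in ("0_1",):
        wr = writhe(pos, method="gauss")
        want_positive = chirality == "right"
        if abs(wr) > 0.5 and (wr > 0) != want_positive:
            pos = pos.copy()
            pos[:, 2] *= -1.0
    # uniform scale to the requested mean bond length
    bonds = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
    pos = pos * (bond_length / bonds.mean())
    pos -= pos.mean(axis=0)
    ring = RingConformation(pos)
    if verify:
        kid = knot_type(ring, rng=np.random.default_rng(7))
        if kid.label != label:
            raise RuntimeError(
                f"parametric initializer for {label} produced {kid.label} "
                f"(det pair {kid.det1}, {kid.det2}); increase N"
            )
    return ring


# ---------------------------------------------------------------------------
# exact phantom-model equilibrium (mode-space Gaussian)
# ---------------------------------------------------------------------------

def sample_gaussian_equilibrium(
    params: ChainParameters,
    n_samples: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[RingConformation]:
    """Independent equilibrium draws of the phantom quadratic ring.

    Each non-zero mode is Gaussian with the equipartition variance of the
    mode-diagonal potential, ``<|rho_p|^2> = 1/(2 N Omega_p)`` per Cartesian
    component (total over real and imaginary parts); the centre of mass
    (p = 0) is pinned at the origin.  Draws are generated by scaling the FFT
    of white noise, which realizes the exact joint law including the
    Hermitian pairing and the purely real p = N/2 mode.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    om = relaxation_rates(params)
    scale = np.zeros(params.N)
    scale[1:] = np.sqrt(1.0 / (2.0 * om[1:]))
    g = rng.standard_normal((n_samples, params.N, 3))
    f = np.fft.fft(g, axis=1) / params.N
    rho = f * scale[None, :, None]
    pos = np.fft.ifft(rho * params.N, axis=1).real
    return [RingConformation(p) for p in pos]


# ---------------------------------------------------------------------------
# fixed-topology Monte Carlo of self-avoiding cylinder rings
# ---------------------------------------------------------------------------

def _bend_energy_at(pos: np.ndarray, n: int, K: float) -> float:
    N = len(pos)
    v = pos[(n + 1) % N] - 2.0 * pos[n % N] + pos[(n - 1) % N]
    return 0.5 * K * float(v @ v)


def mc_equilibrate(
    start: CylinderRing,
    params: ChainParameters,
    n_sweeps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_arc: Optional[int] = None,
    max_angle: float = math.pi / 2,
    verify: bool = True,
) -> CylinderRing:
    """Metropolis Monte Carlo of the self-avoiding semiflexible ring.

    Crankshaft moves: a random sub-arc (length <= N/4 by default) is rotated
    about the chord through its end beads by a uniform random angle.
    Crankshafts leave every bond length and all arc-internal bending terms
    invariant, so only the two hinge bending energies enter the Metropolis
    ratio.  Topology protection is two-fold: moves that bring non-adjacent
    cylinders closer than sigma are rejected, and the rotation amplitude is
    capped so that no bead displaces by more than sigma in one move -- a
    strand passage between two overlap-free states requires at least 2*sigma
    of travel, so jump-through passages are excluded.  The amplitude cap
    depends only on the arc beads' distances from the rotation axis, which
    the rotation leaves invariant, so forward and reverse proposals remain
    symmetric (detailed balance).  The output's knot label is re-verified
    against the input's.

    ``n_sweeps`` sweeps of N attempted moves each are performed.
    """
    pos = start.ring.positions.copy()
    N = len(pos)
    if N != params.N:
        raise ValueError("ring size does not match parameters")
    sigma = start.sigma
    if sigma > 0 and not self_avoiding(pos, sigma):
        raise ValueError("start configuration violates self-avoidance")
    if rng is None:
        rng = np.random.default_rng(seed)
    if max_arc is None:
        max_arc = max(2, N // 4)
    idx = np.arange(N)

    for _ in range(n_sweeps * N):
        i = int(rng.integers(N))
        L = int(rng.integers(2, max_arc + 1))
        j = (i + L) % N
        axis = pos[j] - pos[i]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        axis = axis / norm
        arc = (idx[i] + 1 + np.arange(L - 1)) % N
        rel = pos[arc] - pos[i]
        if sigma > 0:
            # cap the amplitude so no bead displaces more than sigma
            # (chord <= axis_distance * angle); axis distances are invariant
            # under the rotation, so the cap is symmetric under reversal
            r_axis = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
            r_max = float(r_axis.max())
            delta = max_angle if r_max == 0 else min(max_angle, sigma / r_max)
        else:
            delta = max_angle
        angle = rng.uniform(-delta, delta)
        rot = Rotation.from_rotvec(axis * angle)
        moved = pos[i] + rot.apply(rel)

        dU = 0.0
        new_pos = pos.copy()
        new_pos[arc] = moved
        for hinge in (i, j):
            dU += _bend_energy_at(new_pos, hinge, params.K) - _bend_energy_at(
                pos, hinge, params.K
            )
        if dU > 0 and rng.random() >= math.exp(-dU):
            continue
        if sigma > 0:
            # moved segments: i .. i+L-1; static: everything else
            moved_seg = (i + np.arange(L)) % N
            static_seg = np.setdiff1d(idx, moved_seg, assume_unique=False)
            # drop static segments adjacent (sharing a bead) to a moved one
            static_seg = static_seg[
                ~np.isin(static_seg, [(i - 1) % N, j])
            ]
            if len(static_seg):
                a = new_pos[moved_seg]
                da = new_pos[(moved_seg + 1) % N] - a
                bset = new_pos[static_seg]
                db = new_pos[(static_seg + 1) % N] - bset
                dmat = _segment_distances(
                    a[:, None, :], da[:, None, :], bset[None, :, :], db[None, :, :]
                )
                if dmat.min() < sigma:
                    continue
        pos = new_pos

    ring = RingConformation(pos)
    if verify:
        kid = knot_type(ring, rng=np.random.default_rng(11))
        if kid.label != start.knot.label:
            raise RuntimeError(
                f"Monte Carlo changed the knot type: {start.knot.label} -> {kid.label}"
            )
        knot = kid
    else:
        knot = start.knot
    return CylinderRing(ring=ring, sigma=sigma, knot=knot)
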