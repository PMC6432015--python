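"""Plain-text and HDF5 I/O: XYZ conformations/trajectories, metrics, config."""

from __future__ import annotations

import numpy as np
import yaml

from .bridge import BridgeTrajectory
from .chain import ChainParameters, RingConformation, _as_positions

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "save_trajectory_h5",
    "load_trajectory_h5",
    "load_config",
    "params_from_config",
]


def write_xyz(path, ring, comment: str = "", element: str = "C") -> None:
    """Write one conformation as a single-frame XYZ block."""
    pos = _as_positions(ring)
    with open(path, "w") as fh:
        fh.write(f"{len(pos)}\n{comment}\n")
        for x, y, z in pos:
            fh.write(f"{element} {x:.12g} {y:.12g} {z:.12g}\n")


def _read_xyz_blocks(path):
    frames, comments = [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comments.append(fh.readline().rstrip("\n"))
            block = np.empty((n, 3))
            for k in range(n):
                parts = fh.readline().split()
                block[k] = [float(v) for v in parts[1:4]]
            frames.append(block)
    return frames, comments


def read_xyz(path) -> RingConformation:
    frames, _ = _read_xyz_blocks(path)
    if not frames:
        raise ValueError(f"no frames in {path}")
    return RingConformation(frames[0])


def write_trajectory_xyz(path, traj: BridgeTrajectory, element: str = "C") -> None:
    """Multi-frame XYZ; the comment line carries the time and, for permuted
    bridges, the current top permutation weight."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            pos = traj.frames[k]
            comment = f"t={traj.times[k]:.10g}"
            if traj.top_weights is not None:
                comment += f" top_weight={traj.top_weights[k]:.6g}"
            fh.write(f"{len(pos)}\n{comment}\n")
            for x, y, z in pos:
                fh.write(f"{element} {x:.12g} {y:.12g} {z:.12g}\n")


def read_trajectory_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (frames, times) from a multi-frame XYZ written by this package."""
    frames, comments = _read_xyz_blocks(path)
    times = []
    for k, c in enumerate(comments):
        t = None
        for tok in c.split():
            if tok.startswith("t="):
                t = float(tok[2:])
        times.append(t if t is not None else float(k))
    return np.array(frames), np.array(times)


def save_trajectory_h5(path, traj: BridgeTrajectory) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=traj.frames, compression="gzip")
        f.create_dataset("times", data=traj.times)
        f.attrs["dt"] = traj.dt
        f.attrs["tf"] = traj.tf
        f.attrs["conditioning"] = traj.conditioning
        if traj.seed is not None:
            f.attrs["seed"] = traj.seed
        if traj.landed_shift is not None:
            f.attrs["landed_shift"] = traj.landed_shift
        if traj.top_weights is not None:
            f.create_dataset("top_weights", data=traj.top_weights)


def load_trajectory_h5(path) -> BridgeTrajectory:
    import h5py

    with h5py.File(path, "r") as f:
        return BridgeTrajectory(
            frames=f["frames"][...],
            times=f["times"][...],
            dt=float(f.attrs["dt"]),
            tf=float(f.attrs["tf"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            conditioning=str(f.attrs["conditioning"]),
            top_weights=f["top_weights"][...] if "top_weights" in f else None,
            landed_shift=int(f.attrs["landed_shift"])
            if "landed_shift" in f.attrs
            else None,
        )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg


def params_from_config(cfg: dict) -> ChainParameters:
    """Build chain parameters from the run-config keys.

    Recognized keys: n_beads, bond_length, persistence_length, diffusion.
    """
    return ChainParameters.from_targets(
        N=int(cfg.get("n_beads", 240)),
        b=float(cfg.get("bond_length", 1.0)),
        lP=float(cfg.get("persistence_length", 5.0)),
        D=float(cfg.get("diffusion", 1.0)),
    )
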