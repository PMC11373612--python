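"""File round-trips: trajectories (HDF5/text), profiles and correlations (CSV),
spectral models (HDF5), summaries (JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .committor import CommittorProfile
from .correlators import CorrelationSeries
from .dynamics import SimParams, Trajectory
from .potentials import ThermoState
from .spectral import SpectralModel

__all__ = [
    "write_trajectory_h5", "read_trajectory_h5",
    "write_trajectory_text", "read_trajectory_text",
    "write_correlation_csv", "read_correlation_csv",
    "write_committor_csv", "read_committor_csv",
    "write_spectral_h5", "read_spectral_h5",
    "write_summary_json", "read_summary_json",
]


class ParseError(ValueError):
    """A data file could not be read; the message names the offending part."""


_SP_FIELDS = ("integrator", "dt", "n_steps", "stride", "seed",
              "initial_position", "initial_velocity", "noise_scale")


def write_trajectory_h5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        if traj.velocities is not None:
            f.create_dataset("velocities", data=traj.velocities)
        for k in _SP_FIELDS:
            f.attrs[f"sim_{k}"] = getattr(traj.params, k)
        f.attrs["potential_id"] = traj.potential_id
        f.attrs["kBT"] = traj.thermo.kBT
        f.attrs["D"] = traj.thermo.D
        if traj.thermo.mass is not None:
            f.attrs["mass"] = traj.thermo.mass


def read_trajectory_h5(path) -> Trajectory:
    try:
        with h5py.File(path, "r") as f:
            for ds in ("times", "positions"):
                if ds not in f:
                    raise ParseError(f"{path}: missing dataset {ds!r}")
            times = f["times"][:]
            positions = f["positions"][:]
            velocities = f["velocities"][:] if "velocities" in f else None
            sp_kw = {k: f.attrs[f"sim_{k}"] for k in _SP_FIELDS}
            sp_kw["integrator"] = str(sp_kw["integrator"])
            sp_kw["n_steps"] = int(sp_kw["n_steps"])
            sp_kw["stride"] = int(sp_kw["stride"])
            sp_kw["seed"] = int(sp_kw["seed"])
            th = ThermoState(
                kBT=float(f.attrs["kBT"]), D=float(f.attrs["D"]),
                mass=float(f.attrs["mass"]) if "mass" in f.attrs else None,
            )
            pot_id = str(f.attrs["potential_id"])
    except OSError as e:
        raise ParseError(f"{path}: not a readable HDF5 trajectory ({e})") from e
    return Trajectory(times, positions, velocities, SimParams(**sp_kw), pot_id, th)


def write_trajectory_text(traj: Trajectory, path) -> None:
    cols = [traj.times, traj.positions]
    header = ["time_ps", "position_A"]
    if traj.velocities is not None:
        cols.append(traj.velocities)
        header.append("velocity_A_per_ps")
    meta = {f"sim_{k}": getattr(traj.params, k) for k in _SP_FIELDS}
    meta.update(potential_id=traj.potential_id, kBT=traj.thermo.kBT,
                D=traj.thermo.D)
    if traj.thermo.mass is not None:
        meta["mass"] = traj.thermo.mass
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    lines.append("# " + "\t".join(header))
    body = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.17g", delimiter="\t")


def read_trajectory_text(path) -> Trajectory:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for ln in lines:
        if not ln.startswith("#"):
            break
        n_header += 1
        if "=" in ln:
            k, v = ln[1:].split("=", 1)
            meta[k.strip()] = v.strip()
    try:
        body = np.loadtxt(lines[n_header:], delimiter="\t", ndmin=2)
    except ValueError as e:
        raise ParseError(f"{path}: malformed data line ({e})") from e
    if body.shape[1] not in (2, 3):
        raise ParseError(f"{path}: expected 2 or 3 columns, got {body.shape[1]}")
    try:
        sp = SimParams(
            integrator=meta["sim_integrator"], dt=float(meta["sim_dt"]),
            n_steps=int(meta["sim_n_steps"]), stride=int(meta["sim_stride"]),
            seed=int(meta["sim_seed"]),
            initial_position=float(meta["sim_initial_position"]),
            initial_velocity=float(meta["sim_initial_velocity"]),
            noise_scale=float(meta["sim_noise_scale"]),
        )
        th = ThermoState(kBT=float(meta["kBT"]), D=float(meta["D"]),
                         mass=float(meta["mass"]) if "mass" in meta else None)
        pot_id = meta["potential_id"]
    except KeyError as e:
        raise ParseError(f"{path}: missing metadata key {e}") from e
    vel = body[:, 2] if body.shape[1] == 3 else None
    return Trajectory(body[:, 0], body[:, 1], vel, sp, pot_id, th)


def write_correlation_csv(cs: CorrelationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# estimator = {cs.estimator}\n# n_origins = {cs.n_origins}\n")
        fh.write("lag_ps,value,stderr\n")
        for lag, v, e in zip(cs.lags, cs.values, cs.stderr):
            fh.write(f"{lag:.17g},{v:.17g},{e:.17g}\n")


def read_correlation_csv(path) -> CorrelationSeries:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for ln in lines:
        if not ln.startswith("#"):
            break
        n_header += 1
        k, v = ln[1:].split("=", 1)
        meta[k.strip()] = v.strip()
    df = pd.read_csv(Path(path), comment="#", float_precision="round_trip")
    for col in ("lag_ps", "value", "stderr"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return CorrelationSeries(
        lags=df["lag_ps"].to_numpy(), values=df["value"].to_numpy(),
        stderr=df["stderr"].to_numpy(),
        estimator=meta.get("estimator", "unknown"),
        n_origins=int(meta.get("n_origins", 0)),
    )


def write_committor_csv(cp: CommittorProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# z1 = {cp.z1!r}\n# z2 = {cp.z2!r}\n")
        fh.write(f"# kBT = {cp.thermo.kBT!r}\n# D = {cp.thermo.D!r}\n")
        if cp.thermo.mass is not None:
            fh.write(f"# mass = {cp.thermo.mass!r}\n")
        fh.write("z,q\n")
        for z, q in zip(cp.grid, cp.q):
            fh.write(f"{z:.17g},{q:.17g}\n")


def read_committor_csv(path) -> CommittorProfile:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for ln in lines:
        if not ln.startswith("#"):
            break
        k, v = ln[1:].split("=", 1)
        meta[k.strip()] = v.strip()
    df = pd.read_csv(Path(path), comment="#", float_precision="round_trip")
    if "z" not in df.columns or "q" not in df.columns:
        raise ParseError(f"{path}: committor CSV needs columns z,q")
    try:
        th = ThermoState(kBT=float(meta["kBT"]), D=float(meta["D"]),
                         mass=float(meta["mass"]) if "mass" in meta else None)
        z1, z2 = float(meta["z1"]), float(meta["z2"])
    except KeyError as e:
        raise ParseError(f"{path}: missing metadata key {e}") from e
    return CommittorProfile(grid=df["z"].to_numpy(), q=df["q"].to_numpy(),
                            z1=z1, z2=z2, thermo=th)


def write_spectral_h5(sm: SpectralModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("bin_edges", data=sm.bin_edges)
        f.create_dataset("counts", data=sm.counts)
        f.create_dataset("T", data=sm.T)
        f.create_dataset("stationary", data=sm.stationary)
        f.create_dataset("bin_map", data=sm.bin_map)
        f.attrs["lag"] = sm.lag
        for name in ("lambdas", "mus", "left_vectors", "right_vectors"):
            arr = getattr(sm, name)
            if arr is not None:
                f.create_dataset(name, data=arr)


def read_spectral_h5(path) -> SpectralModel:
    try:
        with h5py.File(path, "r") as f:
            kw = {}
            for name in ("lambdas", "mus", "left_vectors", "right_vectors"):
                kw[name] = f[name][:] if name in f else None
            sm = SpectralModel(
                bin_edges=f["bin_edges"][:], lag=float(f.attrs["lag"]),
                counts=f["counts"][:], T=f["T"][:],
                stationary=f["stationary"][:], bin_map=f["bin_map"][:], **kw,
            )
    except (OSError, KeyError) as e:
        raise ParseError(f"{path}: not a readable spectral model ({e})") from e
    return sm


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary_json(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON at line {e.lineno}") from e
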