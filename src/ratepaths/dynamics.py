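"""Brownian and Langevin dynamics on 1D potentials, plus first-passage tools.

Integrators
-----------
* Brownian (overdamped) dynamics: Euler–Maruyama,
  z' = z + (D/kBT) F(z) dt + sqrt(2 D dt) G.
* Langevin dynamics: BAOAB splitting with friction fixed by the Einstein
  relation γ = kBT/(m D); velocities are thermalized at kBT/m.

The tight inner loops are numba-compiled; Gaussian noise is drawn chunk-wise
from a seeded :class:`numpy.random.Generator` outside the kernels, so a given
``SimParams.seed`` reproduces a trajectory bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .potentials import Potential1D, ThermoState, equilibrium_profile
from .units import KCAL_PER_MOL_IN_AMU_A2_PS2 as _E

__all__ = [
    "SimParams",
    "Trajectory",
    "simulate_brownian",
    "simulate_langevin",
    "simulate_batch",
    "shoot_committor",
    "first_passage_times",
    "sample_dividing_surface",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation protocol.

    ``noise_scale`` rescales the random force (0 disables it; a test hook for
    deterministic limits) and ``friction`` overrides the Einstein-relation
    value γ = kBT/(mD) for Langevin runs (again mainly for limiting cases).
    """

    integrator: str  # 'brownian' | 'langevin'
    dt: float
    n_steps: int
    stride: int = 1
    seed: int = 0
    initial_position: float = 0.0
    initial_velocity: float = 0.0
    noise_scale: float = 1.0
    friction: float | None = None

    def __post_init__(self) -> None:
        if self.integrator not in ("brownian", "langevin"):
            raise ValueError("integrator must be 'brownian' or 'langevin'")
        if self.dt <= 0 or self.n_steps < 1 or self.stride < 1:
            raise ValueError("need dt > 0, n_steps >= 1, stride >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled time series of positions (and Langevin velocities)."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None
    params: SimParams
    potential_id: str
    thermo: ThermoState

    @property
    def frame_dt(self) -> float:
        return self.params.dt * self.params.stride

    def __len__(self) -> int:
        return len(self.positions)


class TrajectoryEscapeError(RuntimeError):
    """Trajectory left the potential's evaluation domain (diagnostic for bad dt)."""


# -- numba kernels -----------------------------------------------------------
# family encoded through parameters: the double-well formula with h=0 and a
# huge confinement scale a_c degenerates to a flat potential.


@njit(cache=True, fastmath=True)
def _force(z, ac12, h, w, p):
    t = abs(z) / w
    ip = int(p)
    u = t**ip if ip == p else t**p  # integer fast path for the benchmark families
    dbump = -h * (p / w) * (u / t) * np.exp(-u) if t > 0.0 else 0.0
    if z < 0.0:
        dbump = -dbump
    z2 = z * z
    z4 = z2 * z2
    return -(12.0 * z4 * z4 * z2 * z / ac12 + dbump)


@njit(cache=True, fastmath=True)
def _bd_chunk(z, noise, mob_dt, amp, ac12, h, w, p, stride, out, out0):
    nw = z.shape[0]
    nf = 0
    for s in range(noise.shape[0]):
        for k in range(nw):
            zz = z[k]
            zz += mob_dt * _force(zz, ac12, h, w, p) + amp * noise[s, k]
            z[k] = zz
        if (s + 1) % stride == 0:
            for k in range(nw):
                out[out0 + nf, k] = z[k]
            nf += 1
    return nf


@njit(cache=True, fastmath=True)
def _baoab_chunk(z, v, noise, dt, inv_m, c1, c2, ac12, h, w, p,
                 stride, out, vout, out0):
    nw = z.shape[0]
    nf = 0
    half = 0.5 * dt
    for s in range(noise.shape[0]):
        for k in range(nw):
            zz = z[k]
            vv = v[k] + half * inv_m * _force(zz, ac12, h, w, p)
            zz += half * vv
            vv = c1 * vv + c2 * noise[s, k]
            zz += half * vv
            vv += half * inv_m * _force(zz, ac12, h, w, p)
            z[k] = zz
            v[k] = vv
        if (s + 1) % stride == 0:
            for k in range(nw):
                out[out0 + nf, k] = z[k]
                vout[out0 + nf, k] = v[k]
            nf += 1
    return nf


def _family_consts(pot: Potential1D) -> tuple[float, float, float, float]:
    if pot.family == "flat":
        return 1e300, 0.0, 1.0, 2.0
    if pot.family == "custom":
        raise NotImplementedError(
            "compiled integrators support the closed-form families; "
            "custom potentials are integrated through the python path"
        )
    return pot.a_c**12, pot.h, pot.w, pot.p


_CHUNK = 250_000  # steps per noise chunk; bounds memory at ~2 MB per walker


def _run_brownian(pot, th, sp, z0: np.ndarray):
    ac12, h, w, p = _family_consts(pot)
    mob_dt = th.D / th.kBT * sp.dt
    amp = np.sqrt(2.0 * th.D * sp.dt) * sp.noise_scale
    nw = z0.size
    n_frames = sp.n_steps // sp.stride
    out = np.empty((n_frames + 1, nw))
    out[0] = z0
    z = z0.copy()
    rng = np.random.default_rng(sp.seed)
    chunk = max(sp.stride, (_CHUNK // sp.stride) * sp.stride)
    done, out0 = 0, 1
    while done < sp.n_steps:
        n = min(chunk, sp.n_steps - done)
        noise = rng.standard_normal((n, nw))
        out0 += _bd_chunk(z, noise, mob_dt, amp, ac12, h, w, p, sp.stride, out, out0)
        done += n
    _check_escape(out, pot, sp)
    return out


def _run_langevin(pot, th, sp, z0: np.ndarray, v0: np.ndarray):
    if th.mass is None:
        raise ValueError("Langevin dynamics requires a mass in ThermoState")
    ac12, h, w, p = _family_consts(pot)
    kBT_m = th.kBT * _E / th.mass  # Å²/ps²
    gamma = sp.friction if sp.friction is not None else kBT_m / th.D
    c1 = np.exp(-gamma * sp.dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1) * kBT_m) * sp.noise_scale
    inv_m = _E / th.mass  # converts kcal/mol/Å force to Å/ps² acceleration
    nw = z0.size
    n_frames = sp.n_steps // sp.stride
    out = np.empty((n_frames + 1, nw))
    vout = np.empty((n_frames + 1, nw))
    out[0] = z0
    vout[0] = v0
    z, v = z0.copy(), v0.copy()
    rng = np.random.default_rng(sp.seed)
    chunk = max(sp.stride, (_CHUNK // sp.stride) * sp.stride)
    done, out0 = 0, 1
    while done < sp.n_steps:
        n = min(chunk, sp.n_steps - done)
        noise = rng.standard_normal((n, nw))
        out0 += _baoab_chunk(z, v, noise, sp.dt, inv_m, c1, c2,
                             ac12, h, w, p, sp.stride, out, vout, out0)
        done += n
    _check_escape(out, pot, sp)
    return out, vout


def _check_escape(frames: np.ndarray, pot: Potential1D, sp: SimParams) -> None:
    lo, hi = pot.domain
    bad = (frames < lo) | (frames > hi)
    if bad.any():
        i = int(np.argmax(bad.any(axis=1)))
        raise TrajectoryEscapeError(
            f"trajectory left domain [{lo}, {hi}] near step "
            f"{i * sp.stride} (dt={sp.dt} ps is likely too large)"
        )


def _times(sp: SimParams) -> np.ndarray:
    n_frames = sp.n_steps // sp.stride
    return np.arange(n_frames + 1) * (sp.dt * sp.stride)


def simulate_brownian(pot: Potential1D, th: ThermoState, sp: SimParams) -> Trajectory:
    """Single overdamped trajectory (Euler–Maruyama), seeded and reproducible."""
    if sp.integrator != "brownian":
        raise ValueError("SimParams.integrator must be 'brownian'")
    out = _run_brownian(pot, th, sp, np.array([sp.initial_position]))
    return Trajectory(_times(sp), out[:, 0], None, sp, pot.family, th)


def simulate_langevin(pot: Potential1D, th: ThermoState, sp: SimParams) -> Trajectory:
    """Single inertial trajectory (BAOAB), with velocities stored."""
    if sp.integrator != "langevin":
        raise ValueError("SimParams.integrator must be 'langevin'")
    out, vout = _run_langevin(
        pot, th, sp, np.array([sp.initial_position]), np.array([sp.initial_velocity])
    )
    return Trajectory(_times(sp), out[:, 0], vout[:, 0], sp, pot.family, th)


def simulate_batch(
    pot: Potential1D,
    th: ThermoState,
    sp: SimParams,
    n_walkers: int,
    equilibrium_start: bool = True,
) -> list[Trajectory]:
    """Batch of independent walkers advanced in one compiled loop.

    Initial positions are drawn from the equilibrium density (inverse-CDF
    sampling) unless ``equilibrium_start`` is False, in which case all walkers
    start at ``sp.initial_position``.  Langevin velocities start
    Maxwell–Boltzmann distributed.  One walker = one returned Trajectory.
    """
    rng = np.random.default_rng(np.random.SeedSequence([sp.seed, 0x5EED]))
    if equilibrium_start:
        prof = equilibrium_profile(pot, th, check_refinement=False)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (prof.density[1:] + prof.density[:-1]) * np.diff(prof.grid))])
        cdf /= cdf[-1]
        z0 = np.interp(rng.random(n_walkers), cdf, prof.grid)
    else:
        z0 = np.full(n_walkers, sp.initial_position)
    times = _times(sp)
    if sp.integrator == "brownian":
        out = _run_brownian(pot, th, sp, z0)
        return [
            Trajectory(times, out[:, k].copy(), None, sp, pot.family, th)
            for k in range(n_walkers)
        ]
    v0 = rng.standard_normal(n_walkers) * np.sqrt(th.kBT * _E / th.mass)
    out, vout = _run_langevin(pot, th, sp, z0, v0)
    return [
        Trajectory(times, out[:, k].copy(), vout[:, k].copy(), sp, pot.family, th)
        for k in range(n_walkers)
    ]


# -- first passage -----------------------------------------------------------


@njit(cache=True, fastmath=True)
def _bd_first_passage(z0, dt, mob, amp, ac12, h, w, p,
                      lo_abs, hi_abs, max_steps, seed):
    """Run until z <= lo_abs (outcome 0) or z >= hi_abs (outcome 1).

    Returns (outcome, steps); outcome -1 means censored at max_steps.
    """
    np.random.seed(seed)
    z = z0
    mob_dt = mob * dt
    for s in range(max_steps):
        z += mob_dt * _force(z, ac12, h, w, p) + amp * np.random.normal()
        if z <= lo_abs:
            return 0, s + 1
        if z >= hi_abs:
            return 1, s + 1
    return -1, max_steps


@njit(cache=True, fastmath=True)
def _lang_first_passage(z0, v0, dt, inv_m, c1, c2, ac12, h, w, p,
                        lo_abs, hi_abs, max_steps, seed):
    np.random.seed(seed)
    z, v = z0, v0
    half = 0.5 * dt
    for s in range(max_steps):
        v += half * inv_m * _force(z, ac12, h, w, p)
        z += half * v
        v = c1 * v + c2 * np.random.normal()
        z += half * v
        v += half * inv_m * _force(z, ac12, h, w, p)
        if z <= lo_abs:
            return 0, s + 1
        if z >= hi_abs:
            return 1, s + 1
    return -1, max_steps


def _fp_setup(pot, th, sp):
    ac12, h, w, p = _family_consts(pot)
    if sp.integrator == "brownian":
        mob = th.D / th.kBT
        amp = np.sqrt(2.0 * th.D * sp.dt) * sp.noise_scale
        return ("brownian", (sp.dt, mob, amp, ac12, h, w, p))
    kBT_m = th.kBT * _E / th.mass
    gamma = sp.friction if sp.friction is not None else kBT_m / th.D
    c1 = np.exp(-gamma * sp.dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1) * kBT_m) * sp.noise_scale
    return ("langevin", (sp.dt, _E / th.mass, c1, c2, ac12, h, w, p))


def shoot_committor(
    pot: Potential1D,
    th: ThermoState,
    sp_template: SimParams,
    start_positions,
    n_shots: int,
    z1: float = -7.0,
    z2: float = 7.0,
    max_steps: int = 1_000_000_000,
) -> pd.DataFrame:
    """Empirical committor by shooting: fraction of trajectories hitting z2 first.

    Returns a DataFrame with columns ``position, q_hat, stderr, n_censored``;
    censored shots (step cap reached) are excluded from q_hat but reported.
    """
    start_positions = np.atleast_1d(np.asarray(start_positions, dtype=float))
    if np.any(start_positions <= z1) or np.any(start_positions >= z2):
        raise ValueError("start positions must lie strictly inside (z1, z2)")
    kind, args = _fp_setup(pot, th, sp_template)
    ss = np.random.SeedSequence([sp_template.seed, 0x51107])
    seeds = ss.generate_state(len(start_positions) * n_shots) >> 1
    vel_rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    for i, z0 in enumerate(start_positions):
        nB = n_ok = n_cens = 0
        for j in range(n_shots):
            seed = int(seeds[i * n_shots + j])
            if kind == "brownian":
                outcome, _ = _bd_first_passage(z0, *args, z1, z2, max_steps, seed)
            else:
                v0 = vel_rng.standard_normal() * np.sqrt(th.kBT * _E / th.mass)
                outcome, _ = _lang_first_passage(z0, v0, *args, z1, z2,
                                                 max_steps, seed)
            if outcome < 0:
                n_cens += 1
            else:
                n_ok += 1
                nB += outcome
        q_hat = nB / n_ok if n_ok else np.nan
        err = np.sqrt(q_hat * (1 - q_hat) / n_ok) if n_ok else np.nan
        rows.append((z0, q_hat, err, n_cens))
    return pd.DataFrame(rows, columns=["position", "q_hat", "stderr", "n_censored"])


def first_passage_times(
    pot: Potential1D,
    th: ThermoState,
    sp_template: SimParams,
    source_region: tuple[float, float],
    target_boundary,
    n_samples: int,
    max_steps: int = 1_000_000_000,
) -> pd.DataFrame:
    """First-passage times from equilibrium-within-source starts to a boundary.

    Initial points are sampled from ρ_eq restricted to ``source_region``; each
    trajectory runs until it crosses ``target_boundary`` — a single position,
    or a pair ``(lo, hi)`` of boundaries both absorbing.  The sample mean
    estimates the MFPT.  Returns a DataFrame ``time, censored``.
    """
    lo_src, hi_src = source_region
    if np.ndim(target_boundary) == 0:
        targets = (float(target_boundary),)
    else:
        targets = tuple(float(t) for t in target_boundary)
    for t in targets:
        if lo_src <= t <= hi_src:
            raise ValueError("target boundary lies inside the source region")
    kind, args = _fp_setup(pot, th, sp_template)
    ss = np.random.SeedSequence([sp_template.seed, 0xF1257])
    rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = ss.generate_state(n_samples) >> 1
    prof = equilibrium_profile(pot, th, check_refinement=False)
    mask = (prof.grid >= lo_src) & (prof.grid <= hi_src)
    g, r = prof.grid[mask], prof.density[mask]
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(g))])
    cdf /= cdf[-1]
    starts = np.interp(rng.random(n_samples), cdf, g)
    if len(targets) == 2:
        lo_abs_all, hi_abs_all = min(targets), max(targets)
    elif targets[0] > hi_src:
        lo_abs_all, hi_abs_all = pot.domain[0] - 1.0, targets[0]
    else:  # confinement holds the walker on the open side
        lo_abs_all, hi_abs_all = targets[0], pot.domain[1] + 1.0
    rows = []
    for i, z0 in enumerate(starts):
        seed = int(seeds[i])
        lo_abs, hi_abs = lo_abs_all, hi_abs_all
        if kind == "brownian":
            _, steps = _bd_first_passage(z0, *args, lo_abs, hi_abs, max_steps, seed)
            censored = steps >= max_steps
        else:
            v0 = rng.standard_normal() * np.sqrt(th.kBT * _E / th.mass)
            out, steps = _lang_first_passage(z0, v0, *args, lo_abs, hi_abs,
                                             max_steps, seed)
            censored = out < 0
        rows.append((steps * sp_template.dt, bool(censored)))
    return pd.DataFrame(rows, columns=["time", "censored"])


def sample_dividing_surface(
    th: ThermoState, z_dagger: float, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-space points on the dividing surface: z = z†, v ~ Maxwell–Boltzmann."""
    if th.mass is None:
        raise ValueError("sampling velocities requires a mass in ThermoState")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n) * np.sqrt(th.kBT * _E / th.mass)
    return np.full(n, float(z_dagger)), v
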