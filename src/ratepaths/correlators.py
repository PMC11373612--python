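"""Time-correlation estimators and rate extraction from their slopes.

Four estimators of the reactive flux J_AB are provided, all of the
"increment" form C(0) = 0, C(t) → (slope = J_AB)·t at intermediate times:

* C_BB(t)    = ⟨H_B(0)H_B(0)⟩ − ⟨H_B(0)H_B(t)⟩        (indicator / activated dynamics)
* C_zz(t)    = p_A p_B [1 − ⟨δz(0)δz(t)⟩/⟨δz²⟩]       (position)
* C_qq(t)    = ⟨q(0)q(0)⟩ − ⟨q(0)q(t)⟩                (committor / TPT)
* C_ABqq(t)  = ⟨H_A(0) H_B(t) (q(t) − q(0))⟩           (indicator-restricted committor)

C_BB and C_qq are computed through the cancellation-free stationary identity
⟨v v⟩ − ⟨v(0)v(t)⟩ = ½⟨(v(t) − v(0))²⟩, which matters because the increments
are ~1e-4 of the variance.  Standard errors come from block averaging
(contiguous time blocks, pooled across independent walkers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .committor import CommittorProfile
from .dynamics import Trajectory, _run_langevin
from .potentials import EquilibriumProfile, Potential1D, ThermoState
from .units import KCAL_PER_MOL_IN_AMU_A2_PS2 as _E

__all__ = [
    "DividingSurface",
    "CorrelationSeries",
    "RateEstimate",
    "PlateauNotFoundError",
    "estimate_correlation",
    "population_correlation",
    "indicator_correlation",
    "position_correlation",
    "committor_correlation",
    "restricted_committor_correlation",
    "correlation_derivative",
    "extract_flux",
    "tst_rate",
    "transmission_coefficient",
]


@dataclass(frozen=True)
class DividingSurface:
    """Surface separating states A and B, in position (z†) or committor (q†)."""

    kind: str = "position"  # 'position' | 'committor'
    threshold: float = 0.0
    committor: CommittorProfile | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("position", "committor"):
            raise ValueError("kind must be 'position' or 'committor'")
        if self.kind == "committor" and not 0.0 < self.threshold < 1.0:
            raise ValueError("committor threshold must lie in (0, 1)")

    def indicator_B(self, positions: np.ndarray) -> np.ndarray:
        """H_B on a position series; z (or q) at the threshold belongs to B."""
        if self.kind == "position":
            return (positions >= self.threshold).astype(float)
        if self.committor is None:
            raise ValueError("committor-kind surface needs a CommittorProfile")
        return (self.committor.interp(positions) >= self.threshold).astype(float)


@dataclass(frozen=True)
class CorrelationSeries:
    """Lagged correlation values with block-averaged standard errors."""

    lags: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    estimator: str
    n_origins: int
    block_values: np.ndarray | None = None  # (n_blocks, n_lags)


class PlateauNotFoundError(RuntimeError):
    """The correlation derivative never stabilizes before the last lag."""


@dataclass(frozen=True)
class RateEstimate:
    """Flux/rate extracted from a correlation-function slope or plateau."""

    J_AB: float
    J_err: float
    k_AB: float | None
    kappa: float | None
    k_TST: float | None
    fit_window: tuple[float, float]
    plateau_time: float
    method: str


# -- numba inner loops -------------------------------------------------------


@njit(cache=True, fastmath=True)
def _sq_increment_sums(x, lags, n_blocks, sums, counts):
    n = x.shape[0]
    for li in range(lags.shape[0]):
        lag = lags[li]
        m = n - lag
        for b in range(n_blocks):
            t0 = b * m // n_blocks
            t1 = (b + 1) * m // n_blocks
            s = 0.0
            for t in range(t0, t1):
                d = x[t + lag] - x[t]
                s += d * d
            sums[li, b] += s
            counts[li, b] += t1 - t0


@njit(cache=True, fastmath=True)
def _lagged_product_sums(a, b_arr, lags, n_blocks, sums, counts):
    n = a.shape[0]
    for li in range(lags.shape[0]):
        lag = lags[li]
        m = n - lag
        for b in range(n_blocks):
            t0 = b * m // n_blocks
            t1 = (b + 1) * m // n_blocks
            s = 0.0
            for t in range(t0, t1):
                s += a[t] * b_arr[t + lag]
            sums[li, b] += s
            counts[li, b] += t1 - t0


@njit(cache=True, fastmath=True)
def _restricted_sums(q, lags, q_dagger, n_blocks, sums, counts):
    n = q.shape[0]
    for li in range(lags.shape[0]):
        lag = lags[li]
        m = n - lag
        for b in range(n_blocks):
            t0 = b * m // n_blocks
            t1 = (b + 1) * m // n_blocks
            s = 0.0
            for t in range(t0, t1):
                if q[t] < q_dagger and q[t + lag] >= q_dagger:
                    s += q[t + lag] - q[t]
            sums[li, b] += s
            counts[li, b] += t1 - t0


# -- helpers -----------------------------------------------------------------


def _as_traj_list(trajs) -> list[Trajectory]:
    if isinstance(trajs, Trajectory):
        return [trajs]
    out = list(trajs)
    if not out:
        raise ValueError("no trajectories given")
    dt0 = out[0].frame_dt
    if any(abs(t.frame_dt - dt0) > 1e-12 for t in out):
        raise ValueError("trajectories must share a sampling interval")
    return out


def _lag_steps(trajs: list[Trajectory], lags) -> tuple[np.ndarray, np.ndarray]:
    frame_dt = trajs[0].frame_dt
    lags = np.asarray(lags, dtype=float)
    if lags.ndim != 1 or lags.size == 0:
        raise ValueError("lags must be a non-empty 1D array of times")
    steps = np.rint(lags / frame_dt).astype(np.int64)
    if np.any(np.abs(steps * frame_dt - lags) > 1e-9 * max(frame_dt, 1.0)):
        raise ValueError("lags must be multiples of the trajectory sampling interval")
    if np.any(steps < 0):
        raise ValueError("lags must be non-negative")
    nmin = min(len(t) for t in trajs)
    if np.any(steps >= nmin):
        raise ValueError("lag exceeds trajectory length")
    return steps * frame_dt, steps


def _blocks_per_traj(n_traj: int, n_blocks: int) -> int:
    return max(1, -(-n_blocks // n_traj))  # ceil division


def _series_from_sums(lags_ps, sums, counts, estimator, scale=1.0) -> CorrelationSeries:
    block_means = sums / np.maximum(counts, 1)
    values = sums.sum(axis=1) / counts.sum(axis=1) * scale
    nb = sums.shape[1]
    if nb > 1:
        stderr = np.std(block_means * scale, axis=1, ddof=1) / np.sqrt(nb)
    else:
        stderr = np.zeros_like(values)
    return CorrelationSeries(
        lags=lags_ps, values=values, stderr=stderr, estimator=estimator,
        n_origins=int(counts.sum(axis=1).max()),
        block_values=(block_means * scale).T,
    )


def _accumulate(kernel, series_list, lags_steps, n_blocks, extra=()):
    n_traj = len(series_list)
    nb_per = _blocks_per_traj(n_traj, n_blocks)
    nb_tot = nb_per * n_traj
    sums = np.zeros((lags_steps.size, nb_tot))
    counts = np.zeros((lags_steps.size, nb_tot), dtype=np.int64)
    for i, x in enumerate(series_list):
        sl = slice(i * nb_per, (i + 1) * nb_per)
        kernel(*x, lags_steps, *extra, nb_per, sums[:, sl], counts[:, sl])
    return sums, counts


# -- estimators --------------------------------------------------------------


def estimate_correlation(trajs, observable, lags, n_blocks: int = 20) -> CorrelationSeries:
    """Raw multiple-time-origin correlation ⟨v(0)v(t)⟩ of observable v(z)."""
    tl = _as_traj_list(trajs)
    lags_ps, steps = _lag_steps(tl, lags)
    series = [np.ascontiguousarray(observable(t.positions), dtype=float) for t in tl]
    sums, counts = _accumulate(
        _lagged_product_sums, [(s, s) for s in series], steps, n_blocks
    )
    return _series_from_sums(lags_ps, sums, counts, "C_raw")


def _half_msd_series(series_list, tl, lags, n_blocks, estimator, scale=1.0):
    lags_ps, steps = _lag_steps(tl, lags)
    sums, counts = _accumulate(
        _sq_increment_sums, [(s,) for s in series_list], steps, n_blocks
    )
    return _series_from_sums(lags_ps, sums, counts, estimator, scale=0.5 * scale)


def _pApB_hat(indicators: list[np.ndarray]) -> tuple[float, float]:
    n = sum(s.size for s in indicators)
    pB = sum(float(s.sum()) for s in indicators) / n
    return 1.0 - pB, pB


def indicator_correlation(trajs, ds: DividingSurface, lags, n_blocks: int = 20
                          ) -> CorrelationSeries:
    """C_BB(t): increment correlation of the state-B indicator."""
    tl = _as_traj_list(trajs)
    H = [np.ascontiguousarray(ds.indicator_B(t.positions)) for t in tl]
    pA, pB = _pApB_hat(H)
    if pA == 0.0 or pB == 0.0:
        raise ValueError("trajectory never visits one of the states")
    return _half_msd_series(H, tl, lags, n_blocks, "C_BB")


def population_correlation(trajs, ds: DividingSurface, lags, n_blocks: int = 20
                           ) -> CorrelationSeries:
    """Normalized population correlation C(t) = 1 − C_BB(t)/(p̂_A p̂_B)."""
    tl = _as_traj_list(trajs)
    H = [np.ascontiguousarray(ds.indicator_B(t.positions)) for t in tl]
    pA, pB = _pApB_hat(H)
    if pA == 0.0 or pB == 0.0:
        raise ValueError("trajectory never visits one of the states")
    cbb = _half_msd_series(H, tl, lags, n_blocks, "C_pop", scale=1.0 / (pA * pB))
    return CorrelationSeries(
        lags=cbb.lags, values=1.0 - cbb.values, stderr=cbb.stderr,
        estimator="C_pop", n_origins=cbb.n_origins,
        block_values=None if cbb.block_values is None else 1.0 - cbb.block_values,
    )


def position_correlation(trajs, ds: DividingSurface | None = None, lags=None,
                         n_blocks: int = 20) -> CorrelationSeries:
    """C_zz(t) = p̂_A p̂_B [1 − ⟨δz(0)δz(t)⟩/⟨δz²⟩] = p̂_A p̂_B · ½MSD(t)/⟨δz²⟩.

    The p̂_A p̂_B prefactor uses the dividing surface (default: z† = 0).
    """
    tl = _as_traj_list(trajs)
    if ds is None:
        ds = DividingSurface("position", 0.0)
    allz = np.concatenate([t.positions for t in tl])
    var = float(np.var(allz))
    if var == 0.0:
        raise ValueError("position series has zero variance")
    H = [ds.indicator_B(t.positions) for t in tl]
    pA, pB = _pApB_hat(H)
    mean = float(allz.mean())
    dz = [np.ascontiguousarray(t.positions - mean) for t in tl]
    return _half_msd_series(dz, tl, lags, n_blocks, "C_zz", scale=pA * pB / var)


def committor_correlation(trajs, cp: CommittorProfile, lags, n_blocks: int = 20
                          ) -> CorrelationSeries:
    """C_qq(t): increment correlation of the committor mapped onto the trajectory."""
    tl = _as_traj_list(trajs)
    q = [np.ascontiguousarray(cp.interp(t.positions)) for t in tl]
    return _half_msd_series(q, tl, lags, n_blocks, "C_qq")


def restricted_committor_correlation(trajs, cp: CommittorProfile,
                                     ds: DividingSurface | None = None,
                                     lags=None, n_blocks: int = 20
                                     ) -> CorrelationSeries:
    """C_ABqq(t) = ⟨H_A(0) H_B(t) (q(t) − q(0))⟩, with H's defined on q vs q†."""
    if ds is None:
        ds = DividingSurface("committor", 0.5, cp)
    if ds.kind != "committor":
        raise ValueError("restricted correlator requires a committor-kind surface")
    tl = _as_traj_list(trajs)
    lags_ps, steps = _lag_steps(tl, lags)
    q = [np.ascontiguousarray(cp.interp(t.positions)) for t in tl]
    sums, counts = _accumulate(
        _restricted_sums, [(s,) for s in q], steps, n_blocks,
        extra=(float(ds.threshold),),
    )
    return _series_from_sums(lags_ps, sums, counts, "C_ABqq")


# -- derivatives and rate extraction ----------------------------------------


def _fd_stencil(v: np.ndarray, h: float) -> np.ndarray:
    """Central differences interior, one-sided at the ends; acts on last axis."""
    dv = np.empty_like(v)
    dv[..., 1:-1] = (v[..., 2:] - v[..., :-2]) / (2 * h)
    dv[..., 0] = (v[..., 1] - v[..., 0]) / h
    dv[..., -1] = (v[..., -1] - v[..., -2]) / h
    return dv


def correlation_derivative(cs: CorrelationSeries) -> CorrelationSeries:
    """Finite-difference time derivative (central interior, one-sided ends), ps⁻¹.

    When per-block values are available the error bars come from the spread
    of block-wise derivatives, which correctly accounts for the strong
    lag-to-lag correlation of C(t); naive error propagation of the per-lag
    standard errors would overestimate them grossly.
    """
    if cs.lags.size < 3:
        raise ValueError("need at least 3 lags to differentiate")
    d = np.diff(cs.lags)
    if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        raise ValueError("lags must be uniformly spaced to differentiate")
    h = d[0]
    dv = _fd_stencil(cs.values, h)
    blocks = None
    if cs.block_values is not None and cs.block_values.shape[0] > 1:
        blocks = _fd_stencil(cs.block_values, h)
        nb = blocks.shape[0]
        ds_ = np.std(blocks, axis=0, ddof=1) / np.sqrt(nb)
    else:
        s = cs.stderr
        ds_ = np.empty_like(dv)
        ds_[1:-1] = np.sqrt(s[2:] ** 2 + s[:-2] ** 2) / (2 * h)
        ds_[0] = np.sqrt(s[1] ** 2 + s[0] ** 2) / h
        ds_[-1] = np.sqrt(s[-1] ** 2 + s[-2] ** 2) / h
    return CorrelationSeries(
        lags=cs.lags.copy(), values=dv, stderr=ds_,
        estimator=cs.estimator + "_dot", n_origins=cs.n_origins,
        block_values=blocks,
    )


def find_plateau(deriv: CorrelationSeries, rel_tol: float = 0.05,
                 window: int = 20, err_mult: float = 4.0) -> int:
    """Index of the earliest lag where the derivative is stable over a window.

    A window is stable when its spread (max − min) is below
    ``rel_tol·|mean| + err_mult·⟨stderr⟩``: the second term is the statistical
    noise floor, so Monte Carlo scatter alone never masks a true plateau.
    """
    n = deriv.lags.size
    w = min(window, n)
    for i in range(0, n - w + 1):
        seg = deriv.values[i:i + w]
        tol = rel_tol * abs(seg.mean()) + err_mult * deriv.stderr[i:i + w].mean()
        if seg.max() - seg.min() <= tol:
            return i
    raise PlateauNotFoundError(
        f"{deriv.estimator}: no stable plateau before t = {deriv.lags[-1]:g} ps "
        f"(rel_tol={rel_tol}, window={w})"
    )


def extract_flux(cs: CorrelationSeries, pA: float | None = None,
                 rel_tol: float = 0.05, window: int = 20,
                 err_mult: float = 4.0, k_TST: float | None = None
                 ) -> RateEstimate:
    """Flux from the limiting slope of a correlation function.

    The derivative series is scanned for a plateau; J_AB is the error-weighted
    mean derivative over [plateau_time, t_max].  The quoted error is the
    between-block spread of the secant slope over the fit window, which is
    robust to the strong lag-to-lag correlation of the derivative points.
    """
    deriv = correlation_derivative(cs)
    i0 = find_plateau(deriv, rel_tol=rel_tol, window=window, err_mult=err_mult)
    seg, err = deriv.values[i0:], deriv.stderr[i0:]
    if np.all(err > 0):
        wgt = 1.0 / err**2
        J = float(np.sum(seg * wgt) / np.sum(wgt))
    else:
        J = float(seg.mean())
    t_lo, t_hi = float(cs.lags[i0]), float(cs.lags[-1])
    if cs.block_values is not None and cs.block_values.shape[0] > 1 and t_hi > t_lo:
        bv = cs.block_values
        slopes = (bv[:, -1] - bv[:, i0]) / (t_hi - t_lo)
        J_err = float(np.std(slopes, ddof=1) / np.sqrt(bv.shape[0]))
    else:
        J_err = float(np.median(err)) if err.size else 0.0
    k_AB = J / pA if pA else None
    kappa = (k_AB / k_TST) if (k_AB is not None and k_TST) else None
    return RateEstimate(
        J_AB=J, J_err=J_err, k_AB=k_AB, kappa=kappa, k_TST=k_TST,
        fit_window=(t_lo, t_hi), plateau_time=float(deriv.lags[i0]),
        method=cs.estimator,
    )


# -- transition state theory -------------------------------------------------


def tst_rate(profile: EquilibriumProfile, th: ThermoState, z_dagger: float) -> float:
    """TST rate k_TST = [ρ_eq(z†)/p_A]·⟨ż θ(ż)⟩ with ⟨ż θ(ż)⟩ = √(kBT/2πm), ps⁻¹."""
    if th.mass is None:
        raise ValueError("TST rate requires a mass in ThermoState")
    from .potentials import state_probabilities

    pA, _ = state_probabilities(profile, z_dagger)
    kBT_m = th.kBT * _E / th.mass
    return float(profile.interp(z_dagger) / pA * np.sqrt(kBT_m / (2.0 * np.pi)))


def transmission_coefficient(shots: tuple[np.ndarray, np.ndarray],
                             pot: Potential1D, th: ThermoState, t_max: float,
                             dt: float = 0.001, stride: int = 1,
                             z_dagger: float | None = None,
                             seed: int = 0, noise_scale: float = 1.0,
                             friction: float | None = None) -> CorrelationSeries:
    """κ(t) = ⟨v(0) H_B(t)⟩_{z†} / ⟨v(0) θ(v(0))⟩ from dividing-surface shots.

    ``shots`` is the (positions, velocities) ensemble from
    :func:`ratepaths.dynamics.sample_dividing_surface`.  The t = 0⁺ value is
    pinned to 1 analytically (a forward-moving shot is in B the instant it
    leaves the surface), using the half-Gaussian flux √(kBT/2πm) as the
    normalization rather than a finite difference.
    """
    from .dynamics import SimParams

    z0, v0 = np.asarray(shots[0], float), np.asarray(shots[1], float)
    if z_dagger is None:
        z_dagger = float(z0[0])
    n_steps = int(round(t_max / dt))
    sp = SimParams("langevin", dt=dt, n_steps=n_steps, stride=stride, seed=seed,
                   noise_scale=noise_scale, friction=friction)
    frames, _ = _run_langevin(pot, th, sp, z0.copy(), v0.copy())
    kBT_m = th.kBT * _E / th.mass
    denom = np.sqrt(kBT_m / (2.0 * np.pi))
    H = (frames[1:] >= z_dagger).astype(float)  # (n_frames, n_shots)
    per_shot = v0[None, :] * H / denom
    kappa = per_shot.mean(axis=1)
    err = per_shot.std(axis=1, ddof=1) / np.sqrt(v0.size)
    lags = np.concatenate([[0.0], np.arange(1, H.shape[0] + 1) * dt * stride])
    return CorrelationSeries(
        lags=lags,
        values=np.concatenate([[1.0], kappa]),
        stderr=np.concatenate([[0.0], err]),
        estimator="kappa", n_origins=v0.size,
    )
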