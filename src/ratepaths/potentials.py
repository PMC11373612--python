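"""One-dimensional double-well potentials and their equilibrium statistics.

The three built-in benchmark families share the functional form

    W(z) = (z / a_c)^12 + h · exp(-(|z|/w)^p) + c        [kcal/mol, z in Å]

i.e. a steep confining wall at |z| ≈ a_c = 9.51 Å plus a Gaussian-like bump of
height ``h`` and width ``w`` centred at the origin.  Depending on (h, w, p, c)
the barrier between the two symmetric wells is narrow, medium or broad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Potential1D",
    "ThermoState",
    "EquilibriumProfile",
    "FAMILY_PARAMS",
    "make_potential",
    "eval_potential",
    "eval_force",
    "equilibrium_profile",
    "state_probabilities",
]

#: (h, w, p, c) for the named double-well families; a_c = 9.51 Å for all three.
FAMILY_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "narrow": (3.3, 0.6, 2.0, -3.2),
    "medium": (3.3, 4.0, 2.0, -3.3),
    "broad": (3.2, 7.0, 16.0, -3.2),
}

_DEFAULT_DOMAIN = (-14.0, 14.0)
_DEFAULT_SPACING = 0.001


class DomainError(ValueError):
    """Raised when a position lies outside a potential's evaluation domain."""


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic/dynamic parameters of the bath.

    Parameters
    ----------
    kBT : float
        Thermal energy, kcal/mol.
    D : float
        Diffusion coefficient, Å²/ps.
    mass : float, optional
        Particle mass, amu.  Required for inertial (Langevin) dynamics;
        ``None`` for overdamped dynamics.
    """

    kBT: float
    D: float
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.mass is not None and self.mass <= 0:
            raise ValueError("mass must be positive when given")

    @property
    def beta(self) -> float:
        return 1.0 / self.kBT


@dataclass(frozen=True)
class Potential1D:
    """A 1D potential energy function with analytic derivative.

    The named families use the closed-form double-well expression above;
    ``family='custom'`` wraps user-supplied callables ``energy_fn(z)`` and
    ``dW_fn(z)`` (the derivative dW/dz, *not* the force).
    """

    family: str
    a_c: float = 9.51
    h: float = 0.0
    w: float = 1.0
    p: float = 2.0
    c: float = 0.0
    domain: tuple[float, float] = _DEFAULT_DOMAIN
    energy_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    dW_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in (*FAMILY_PARAMS, "flat", "custom"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "custom" and (self.energy_fn is None or self.dW_fn is None):
            raise ValueError("custom potentials must supply energy_fn and dW_fn")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain must be an increasing interval")

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, z: np.ndarray) -> None:
        lo, hi = self.domain
        if np.any(z < lo) or np.any(z > hi):
            raise DomainError(
                f"position outside evaluation domain [{lo}, {hi}] of {self.family!r}"
            )

    def energy(self, z):
        """W(z) in kcal/mol; vectorized."""
        z = np.asarray(z, dtype=float)
        self._check_domain(z)
        if self.family == "flat":
            return np.zeros_like(z) + self.c
        if self.family == "custom":
            return np.asarray(self.energy_fn(z), dtype=float)
        u = (np.abs(z) / self.w) ** self.p
        return (z / self.a_c) ** 12 + self.h * np.exp(-u) + self.c

    def force(self, z):
        """-dW/dz in kcal/mol/Å; vectorized."""
        z = np.asarray(z, dtype=float)
        self._check_domain(z)
        if self.family == "flat":
            return np.zeros_like(z)
        if self.family == "custom":
            return -np.asarray(self.dW_fn(z), dtype=float)
        az = np.abs(z)
        u = (az / self.w) ** self.p
        # d/dz [h e^{-u}] = -h (p/w) (|z|/w)^{p-1} sgn(z) e^{-u}
        bump = -self.h * (self.p / self.w) * (az / self.w) ** (self.p - 1.0)
        bump *= np.sign(z) * np.exp(-u)
        dW = 12.0 * z**11 / self.a_c**12 + bump
        return -dW

    @property
    def is_symmetric(self) -> bool:
        return self.family in FAMILY_PARAMS or self.family == "flat"


def make_potential(
    family: str,
    domain: tuple[float, float] = _DEFAULT_DOMAIN,
    **overrides,
) -> Potential1D:
    """Construct a named-family, flat, or custom potential."""
    if family in FAMILY_PARAMS:
        h, w, p, c = FAMILY_PARAMS[family]
        params = dict(h=h, w=w, p=p, c=c)
        params.update(overrides)
        return Potential1D(family=family, domain=domain, **params)
    if family == "flat":
        return Potential1D(family="flat", domain=domain, **overrides)
    if family == "custom":
        return Potential1D(family="custom", domain=domain, **overrides)
    raise ValueError(f"unknown family {family!r}")


def eval_potential(pot: Potential1D, z) -> np.ndarray:
    """Potential energy W(z), kcal/mol."""
    return pot.energy(z)


def eval_force(pot: Potential1D, z) -> np.ndarray:
    """Force -dW/dz, kcal/mol/Å."""
    return pot.force(z)


# -- equilibrium ------------------------------------------------------------


@dataclass(frozen=True)
class EquilibriumProfile:
    """Boltzmann marginal ρ_eq(z) = e^{-W/kBT}/Z on a uniform grid (Å⁻¹)."""

    grid: np.ndarray
    density: np.ndarray
    Z: float
    thermo: ThermoState

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def interp(self, z) -> np.ndarray:
        return np.interp(z, self.grid, self.density)

    def to_frame(self, pot: Potential1D | None = None):
        import pandas as pd

        cols = {"z": self.grid, "rho_eq": self.density}
        if pot is not None:
            cols = {"z": self.grid, "W": pot.energy(self.grid), "rho_eq": self.density}
        return pd.DataFrame(cols)


def _grid_from_spec(pot: Potential1D, grid_spec) -> np.ndarray:
    """grid_spec: None (defaults), a float spacing, or an explicit array."""
    if grid_spec is None:
        grid_spec = _DEFAULT_SPACING
    if np.isscalar(grid_spec):
        lo, hi = pot.domain
        n = int(round((hi - lo) / float(grid_spec)))
        return np.linspace(lo, hi, n + 1)
    return np.asarray(grid_spec, dtype=float)


def equilibrium_profile(
    pot: Potential1D,
    th: ThermoState,
    grid_spec=None,
    check_refinement: bool = True,
) -> EquilibriumProfile:
    """Normalized Boltzmann density on a grid, by trapezoid quadrature.

    A grid-refinement check (halved spacing) warns if the normalization
    constant shifts by more than 1e-6 relative, which indicates the grid is
    too coarse for the barrier/curvature of the potential.
    """
    grid = _grid_from_spec(pot, grid_spec)
    w = pot.energy(grid) * th.beta
    shift = w.min()
    unnorm = np.exp(-(w - shift))
    Z_shift = np.trapezoid(unnorm, grid)
    density = unnorm / Z_shift
    Z = Z_shift * np.exp(-shift)

    if check_refinement and grid.size > 2:
        fine = np.linspace(grid[0], grid[-1], 2 * (grid.size - 1) + 1)
        wf = pot.energy(fine) * th.beta
        Zf = np.trapezoid(np.exp(-(wf - shift)), fine)
        if abs(Zf - Z_shift) > 1e-6 * Zf:
            warnings.warn(
                "equilibrium_profile: normalization shifts by more than 1e-6 "
                "on grid refinement; use a finer grid",
                stacklevel=2,
            )
    return EquilibriumProfile(grid=grid, density=density, Z=Z, thermo=th)


def state_probabilities(
    profile: EquilibriumProfile, dividing_point: float
) -> tuple[float, float]:
    """(p_A, p_B) split of the equilibrium density at z†.

    Convention: z ≥ z† belongs to state B (half-open), so p_A is the integral
    of ρ_eq over z < z†.
    """
    grid, rho = profile.grid, profile.density
    if not grid[0] <= dividing_point <= grid[-1]:
        raise DomainError("dividing point outside profile grid")
    mask = grid <= dividing_point
    zA = grid[mask]
    rA = rho[mask]
    pA = float(np.trapezoid(rA, zA))
    if zA[-1] < dividing_point:  # partial trapezoid up to z†
        z0, z1 = zA[-1], dividing_point
        r1 = np.interp(dividing_point, grid, rho)
        pA += 0.5 * (rA[-1] + r1) * (z1 - z0)
    total = float(np.trapezoid(rho, grid))
    pA /= total
    return pA, 1.0 - pA
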