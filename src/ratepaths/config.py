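"""TOML experiment configuration with strict schema validation.

One TOML file describes one experiment: potential, thermodynamic state,
simulation protocol, committor boundaries, correlator settings, MSM settings
and the output directory.  Unknown keys anywhere are rejected, so a typo in a
parameter name cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .potentials import FAMILY_PARAMS, Potential1D, ThermoState, make_potential

__all__ = ["ExperimentConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, set[str]] = {
    "potential": {"family", "a_c", "h", "w", "p", "c", "domain", "spacing"},
    "thermo": {"kBT", "D", "mass"},
    "simulation": {"integrator", "dt", "n_steps", "stride", "seed",
                   "initial_position", "initial_velocity", "n_walkers"},
    "committor": {"z1", "z2", "spacing"},
    "correlators": {"estimators", "lag_max", "lag_spacing", "n_blocks",
                    "plateau_rel_tol", "plateau_window"},
    "msm": {"bins", "lag", "range"},
    "output": {"directory"},
}

_ESTIMATORS = {"bb", "zz", "qq", "abqq"}


@dataclass
class ExperimentConfig:
    potential: dict
    thermo: dict
    simulation: dict
    committor: dict = field(default_factory=dict)
    correlators: dict = field(default_factory=dict)
    msm: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, allowed in _SCHEMA.items():
            got = getattr(self, section)
            unknown = set(got) - allowed
            if unknown:
                raise ConfigError(
                    f"[{section}]: unknown keys {sorted(unknown)}; "
                    f"allowed: {sorted(allowed)}"
                )
        fam = self.potential.get("family")
        if fam not in (*FAMILY_PARAMS, "flat"):
            raise ConfigError(f"[potential].family must be one of "
                              f"{sorted((*FAMILY_PARAMS, 'flat'))}, got {fam!r}")
        for key in ("kBT", "D"):
            if key not in self.thermo:
                raise ConfigError(f"[thermo].{key} is required")
        integ = self.simulation.get("integrator")
        if integ not in ("brownian", "langevin"):
            raise ConfigError("[simulation].integrator must be "
                              "'brownian' or 'langevin'")
        if integ == "langevin" and "mass" not in self.thermo:
            raise ConfigError("[thermo].mass is required for Langevin dynamics")
        if "seed" not in self.simulation:
            raise ConfigError("[simulation].seed is mandatory for stochastic runs")
        for key in ("dt", "n_steps"):
            if key not in self.simulation:
                raise ConfigError(f"[simulation].{key} is required")
        est = self.correlators.get("estimators", ["bb", "zz", "qq", "abqq"])
        bad = set(est) - _ESTIMATORS
        if bad:
            raise ConfigError(f"unknown correlator estimators {sorted(bad)}")

    # -- derived objects ----------------------------------------------------

    def build_potential(self) -> Potential1D:
        kw = dict(self.potential)
        fam = kw.pop("family")
        kw.pop("spacing", None)
        if "domain" in kw:
            kw["domain"] = tuple(kw["domain"])
        return make_potential(fam, **kw)

    def build_thermo(self) -> ThermoState:
        return ThermoState(kBT=float(self.thermo["kBT"]),
                           D=float(self.thermo["D"]),
                           mass=self.thermo.get("mass"))

    def content_hash(self) -> str:
        """Stable short hash of the full config, for provenance in outputs."""
        canon = repr(sorted(
            (sec, sorted((k, repr(v)) for k, v in getattr(self, sec).items()))
            for sec in _SCHEMA
        ))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> ExperimentConfig:
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as e:
            raise ConfigError(f"{path}: {e}") from e
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    return ExperimentConfig(**{k: raw.get(k, {}) for k in _SCHEMA})
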