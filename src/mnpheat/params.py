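"""Simulation parameters and derived physical constants.

All quantities are stored in SI units.  The user-facing configuration file
uses unit-suffixed keys (``radius_nm``, ``dt_ps``, ``moment_muB`` ...) and is
converted on load; see :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .constants import K_B, MU_B


class ParameterError(ValueError):
    """Raised when a physical or numerical parameter is invalid."""


@dataclass(frozen=True)
class SimulationParams:
    """Physical and numerical constants of a rotational Langevin run.

    Parameters
    ----------
    temperature : float
        Bath temperature, K.
    viscosity : float
        Dynamic viscosity of the carrier fluid, Pa s.
    mass_density : float
        Particle mass density, kg m^-3 (iron oxide ~ 5e3).
    moment_mu_B : float
        Magnitude of the particle magnetic moment, in Bohr magnetons.
    particle_radius : float
        Hydrodynamic radius, m.
    time_step : float
        Integration time step, s.  Must not exceed the angular-momentum
        relaxation time I/zeta so the torque kicks resolve the inertial
        dynamics.
    n_steps : int
        Number of production steps.
    cutoff : float
        Real-space cutoff of the dipolar interaction sum, m.
    seed : int
        Seed of the (counter-based) noise generator.
    external_field : tuple of float
        Static uniform field B1, T.
    """

    temperature: float = 320.0
    viscosity: float = 7e-4
    mass_density: float = 5e3
    moment_mu_B: float = 1.3e5
    particle_radius: float = 5e-9
    time_step: float = 10e-12
    n_steps: int = 1_000_000
    cutoff: float = 100e-9
    seed: int = 0
    external_field: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "mass_density", "moment_mu_B",
                     "particle_radius", "time_step", "cutoff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                if name == "temperature" and v == 0.0:
                    continue  # T = 0 is a legal (noiseless) limit
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if self.n_steps < 1:
            raise ParameterError(f"n_steps must be >= 1, got {self.n_steps}")
        if len(self.external_field) != 3:
            raise ParameterError("external_field must be a 3-vector (tesla)")
        if self.time_step > self.momentum_relaxation_time * (1 + 1e-12):
            raise ParameterError(
                f"time_step {self.time_step:g} s exceeds the angular-momentum "
                f"relaxation time I/zeta = {self.momentum_relaxation_time:g} s; "
                "reduce dt to resolve the inertial dynamics")

    # ---- derived quantities -------------------------------------------------

    @property
    def moment(self) -> float:
        """Magnetic moment mu, A m^2."""
        return self.moment_mu_B * MU_B

    @property
    def volume(self) -> float:
        """Particle volume V = (4/3) pi R^3, m^3."""
        return (4.0 / 3.0) * np.pi * self.particle_radius ** 3

    @property
    def friction(self) -> float:
        """Angular viscous friction zeta = 6 eta V, N m s."""
        return 6.0 * self.viscosity * self.volume

    @property
    def inertia(self) -> float:
        """Moment of inertia of a uniform solid sphere, I = (2/5) m R^2, kg m^2."""
        mass = self.mass_density * self.volume
        return 0.4 * mass * self.particle_radius ** 2

    @property
    def momentum_relaxation_time(self) -> float:
        """Angular-momentum relaxation time I/zeta, s."""
        return self.inertia / self.friction

    @property
    def thermal_energy(self) -> float:
        """k_B T, J."""
        return K_B * self.temperature

    @property
    def brownian_time(self) -> float:
        """Brownian (Debye) orientational relaxation time tau_B = 3 eta V / k_B T, s.

        Infinite at T = 0 (no thermal reorientation).
        """
        if self.thermal_energy == 0.0:
            return np.inf
        return 3.0 * self.viscosity * self.volume / self.thermal_energy

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["external_field"] = list(d["external_field"])
        return d


# ---- configuration files ---------------------------------------------------

_SCALES = {
    "temperature_K": ("temperature", 1.0),
    "viscosity_Pa_s": ("viscosity", 1.0),
    "mass_density_kg_m3": ("mass_density", 1.0),
    "moment_muB": ("moment_mu_B", 1.0),
    "radius_nm": ("particle_radius", 1e-9),
    "dt_ps": ("time_step", 1e-12),
    "n_steps": ("n_steps", 1),
    "cutoff_nm": ("cutoff", 1e-9),
    "seed": ("seed", 1),
}


def load_config(path: str | Path) -> tuple[SimulationParams, dict]:
    """Read a flat key-value config file (YAML; JSON is a YAML subset).

    Returns the :class:`SimulationParams` plus a dict of lattice/run keys
    (``n_side``, ``spacing`` in m, and any remaining extras such as
    ``record_stride`` or ``burn_in_steps``).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} did not parse to a mapping")
    kwargs, extras = {}, {}
    for key, value in raw.items():
        if key in _SCALES:
            field, scale = _SCALES[key]
            kwargs[field] = type(scale)(value) * scale if scale != 1 else value
        elif key == "external_field_mT":
            kwargs["external_field"] = tuple(1e-3 * float(v) for v in value)
        elif key == "n_side":
            extras["n_side"] = int(value)
        elif key == "spacing_nm":
            extras["spacing"] = float(value) * 1e-9
        else:
            extras[key] = value
    return SimulationParams(**kwargs), extras


def dump_params(params: SimulationParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


# ---- relaxation-time prediction --------------------------------------------

def coupling_energy(rho: float, moment: float) -> float:
    """Nearest-neighbor dipolar energy scale U(rho) = mu0 mu^2 rho^{3/2} / 4 pi, J.

    rho is the surface density 1/d^2 in m^-2, so rho^{3/2} = 1/d^3.
    """
    from .constants import MU0_OVER_4PI
    return MU0_OVER_4PI * moment * moment * rho ** 1.5


def predicted_relaxation_time(params: SimulationParams, rho: float,
                              prefactor: float = 1.0) -> float:
    """Relaxation time from additive rates, 1/tau = 1/tau_B + a U(rho)/zeta.

    The interaction rate 1/tau_U = U(rho)/zeta follows from the
    nearest-neighbor coupling scale; ``prefactor`` is the single order-unity
    constant the rate law leaves free.  rho = 0 returns tau_B exactly.
    """
    if rho < 0:
        raise ParameterError("rho must be >= 0")
    rate = 0.0 if np.isinf(params.brownian_time) else 1.0 / params.brownian_time
    rate += prefactor * coupling_energy(rho, params.moment) / params.friction
    if rate == 0.0:
        return np.inf
    return 1.0 / rate
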