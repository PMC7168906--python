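"""Viscoelastic material models for shear wave propagation.

Soft tissue responds to shear as a viscoelastic solid: the shear modulus is a
complex, frequency-dependent quantity ``G*(omega)``, and plane shear waves are
therefore dispersive and attenuating.  This module provides the two standard
two-parameter rheological models used in elastography,

* Kelvin–Voigt (spring and dashpot in parallel): ``G* = mu + i*omega*eta``,
  phase velocity increases with frequency without bound;
* Maxwell (spring and dashpot in series):
  ``G* = i*omega*mu2*mu1 / (mu1 + i*omega*mu2)``, phase velocity saturates at
  ``sqrt(mu1/rho)`` at high frequency;

plus the purely elastic limit ``G* = mu``.  Phase velocity and attenuation are
computed from the exact complex wavenumber

    k(omega) = omega * sqrt(rho / G*(omega)),   Re k > 0,

with ``c(omega) = omega / Re k`` and attenuation ``alpha = -Im k`` (Np/m),
rather than from any low-viscosity approximation.  The common Kelvin–Voigt
approximation is available separately for sensitivity checks.

All quantities are SI internally (Pa, Pa*s, kg/m^3, rad/s, m/s); kPa and Hz
appear only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ConfigError

__all__ = [
    "KelvinVoigtParams",
    "MaxwellParams",
    "ElasticParams",
    "Medium",
    "complex_modulus",
    "wavenumber",
    "phase_velocity",
    "kv_phase_velocity_approx",
    "attenuation",
    "modulus_from_velocity",
    "velocity_from_modulus",
]

#: Density assumed for soft tissue when none is given, kg/m^3.
DEFAULT_DENSITY = 1000.0


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Kelvin–Voigt parameters: shear elasticity ``mu`` (Pa), viscosity ``eta`` (Pa*s)."""

    mu: float
    eta: float = 0.0

    def __post_init__(self):
        if not self.mu > 0:
            raise ConfigError(f"Kelvin-Voigt mu must be > 0, got {self.mu}")
        if self.eta < 0:
            raise ConfigError(f"Kelvin-Voigt eta must be >= 0, got {self.eta}")


@dataclass(frozen=True)
class MaxwellParams:
    """Maxwell parameters: shear elasticity ``mu1`` (Pa), viscosity ``mu2`` (Pa*s)."""

    mu1: float
    mu2: float

    def __post_init__(self):
        if not self.mu1 > 0:
            raise ConfigError(f"Maxwell mu1 must be > 0, got {self.mu1}")
        if not self.mu2 > 0:
            raise ConfigError(f"Maxwell mu2 must be > 0, got {self.mu2}")


@dataclass(frozen=True)
class ElasticParams:
    """Purely elastic medium: shear modulus ``mu`` (Pa)."""

    mu: float

    def __post_init__(self):
        if not self.mu > 0:
            raise ConfigError(f"elastic mu must be > 0, got {self.mu}")


RheologyParams = Union[KelvinVoigtParams, MaxwellParams, ElasticParams]

_MODEL_NAMES = {
    KelvinVoigtParams: "kelvin_voigt",
    MaxwellParams: "maxwell",
    ElasticParams: "elastic",
}


@dataclass(frozen=True)
class Medium:
    """A homogeneous isotropic medium: rheological parameters plus density.

    Parameters
    ----------
    params
        One of :class:`KelvinVoigtParams`, :class:`MaxwellParams` or
        :class:`ElasticParams`.
    rho
        Mass density in kg/m^3 (default 1000, the usual soft-tissue value).
    """

    params: RheologyParams
    rho: float = DEFAULT_DENSITY

    def __post_init__(self):
        if type(self.params) not in _MODEL_NAMES:
            raise ConfigError(
                f"unknown rheological parameter record {type(self.params).__name__}"
            )
        if not self.rho > 0:
            raise ConfigError(f"density must be > 0, got {self.rho}")

    @property
    def model(self) -> str:
        return _MODEL_NAMES[type(self.params)]

    # -- serialization with explicit unit suffixes ---------------------------

    def to_dict(self) -> dict:
        d = {"model": self.model, "rho_kg_m3": self.rho}
        p = self.params
        if isinstance(p, KelvinVoigtParams):
            d.update(mu_pa=p.mu, eta_pa_s=p.eta)
        elif isinstance(p, MaxwellParams):
            d.update(mu1_pa=p.mu1, mu2_pa_s=p.mu2)
        else:
            d.update(mu_pa=p.mu)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Medium":
        d = dict(d)
        model = d.pop("model", None)
        rho = d.pop("rho_kg_m3", DEFAULT_DENSITY)
        if model == "kelvin_voigt":
            params = KelvinVoigtParams(mu=d.pop("mu_pa"), eta=d.pop("eta_pa_s", 0.0))
        elif model == "maxwell":
            params = MaxwellParams(mu1=d.pop("mu1_pa"), mu2=d.pop("mu2_pa_s"))
        elif model == "elastic":
            params = ElasticParams(mu=d.pop("mu_pa"))
        else:
            raise ConfigError(f"unknown rheological model {model!r}")
        if d:
            raise ConfigError(f"unknown medium keys: {sorted(d)}")
        return cls(params=params, rho=rho)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Medium":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def complex_modulus(medium: Medium, omega) -> np.ndarray:
    """Complex shear modulus ``G*(omega)`` in Pa.

    ``omega`` is angular frequency in rad/s (scalar or array, >= 0).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ConfigError("omega must be >= 0")
    p = medium.params
    if isinstance(p, KelvinVoigtParams):
        g = p.mu + 1j * omega * p.eta
    elif isinstance(p, MaxwellParams):
        iwm2 = 1j * omega * p.mu2
        g = iwm2 * p.mu1 / (p.mu1 + iwm2)
    elif isinstance(p, ElasticParams):
        g = p.mu + 0j * omega
    else:  # pragma: no cover - guarded by Medium.__post_init__
        raise ConfigError(f"unknown rheological model {medium.model!r}")
    return g if g.ndim else complex(g)


def wavenumber(medium: Medium, omega) -> np.ndarray:
    """Complex wavenumber ``k(omega) = omega*sqrt(rho/G*)`` with ``Re k > 0``.

    The principal square root already selects the branch with positive real
    part and non-positive imaginary part (a forward-travelling, decaying
    wave), since ``arg G* in [0, pi/2]`` for all supported models.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ConfigError("omega must be > 0")
    g = np.asarray(complex_modulus(medium, omega), dtype=complex)
    k = omega * np.sqrt(medium.rho / g)
    return k if k.ndim else complex(k)


def phase_velocity(medium: Medium, omega) -> np.ndarray:
    """Shear-wave phase velocity ``c(omega) = omega / Re k(omega)`` in m/s."""
    omega = np.asarray(omega, dtype=float)
    k = np.asarray(wavenumber(medium, omega), dtype=complex)
    c = omega / k.real
    return c if c.ndim else float(c)


def kv_phase_velocity_approx(params: KelvinVoigtParams, rho: float, omega) -> np.ndarray:
    """Widely used closed-form Kelvin–Voigt phase-velocity approximation.

    ``c = sqrt(2*(mu^2 + omega^2 eta^2) / (rho*(mu + sqrt(mu^2 + omega^2 eta^2))))``

    Kept for comparison with the exact complex-wavenumber evaluation (the two
    agree in the elastic limit and to first order in ``omega*eta/mu``).
    """
    omega = np.asarray(omega, dtype=float)
    m = np.sqrt(params.mu**2 + (omega * params.eta) ** 2)
    c = np.sqrt(2.0 * m**2 / (rho * (params.mu + m)))
    return c if c.ndim else float(c)


def attenuation(medium: Medium, omega) -> np.ndarray:
    """Shear-wave attenuation coefficient ``-Im k(omega)`` in Np/m (>= 0)."""
    omega = np.asarray(omega, dtype=float)
    k = np.asarray(wavenumber(medium, omega), dtype=complex)
    a = -k.imag
    return a if a.ndim else float(a)


def modulus_from_velocity(c, rho: float = DEFAULT_DENSITY):
    """Elastic shear modulus from wave speed: ``mu = rho * c**2`` (Pa)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ConfigError("velocity must be >= 0")
    if not rho > 0:
        raise ConfigError("density must be > 0")
    mu = rho * c**2
    return mu if mu.ndim else float(mu)


def velocity_from_modulus(mu, rho: float = DEFAULT_DENSITY):
    """Elastic shear wave speed from modulus: ``c = sqrt(mu/rho)`` (m/s)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ConfigError("modulus must be >= 0")
    if not rho > 0:
        raise ConfigError("density must be > 0")
    c = np.sqrt(mu / rho)
    return c if c.ndim else float(c)
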