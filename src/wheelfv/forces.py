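"""Resistive-force models and the net horizontal force trace.

Two resistive models are implemented, both fed by the fitted sprint model's
velocity and acceleration:

**AF (air friction)** — the model conventionally used for overground
able-bodied sprinting.  The only resistance is aerodynamic drag
``FR = k (V - Vwind)^2`` with ``k = 0.5 * rho * SA * 0.9`` built from a
stature/mass surface-area estimate and the ambient air density.

**CRF (chair rolling friction)** — a wheelchair-rugby-specific model built
on wind-tunnel and controlled roll-down characterization of rugby chairs.
A velocity-dependent dynamic friction coefficient

    mu = (m*a + CD(V)*V^2) / (m*g + CL(V)*V^2)

combines inertial, drag, gravitational and lift forces, with drag and lift
constants that decay with velocity towards finite asymptotes:

    CD(V) = 0.2955 / (V + 0.0762) + 0.1608
    CL(V) = 0.2099 / (V + 0.1218) + 0.1666

and the resistive force is ``FR = mu * m * g``.

Either resistive force is added to the inertial term to give the net
horizontal force ``FNet = m*a + FR``, from which power ``P = FNet * V``.

Sign convention: resistive forces are returned as positive magnitudes and
*added* in the net-force equation (they are forces the athlete must
overcome, so they increase the propulsive force required).

Note on the CRF model: because mu's numerator contains the inertial term
m*a, adding mu*m*g to m*a counts inertia twice relative to a strict
free-body reading.  This is deliberate — it reproduces the published
computation, whose force outputs align better with direct dynamometry of
comparable athletes, and it makes the zero-velocity net force exactly twice
the AF value.  A strict free-body variant (mu without the inertial term) is
available via ``strict_freebody=True`` but is not the default.

Pressure units: the air-density formula divides pressure by the reference
value 760 (a mmHg convention).  ``pressure`` arguments throughout are in
these formula units; use :func:`pressure_from_hpa` to convert a barometer
reading in hectopascal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import AthleteChairSystem, EnvironmentConditions
from .monoexp import MonoExpFit, model_acceleration, model_velocity

#: Gravitational acceleration, m/s^2.
G = 9.81

#: Reference pressure in formula units (mmHg convention).
PRESSURE_REF = 760.0
#: Standard atmosphere in hPa, used by the unit converter.
HPA_REF = 1013.25

# CRF drag/lift constant parameters (amplitude, velocity offset, asymptote)
_CD_A, _CD_B, _CD_C = 0.2955, 0.0762, 0.1608
_CL_A, _CL_B, _CL_C = 0.2099, 0.1218, 0.1666


def pressure_from_hpa(hpa: float) -> float:
    """Convert a barometer reading in hPa to formula pressure units."""
    return PRESSURE_REF * hpa / HPA_REF


def pressure_from_mmhg(mmhg: float) -> float:
    """mmHg readings are already in formula units."""
    return mmhg


def surface_area(stature: float, mass: float) -> float:
    """Frontal surface area estimate (m^2) from seated stature and mass.

    SA = 0.2025 * H^0.725 * m^0.425 * 0.266 — a Du Bois-type body-surface
    scaling with a frontal-area fraction.
    """
    if stature <= 0 or mass <= 0:
        raise ValueError("stature and mass must be positive")
    return 0.2025 * stature**0.725 * mass**0.425 * 0.266


def air_density(pressure: float, temperature: float) -> float:
    """Air density (kg/m^3): rho = 1.293 * (pressure/760) * (273/(273+T))."""
    if temperature <= -273.0:
        raise ValueError("temperature below absolute zero")
    return 1.293 * (pressure / PRESSURE_REF) * (273.0 / (273.0 + temperature))


def af_drag_constant(rho: float, sa: float) -> float:
    """Aerodynamic drag constant k = 0.5 * rho * SA * 0.9 (kg/m)."""
    return 0.5 * rho * sa * 0.9


def af_resistive_force(vt, k: float, vwind: float = 0.0):
    """Air-friction resistive force magnitude k*(V - Vwind)^2 (N)."""
    vt = np.asarray(vt, dtype=float)
    out = k * (vt - vwind) ** 2
    return out if out.ndim else float(out)


def crf_drag_constant(vt):
    """Velocity-dependent drag constant CD(V) = 0.2955/(V+0.0762) + 0.1608."""
    vt = np.asarray(vt, dtype=float)
    out = _CD_A / (vt + _CD_B) + _CD_C
    return out if out.ndim else float(out)


def crf_lift_constant(vt):
    """Velocity-dependent lift constant CL(V) = 0.2099/(V+0.1218) + 0.1666."""
    vt = np.asarray(vt, dtype=float)
    out = _CL_A / (vt + _CL_B) + _CL_C
    return out if out.ndim else float(out)


def dynamic_friction_mu(at, vt, mass: float, strict_freebody: bool = False):
    """Dynamic friction coefficient of the chair-rolling-friction model.

    mu = (m*a + CD(V)*V^2) / (m*g + CL(V)*V^2).  With
    ``strict_freebody=True`` the inertial term m*a is dropped from the
    numerator (see module docstring).
    """
    if not mass > 0:
        raise ValueError("mass must be positive")
    at = np.asarray(at, dtype=float)
    vt = np.asarray(vt, dtype=float)
    inertial = 0.0 if strict_freebody else mass * at
    num = inertial + crf_drag_constant(vt) * vt**2
    den = mass * G + crf_lift_constant(vt) * vt**2
    out = num / den
    return out if out.ndim else float(out)


def crf_resistive_force(mu, mass: float):
    """Chair-rolling-friction resistive force FR = mu * m * g (N)."""
    if not mass > 0:
        raise ValueError("mass must be positive")
    mu = np.asarray(mu, dtype=float)
    out = mu * mass * G
    return out if out.ndim else float(out)


@dataclass
class AirFrictionParams:
    """Bundled AF-model constants for one athlete and environment."""

    sa: float
    rho: float
    k: float
    vwind: float = 0.0

    @classmethod
    def from_system_env(
        cls, system: AthleteChairSystem, env: EnvironmentConditions
    ) -> "AirFrictionParams":
        sa = surface_area(system.stature, system.system_mass)
        rho = air_density(env.pressure, env.temperature)
        return cls(sa=sa, rho=rho, k=af_drag_constant(rho, sa), vwind=env.wind_velocity)


@dataclass
class ForceTrace:
    """Time series of velocity, acceleration, resistive and net force.

    ``fnet = m*a + fr`` pointwise and ``power = fnet * vt``.
    """

    t: np.ndarray
    vt: np.ndarray
    at: np.ndarray
    fr: np.ndarray
    fnet: np.ndarray
    power: np.ndarray
    model: str
    system_mass: float

    def __post_init__(self):
        n = len(self.t)
        for name in ("vt", "at", "fr", "fnet", "power"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.model not in {"AF", "CRF"}:
            raise ValueError(f"model must be 'AF' or 'CRF', got {self.model!r}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "v_mps": self.vt,
                "a_mps2": self.at,
                "fr_n": self.fr,
                "fnet_n": self.fnet,
                "p_w": self.power,
                "model": self.model,
            }
        )


def net_force_trace(
    fit: MonoExpFit,
    system: AthleteChairSystem,
    env: EnvironmentConditions,
    model: str = "CRF",
    t: np.ndarray | None = None,
    strict_freebody: bool = False,
) -> ForceTrace:
    """Evaluate the net horizontal force along a fitted sprint.

    Velocity and acceleration come from the fitted mono-exponential model;
    the chosen resistive model supplies FR, and FNet = m*a + FR.  When no
    time grid is given, 1000 points spanning five time constants from the
    fitted onset are used (velocity then reaches >99 % of Vmax).
    """
    if t is None:
        t = np.linspace(fit.t0, fit.t0 + 5.0 * fit.tau, 1000)
    t = np.asarray(t, dtype=float)
    vt = np.asarray(model_velocity(fit, t), dtype=float)
    at = np.asarray(model_acceleration(fit, t), dtype=float)
    m = system.system_mass

    if model == "AF":
        params = AirFrictionParams.from_system_env(system, env)
        fr = af_resistive_force(vt, params.k, params.vwind)
    elif model == "CRF":
        mu = dynamic_friction_mu(at, vt, m, strict_freebody=strict_freebody)
        fr = crf_resistive_force(mu, m)
    else:
        raise ValueError(f"model must be 'AF' or 'CRF', got {model!r}")

    fnet = m * at + fr
    return ForceTrace(
        t=t, vt=vt, at=at, fr=np.asarray(fr), fnet=fnet, power=fnet * vt,
        model=model, system_mass=m,
    )
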