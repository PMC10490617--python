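"""Mono-exponential sprint velocity model and its least-squares fit.

The model is

    V(t) = Vmax * (1 - exp(-(t - t0) / tau))

with plateau velocity Vmax (m/s), acceleration time constant tau (s) and a
small onset offset t0 (s) absorbing threshold-crossing and filter-transient
shifts.  Differentiating gives the acceleration

    a(t) = (Vmax / tau) * exp(-(t - t0) / tau)

which satisfies the identity a(t) * tau + V(t) = Vmax for all t.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateRegressionError, FitFailureError
from .kinematics import SprintKinematics

# physically motivated parameter bounds: plateau speed and time constant
# of an all-out wheelchair sprint
VMAX_BOUNDS = (0.5, 15.0)
TAU_BOUNDS = (0.05, 10.0)
T0_BOUNDS = (-0.5, 0.5)
MAX_RESTARTS = 5


@dataclass
class MonoExpFit:
    """Fitted sprint-model parameters plus goodness of fit."""

    vmax: float
    tau: float
    t0: float
    rmse: float
    r2: float

    def __post_init__(self):
        if not self.vmax > 0:
            raise ValueError(f"vmax must be positive, got {self.vmax}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def model_velocity(fit: MonoExpFit, t) -> np.ndarray | float:
    """Modelled velocity V(t) = Vmax*(1 - exp(-(t - t0)/tau))."""
    t = np.asarray(t, dtype=float)
    out = fit.vmax * (1.0 - np.exp(-(t - fit.t0) / fit.tau))
    return out if out.ndim else float(out)


def model_acceleration(fit: MonoExpFit, t) -> np.ndarray | float:
    """Modelled acceleration a(t) = (Vmax/tau)*exp(-(t - t0)/tau)."""
    t = np.asarray(t, dtype=float)
    out = (fit.vmax / fit.tau) * np.exp(-(t - fit.t0) / fit.tau)
    return out if out.ndim else float(out)


def goodness_of_fit(measured, modelled) -> tuple[float, float]:
    """Root-mean-square error and coefficient of determination.

    r2 = 1 - SS_res / SS_tot about the measured mean; a zero-variance
    measured series makes r2 undefined and raises.
    """
    measured = np.asarray(measured, dtype=float)
    modelled = np.asarray(modelled, dtype=float)
    if measured.shape != modelled.shape or len(measured) < 2:
        raise ValueError("series must have equal length >= 2")
    resid = measured - modelled
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateRegressionError("measured series has zero variance; r2 undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return rmse, r2


def _residuals(params, t, v):
    vmax, tau, t0 = params
    return vmax * (1.0 - np.exp(-(t - t0) / tau)) - v


def fit_monoexponential(kin: SprintKinematics, seed: int = 0) -> MonoExpFit:
    """Bounded nonlinear least-squares fit of the sprint model.

    Initial values: Vmax from the observed maximum, tau from the time to
    reach 63.2 % of it, t0 = 0.  On solver failure the initial point is
    jittered (deterministically from ``seed``) up to 5 times before a
    :class:`FitFailureError` carrying diagnostics is raised.
    """
    t = np.asarray(kin.time, dtype=float)
    v = np.asarray(kin.velocity, dtype=float)
    if len(t) < 10:
        raise ValueError(f"need >= 10 samples to fit, got {len(t)}")
    vrange = float(v.max() - v.min())
    if vrange <= 0.5:
        raise DegenerateRegressionError(
            f"velocity range {vrange:.3f} m/s too small for a sprint fit"
        )

    vmax0 = float(v.max())
    above = np.flatnonzero(v >= 0.632 * vmax0)
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else 1.0
    x0 = np.array([vmax0, tau0, 0.0])
    lo = np.array([VMAX_BOUNDS[0], TAU_BOUNDS[0], T0_BOUNDS[0]])
    hi = np.array([VMAX_BOUNDS[1], TAU_BOUNDS[1], T0_BOUNDS[1]])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    rng = np.random.default_rng(seed)
    last_msg = ""
    for attempt in range(MAX_RESTARTS + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.uniform(0.7, 1.3, size=3) + rng.uniform(-0.05, 0.05, size=3),
            lo + 1e-9,
            hi - 1e-9,
        )
        res = least_squares(
            _residuals, start, args=(t, v), bounds=(lo, hi), ftol=1e-10, xtol=1e-12
        )
        if res.success:
            vmax, tau, t0 = res.x
            modelled = _residuals(res.x, t, v) + v
            rmse, r2 = goodness_of_fit(v, modelled)
            return MonoExpFit(vmax=float(vmax), tau=float(tau), t0=float(t0), rmse=rmse, r2=r2)
        last_msg = res.message
    raise FitFailureError(
        "mono-exponential fit failed to converge",
        diagnostics={"message": last_msg, "x0": x0.tolist(), "n": len(t)},
    )
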