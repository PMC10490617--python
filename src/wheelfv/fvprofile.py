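"""Force-velocity profile outcome measures from a net-force trace.

A sprint's force-velocity relationship is summarized by an ordinary
least-squares line fitted to net force versus velocity over the modelled
sprint.  From the line's intercept F0 (N) and slope (N·s/m):

* V0 = -F0/slope — theoretical maximum velocity (m/s), the velocity-axis
  intercept;
* Pmax = F0*V0/4 — maximal power (W) of the linear profile;
* FV slope — the slope normalized per kilogram of system mass
  (N·s/m/kg), the conventional between-athlete comparison scale;
* DRF — decrease ratio of force (%·s/m): the horizontal force expressed
  as a percentage of the total force magnitude,
  RF = 100 * FNet / sqrt(FNet^2 + (m*g)^2), regressed on velocity.  More
  negative DRF means mechanical effectiveness declines faster with speed.

The instantaneous power maximum max(FNet*V) is kept as a secondary
diagnostic; on a well-behaved sprint it stays within ~15 % of F0*V0/4.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateRegressionError
from .forces import G, ForceTrace
from .ingest import AthleteChairSystem


@dataclass
class FVProfile:
    """The five outcome measures of one sprint under one resistive model."""

    f0: float
    v0: float
    pmax: float
    drf: float
    fv_slope: float
    slope_abs: float
    model: str
    system_mass: float
    pmax_instant: float = float("nan")
    fv_r2: float = float("nan")

    def __post_init__(self):
        if not self.f0 > 0:
            raise DegenerateRegressionError(f"F0 must be positive, got {self.f0}")
        if not self.slope_abs < 0:
            raise DegenerateRegressionError(
                f"FV slope must be negative, got {self.slope_abs}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def linear_fv_fit(trace: ForceTrace) -> tuple[float, float, float]:
    """OLS regression of net force on velocity.

    Returns ``(slope, intercept, r2)`` with slope in N·s/m and the
    intercept F0 in N.  All modelled points enter unweighted.
    """
    v = np.asarray(trace.vt, dtype=float)
    f = np.asarray(trace.fnet, dtype=float)
    if len(v) < 10:
        raise DegenerateRegressionError(f"need >= 10 points, got {len(v)}")
    if float(v.max() - v.min()) <= 0.5:
        raise DegenerateRegressionError("velocity range too small for an FV fit")
    res = stats.linregress(v, f)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def ratio_of_force_drf(trace: ForceTrace, system: AthleteChairSystem) -> float:
    """Decrease ratio of force: OLS slope of RF(%) versus velocity.

    RF = 100 * FNet / sqrt(FNet^2 + (m*g)^2), with m the system mass.
    """
    v = np.asarray(trace.vt, dtype=float)
    f = np.asarray(trace.fnet, dtype=float)
    if float(v.max() - v.min()) <= 0:
        raise DegenerateRegressionError("velocity has zero range; DRF undefined")
    mg = system.system_mass * G
    rf = 100.0 * f / np.sqrt(f**2 + mg**2)
    res = stats.linregress(v, rf)
    return float(res.slope)


def derive_profile(trace: ForceTrace, system: AthleteChairSystem) -> FVProfile:
    """All five outcome measures from one force trace."""
    slope, f0, r2 = linear_fv_fit(trace)
    if slope >= 0:
        raise DegenerateRegressionError(f"nonnegative FV slope {slope}; not a sprint profile")
    v0 = -f0 / slope
    pmax = f0 * v0 / 4.0
    m = system.system_mass
    return FVProfile(
        f0=f0,
        v0=v0,
        pmax=pmax,
        drf=ratio_of_force_drf(trace, system),
        fv_slope=slope / m,
        slope_abs=slope,
        model=trace.model,
        system_mass=m,
        pmax_instant=float(np.max(trace.power)),
        fv_r2=r2,
    )
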