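"""End-to-end convenience: gyroscope trace in, FV profiles out."""

from __future__ import annotations

import logging

import pandas as pd

from .cohort import build_cohort_table
from .forces import ForceTrace, net_force_trace
from .fvprofile import FVProfile, derive_profile
from .ingest import AthleteChairSystem, EnvironmentConditions, GyroTrace
from .kinematics import SprintKinematics, process_trace
from .monoexp import MonoExpFit, fit_monoexponential

logger = logging.getLogger(__name__)


def profile_sprint(
    trace: GyroTrace,
    system: AthleteChairSystem,
    env: EnvironmentConditions | None = None,
    models: tuple[str, ...] = ("AF", "CRF"),
    fit_seed: int = 0,
) -> tuple[SprintKinematics, MonoExpFit, dict[str, tuple[ForceTrace, FVProfile]]]:
    """Run one sprint through kinematics, model fit and both force models.

    Returns the cleaned kinematics, the mono-exponential fit, and a mapping
    from model tag to its (force trace, FV profile) pair.  The force trace
    is evaluated on the sprint's own 1000-point onset-to-peak grid.
    """
    env = env or EnvironmentConditions()
    kin = process_trace(trace, system.wheel_radius)
    fit = fit_monoexponential(kin, seed=fit_seed)
    out: dict[str, tuple[ForceTrace, FVProfile]] = {}
    for model in models:
        ft = net_force_trace(fit, system, env, model=model, t=kin.time)
        out[model] = (ft, derive_profile(ft, system))
    return kin, fit, out


def profile_cohort(
    sprints: list[tuple[AthleteChairSystem, str, GyroTrace]],
    env: EnvironmentConditions | None = None,
    models: tuple[str, ...] = ("AF", "CRF"),
    fit_seed: int = 0,
    on_error: str = "skip",
) -> pd.DataFrame:
    """Profile every sprint of a cohort into one tidy table.

    One row per sprint x model with the five outcome measures and fit
    quality.  With ``on_error='skip'`` a failing sprint is logged and
    dropped; with ``'raise'`` the first failure propagates.
    """
    records = []
    for system, trial_id, trace in sprints:
        try:
            _, fit, results = profile_sprint(
                trace, system, env, models=models, fit_seed=fit_seed
            )
        except Exception:
            if on_error == "raise":
                raise
            logger.exception("sprint %s/%s failed; skipped", system.athlete_id, trial_id)
            continue
        for model, (_, prof) in results.items():
            records.append(
                {
                    "athlete_id": system.athlete_id,
                    "trial": trial_id,
                    "model": model,
                    "pmax": prof.pmax,
                    "f0": prof.f0,
                    "drf": prof.drf,
                    "v0": prof.v0,
                    "fv_slope": prof.fv_slope,
                    "rmse": fit.rmse,
                    "r2": fit.r2,
                    "vmax_fit": fit.vmax,
                    "tau_fit": fit.tau,
                }
            )
    if not records:
        raise RuntimeError("no sprint could be profiled")
    return build_cohort_table(records)
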