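"""Cohort aggregation, paired model comparison and reference adjustment.

A cohort table holds one row per athlete x trial x resistive model with
the five outcome measures plus fit quality.  Comparisons between the AF
and CRF resistive models use two-sided paired t-tests on per-sprint
differences; descriptives are reported as mean +/- SEM (sample sd / sqrt n).
No multiple-testing correction is applied across the five metrics.

Published force-velocity values from other wheelchair sprint studies can
be carried as :class:`ReferenceValues` and adjusted to a common maximum
velocity along their own FV line — a best-effort reconstruction for
qualitative comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, UndefinedTestError

#: Outcome measures carried through cohort tables.
METRICS = ("pmax", "f0", "drf", "v0", "fv_slope")

_REQUIRED_COLS = {"athlete_id", "trial", "model", *METRICS}


def build_cohort_table(profiles: list[dict]) -> pd.DataFrame:
    """Assemble per-sprint profile records into a cohort DataFrame.

    Each record needs athlete_id, trial, model and the five metrics;
    rmse/r2 columns are carried through when present.  Duplicate
    (athlete, trial, model) rows are rejected.
    """
    df = pd.DataFrame(profiles)
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise ComparisonError(f"cohort records missing columns {sorted(missing)}")
    if df.duplicated(subset=["athlete_id", "trial", "model"]).any():
        raise ComparisonError("duplicate (athlete, trial, model) rows in cohort table")
    return df


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of each metric per resistive model.

    SEM = sample sd (n-1 denominator) / sqrt(n); NaN when n == 1.
    """
    if len(table) == 0:
        raise ComparisonError("empty cohort table")
    rows = []
    for model, grp in table.groupby("model"):
        for metric in METRICS:
            x = grp[metric].to_numpy(dtype=float)
            n = len(x)
            sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {"model": model, "metric": metric, "mean": float(np.mean(x)),
                 "sem": sem, "n": n}
            )
    return pd.DataFrame(rows)


def paired_model_test(table: pd.DataFrame, metric: str) -> tuple[float, float, float]:
    """Two-sided paired t-test of CRF vs AF on one metric.

    Rows are paired by (athlete_id, trial); differences are CRF - AF.
    Returns ``(t, p, mean_difference)``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    wide = table.pivot_table(
        index=["athlete_id", "trial"], columns="model", values=metric
    )
    if "AF" not in wide.columns or "CRF" not in wide.columns:
        raise ComparisonError("paired test needs both AF and CRF rows")
    wide = wide.dropna()
    if len(wide) < 3:
        raise UndefinedTestError(f"only {len(wide)} complete pairs; need >= 3")
    diff = (wide["CRF"] - wide["AF"]).to_numpy(dtype=float)
    if np.std(diff, ddof=1) == 0:
        raise UndefinedTestError("zero variance of paired differences; t undefined")
    t, p = stats.ttest_rel(wide["CRF"], wide["AF"])
    return float(t), float(p), float(diff.mean())


def compare_models(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired tests for every metric; one row each with a significance flag."""
    rows = []
    for metric in METRICS:
        try:
            t, p, d = paired_model_test(table, metric)
            rows.append({"metric": metric, "t": t, "p": p, "mean_diff_crf_minus_af": d,
                         "significant": p < alpha})
        except UndefinedTestError as exc:
            rows.append({"metric": metric, "t": float("nan"), "p": float("nan"),
                         "mean_diff_crf_minus_af": float("nan"),
                         "significant": False, "note": str(exc)})
    return pd.DataFrame(rows)


@dataclass
class ReferenceValues:
    """Published cohort-mean FV values from another study (mean, SEM)."""

    source: str
    pmax: float
    f0: float
    v0: float
    fv_slope: float | None = None
    pmax_sem: float = float("nan")
    f0_sem: float = float("nan")
    v0_sem: float = float("nan")
    fv_slope_sem: float = float("nan")
    note: str = ""


#: Ergometer dynamometry of experienced wheelchair rugby athletes
#: (Janssen et al. 2023), cohort means.
REFERENCE_JANSSEN = ReferenceValues(
    source="Janssen et al. (2023), wheelchair rugby ergometer",
    pmax=307.174, f0=256.056, v0=4.700, fv_slope=-0.728,
    pmax_sem=42.15, f0_sem=24.75, v0_sem=0.33, fv_slope_sem=0.16,
)

#: Court/ergometer sprints of national-team wheelchair basketball athletes
#: (Brassart et al. 2023), cohort means; no published slope.
REFERENCE_BRASSART = ReferenceValues(
    source="Brassart et al. (2023), wheelchair basketball",
    pmax=277.6, f0=244.0, v0=4.700, fv_slope=None,
    pmax_sem=25.15, f0_sem=16.37, v0_sem=0.15,
)


def velocity_correct_reference(
    ref: ReferenceValues, target_v0: float, system_mass: float
) -> ReferenceValues:
    """Adjust published reference values to a common maximum velocity.

    The reference cohort's F0 is recomputed along its own FV line at the
    target V0: F0' = -slope_per_kg * m * V0_target, then Pmax' = F0'*V0'/4.
    This is a best-effort reconstruction for qualitative comparison; SEMs
    are not propagated.
    """
    if ref.fv_slope is None:
        raise ComparisonError(f"{ref.source}: no FV slope published; cannot correct")
    if not target_v0 > 0:
        raise ValueError("target_v0 must be positive")
    f0_corr = -ref.fv_slope * system_mass * target_v0
    return replace(
        ref,
        v0=target_v0,
        f0=f0_corr,
        pmax=f0_corr * target_v0 / 4.0,
        f0_sem=float("nan"),
        pmax_sem=float("nan"),
        v0_sem=float("nan"),
        note="best-effort reconstruction: velocity-corrected along the reference FV line",
    )
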