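"""Figure generation: measured-vs-modelled velocity, FV lines, metric panels.

Figures are output artifacts only; no number in the pipeline is ever read
back from a plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fvprofile import FVProfile
from .kinematics import SprintKinematics
from .monoexp import MonoExpFit, model_velocity

_MODEL_COLORS = {"AF": "tab:blue", "CRF": "tab:red"}


def plot_velocity_fit(kin: SprintKinematics, fit: MonoExpFit, path: str | Path) -> Path:
    """Measured velocity against the fitted mono-exponential curve."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(kin.time, kin.velocity, lw=1, color="0.4", label="measured (IMU)")
    ax.plot(kin.time, model_velocity(fit, kin.time), lw=2, color="tab:red",
            label=f"model: Vmax={fit.vmax:.2f} m/s, tau={fit.tau:.2f} s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("velocity (m/s)")
    ax.legend(frameon=False)
    ax.set_title(f"rmse={fit.rmse:.3f} m/s, r2={fit.r2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_fv_profiles(profiles: list[FVProfile], path: str | Path) -> Path:
    """Individual and mean FV lines per resistive model."""
    fig, ax = plt.subplots(figsize=(6, 4))
    by_model: dict[str, list[FVProfile]] = {}
    for p in profiles:
        by_model.setdefault(p.model, []).append(p)
    for model, plist in sorted(by_model.items()):
        c = _MODEL_COLORS.get(model, "0.5")
        for p in plist:
            v = np.linspace(0, p.v0, 50)
            ax.plot(v, p.f0 + p.slope_abs * v, color=c, alpha=0.25, lw=0.8)
        f0m = np.mean([p.f0 for p in plist])
        sm = np.mean([p.slope_abs for p in plist])
        v = np.linspace(0, -f0m / sm, 50)
        ax.plot(v, f0m + sm * v, color=c, lw=2.5, label=f"{model} mean")
    ax.set_xlabel("velocity (m/s)")
    ax.set_ylabel("net force (N)")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_metric_panels(table: pd.DataFrame, path: str | Path) -> Path:
    """Per-model distributions of Pmax, F0, V0 and FV slope."""
    metrics = ["pmax", "f0", "v0", "fv_slope"]
    fig, axes = plt.subplots(1, 4, figsize=(12, 3.2))
    for ax, metric in zip(axes, metrics):
        for i, (model, grp) in enumerate(sorted(table.groupby("model"))):
            x = grp[metric].to_numpy(dtype=float)
            c = _MODEL_COLORS.get(model, "0.5")
            jitter = (np.arange(len(x)) % 7 - 3) * 0.01
            ax.scatter(np.full(len(x), i) + jitter, x, s=12, color=c, alpha=0.6)
            ax.hlines(np.mean(x), i - 0.2, i + 0.2, color=c, lw=2)
        ax.set_xticks(range(table["model"].nunique()))
        ax.set_xticklabels(sorted(table["model"].unique()))
        ax.set_title(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
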