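"""Reading and validating gyroscope CSV files and athlete/chair metadata.

Two CSV dialects are supported for single-axis gyroscope traces:

``generic``
    The package's canonical interchange format: two columns,
    ``time_s`` (seconds) and ``gyro_y_dps`` (angular rate about the wheel
    axle, degrees per second).  Files written by
    :func:`write_gyro_csv` round-trip bit-for-bit.

``xsens_dot``
    Best-effort mapping of the Xsens DOT app export: a ``SampleTimeFine``
    column (microsecond ticks) and a ``Gyr_Y`` column in deg/s.  The vendor
    does not document a single stable export schema, so this reader only
    promises to handle files with those two columns present.

Ingestion never alters sample values; it only drops rows containing NaN
(and counts them) and rebases the time axis to start at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyTraceError, FormatError, MetadataError, OrderingError

logger = logging.getLogger(__name__)

#: Nominal sampling rate of the wheel-hub IMU, Hz.
NOMINAL_FS = 60.0


@dataclass
class GyroTrace:
    """Raw single-axis angular-rate time series from a wheel-hub gyroscope.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing, rebased to start at 0.
    gyro_y : ndarray
        Angular rate about the wheel axle in deg/s. Sign depends on which
        hub the sensor is mounted on; downstream processing fixes
        orientation.
    fs : float
        Nominal sampling frequency in Hz (60 for the wheel-hub IMU).
    device_id : str
        Free-text device identifier.
    dropped_rows : int
        Number of rows discarded during ingestion because of NaN values.
    """

    time: np.ndarray
    gyro_y: np.ndarray
    fs: float = NOMINAL_FS
    device_id: str = ""
    dropped_rows: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.gyro_y = np.asarray(self.gyro_y, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.gyro_y.shape:
            raise FormatError("time and gyro_y must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise EmptyTraceError(f"trace has {len(self.time)} valid samples; need >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise OrderingError("time stamps are not strictly increasing")
        if np.isnan(self.time).any() or np.isnan(self.gyro_y).any():
            raise FormatError("NaN values must be dropped before constructing a GyroTrace")
        if not self.fs > 0:
            raise MetadataError(f"sampling frequency must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return float(self.time[-1] - self.time[0])


@dataclass
class AthleteChairSystem:
    """Masses and geometry of one athlete-plus-wheelchair system.

    The net-force equation uses the combined system mass m; the
    air-friction model additionally needs the seated (chair) stature H for
    the surface-area estimate and the wheel radius for converting wheel
    angular rate to translational velocity.
    """

    system_mass: float
    stature: float
    wheel_radius: float
    body_mass: float | None = None
    chair_mass: float | None = None
    athlete_id: str = ""

    def __post_init__(self):
        # seated stature quoted in cm is a common field-sheet slip;
        # anything over 3 m is physically impossible for a seated athlete
        if self.stature > 3.0:
            warnings.warn(
                f"stature {self.stature} > 3 m; interpreting as centimetres "
                f"and dividing by 100",
                stacklevel=2,
            )
            self.stature = self.stature / 100.0
        for name in ("system_mass", "stature", "wheel_radius"):
            v = getattr(self, name)
            if not v > 0:
                raise MetadataError(f"{name} must be strictly positive, got {v}")
        if not 0.1 <= self.wheel_radius <= 0.5:
            raise MetadataError(
                f"wheel_radius {self.wheel_radius} m outside plausible range [0.1, 0.5]"
            )
        if self.body_mass is not None and self.chair_mass is not None:
            if self.body_mass <= 0 or self.chair_mass <= 0:
                raise MetadataError("body_mass and chair_mass must be strictly positive")
            total = self.body_mass + self.chair_mass
            if abs(total - self.system_mass) > 0.01:
                raise MetadataError(
                    f"system_mass {self.system_mass} != body+chair {total:.2f} (tol 0.01 kg)"
                )

    @classmethod
    def from_parts(
        cls,
        body_mass: float,
        chair_mass: float,
        stature: float,
        wheel_radius: float,
        athlete_id: str = "",
    ) -> "AthleteChairSystem":
        return cls(
            system_mass=body_mass + chair_mass,
            stature=stature,
            wheel_radius=wheel_radius,
            body_mass=body_mass,
            chair_mass=chair_mass,
            athlete_id=athlete_id,
        )


@dataclass
class EnvironmentConditions:
    """Ambient conditions entering the air-density formula.

    ``pressure`` is expressed in the formula's own units, where 760 is the
    reference value (a mmHg convention); see
    :func:`wheelfv.forces.pressure_from_hpa` for converting a barometer
    reading in hPa.  Indoor sprints assume zero wind.
    """

    temperature: float = 20.0
    pressure: float = 760.0
    wind_velocity: float = 0.0

    def __post_init__(self):
        if self.temperature <= -273.0:
            raise MetadataError(f"temperature {self.temperature} degC below absolute zero")
        if not self.pressure > 0:
            raise MetadataError(f"pressure must be positive, got {self.pressure}")


# column names per dialect: (time column, gyro column)
_DIALECTS = {
    "generic": ("time_s", "gyro_y_dps"),
    "xsens_dot": ("SampleTimeFine", "Gyr_Y"),
}


def read_gyro_csv(path: str | Path, dialect: str = "generic") -> GyroTrace:
    """Read a single-axis gyroscope trace from CSV.

    Parameters
    ----------
    path : path-like
        CSV file to read.
    dialect : {"generic", "xsens_dot"}
        Column convention; see the module docstring.

    Returns
    -------
    GyroTrace
        Time rebased to start at 0 s; ``dropped_rows`` records how many
        NaN-containing rows were discarded.  The sampling frequency is
        inferred from the median time step; if it deviates from the nominal
        60 Hz by more than 1 % a warning is emitted (consumer IMU clocks
        jitter) but the trace is still returned.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    time_col, gyro_col = _DIALECTS[dialect]

    df = pd.read_csv(path, float_precision="round_trip")
    missing = {time_col, gyro_col} - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)} for dialect {dialect!r}")

    sub = df[[time_col, gyro_col]].apply(pd.to_numeric, errors="coerce")
    n_raw = len(sub)
    sub = sub.dropna()
    dropped = n_raw - len(sub)
    if len(sub) < 2:
        raise EmptyTraceError(f"{path.name}: only {len(sub)} valid rows after dropping NaN")

    t = sub[time_col].to_numpy(dtype=float)
    g = sub[gyro_col].to_numpy(dtype=float)
    if dialect == "xsens_dot":
        t = t / 1e6  # SampleTimeFine ticks are microseconds
    if np.any(np.diff(t) <= 0):
        raise OrderingError(f"{path.name}: time column is not strictly increasing")
    t = t - t[0]

    fs = 1.0 / float(np.median(np.diff(t)))
    if abs(fs - NOMINAL_FS) / NOMINAL_FS > 0.01:
        warnings.warn(
            f"{path.name}: inferred sampling rate {fs:.2f} Hz deviates >1% from "
            f"nominal {NOMINAL_FS:.0f} Hz",
            stacklevel=2,
        )
    if dropped:
        logger.info("%s: dropped %d NaN row(s) of %d", path.name, dropped, n_raw)

    return GyroTrace(time=t, gyro_y=g, fs=fs, device_id=path.stem, dropped_rows=dropped)


def write_gyro_csv(trace: GyroTrace, path: str | Path) -> Path:
    """Write a trace in the generic dialect with full float precision.

    Re-reading the file reproduces ``time`` and ``gyro_y`` bit-for-bit.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,gyro_y_dps\n")
        for t, g in zip(trace.time, trace.gyro_y):
            fh.write(f"{float(t)!r},{float(g)!r}\n")
    return path


_META_DEFAULTS = {"temperature_c": 20.0, "pressure": 760.0, "wind_velocity_mps": 0.0}


def read_metadata(path: str | Path) -> tuple[AthleteChairSystem, EnvironmentConditions]:
    """Read athlete/chair and environment metadata from a YAML or CSV file.

    YAML files hold a flat mapping; CSV files hold two columns ``key,value``.
    Required keys: ``stature_m``, ``wheel_radius_m`` and either
    ``system_mass_kg`` or both ``body_mass_kg`` and ``chair_mass_kg``.
    Optional: ``temperature_c`` (default 20), ``pressure`` (formula units,
    default 760), ``wind_velocity_mps`` (default 0), ``athlete_id``.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"{path.name}: expected a YAML mapping")
    else:
        df = pd.read_csv(path)
        if not {"key", "value"} <= set(df.columns):
            raise FormatError(f"{path.name}: metadata CSV needs columns 'key','value'")
        raw = dict(zip(df["key"], df["value"]))

    def fget(key, default=None):
        if key in raw and raw[key] is not None:
            return float(raw[key])
        return default

    body = fget("body_mass_kg")
    chair = fget("chair_mass_kg")
    system = fget("system_mass_kg")
    if system is None:
        if body is None or chair is None:
            raise MetadataError(
                f"{path.name}: need system_mass_kg or both body_mass_kg and chair_mass_kg"
            )
        system = body + chair
    stature = fget("stature_m")
    radius = fget("wheel_radius_m")
    if stature is None or radius is None:
        raise MetadataError(f"{path.name}: stature_m and wheel_radius_m are required")

    system_rec = AthleteChairSystem(
        system_mass=system,
        stature=stature,
        wheel_radius=radius,
        body_mass=body,
        chair_mass=chair,
        athlete_id=str(raw.get("athlete_id", path.stem)),
    )
    for key, default in _META_DEFAULTS.items():
        if key not in raw:
            logger.info("%s: %s not given, defaulting to %s", path.name, key, default)
    env = EnvironmentConditions(
        temperature=fget("temperature_c", _META_DEFAULTS["temperature_c"]),
        pressure=fget("pressure", _META_DEFAULTS["pressure"]),
        wind_velocity=fget("wind_velocity_mps", _META_DEFAULTS["wind_velocity_mps"]),
    )
    return system_rec, env
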