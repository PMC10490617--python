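"""From wheel angular rate to a cleaned translational-velocity trace.

The processing pipeline mirrors standard sprint-kinematics practice for a
wheel-hub gyroscope and runs in a fixed order:

1. onset detection — first sample whose absolute angular rate exceeds
   10 deg/s (the wheel has clearly started turning);
2. unit conversion — deg/s to rad/s, times wheel radius, gives
   translational velocity, with the sign fixed so that forward motion is
   positive regardless of which hub the sensor was mounted on;
3. zero-phase low-pass filtering — 5th-order 4.5 Hz Butterworth applied
   forward and backward, removing push-cycle and sensor noise without
   phase lag (lag would bias the acceleration time constant);
4. crop to peak — the sprint model describes the acceleration phase only,
   so the trace is cut at the global maximum velocity;
5. time normalization — linear resampling onto 1000 uniformly spaced
   points between onset and peak.  The time axis stays in real seconds so
   the fitted time constant keeps physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DegenerateSprintError,
    FilterLengthError,
    NoSprintDetectedError,
)
from .ingest import GyroTrace

#: Sprint-onset threshold on |angular rate|, deg/s.
ONSET_THRESHOLD_DPS = 10.0
#: Low-pass cutoff applied to translational velocity, Hz.
FILTER_CUTOFF_HZ = 4.5
#: Butterworth filter order.
FILTER_ORDER = 5
#: Number of samples after time normalization.
N_NORMALIZED = 1000

DEG2RAD = np.pi / 180.0


@dataclass
class SprintKinematics:
    """Cleaned translational-velocity trace for one sprint.

    ``time`` is rebased so 0 s is the detected onset; if ``resampled`` is
    set it holds exactly 1000 uniformly spaced points spanning
    ``[0, t_peak]``.
    """

    time: np.ndarray
    velocity: np.ndarray
    angular_velocity: np.ndarray
    fs: float
    provenance: set = field(default_factory=set)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def t_peak(self) -> float:
        return float(self.time[-1])


def detect_onset(trace: GyroTrace, threshold: float = ONSET_THRESHOLD_DPS) -> int:
    """Index of the first sample with ``|gyro_y| > threshold``.

    The absolute value is used because mounting the sensor on the opposite
    hub negates the whole trace.
    """
    idx = np.flatnonzero(np.abs(trace.gyro_y) > threshold)
    if idx.size == 0:
        raise NoSprintDetectedError(
            f"no sample exceeds {threshold} deg/s; trace contains no sprint"
        )
    return int(idx[0])


def angular_to_translational(
    gyro_dps: np.ndarray, wheel_radius: float, fix_orientation: bool = True
) -> np.ndarray:
    """Convert wheel angular rate (deg/s) to translational velocity (m/s).

    v = (pi/180) * omega_dps * r.  When ``fix_orientation`` is set and the
    trace's dominant sign is negative (sensor on the left hub), the whole
    series is negated so forward motion is positive.
    """
    if not wheel_radius > 0:
        raise ValueError(f"wheel_radius must be positive, got {wheel_radius}")
    v = DEG2RAD * np.asarray(gyro_dps, dtype=float) * wheel_radius
    if fix_orientation and np.sum(v) < 0:
        v = -v
    return v


def lowpass_velocity(
    v: np.ndarray,
    fs: float,
    order: int = FILTER_ORDER,
    fc: float = FILTER_CUTOFF_HZ,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter of a velocity series.

    Forward-backward filtering doubles the effective order's attenuation
    and has exactly unit DC gain, so plateau velocity is untouched.
    """
    if fs <= 2 * fc:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cutoff {fc} Hz")
    v = np.asarray(v, dtype=float)
    b, a = signal.butter(order, fc / (fs / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(v) <= padlen:
        raise FilterLengthError(
            f"series of length {len(v)} too short for zero-phase filtering (need > {padlen})"
        )
    return signal.filtfilt(b, a, v)


def crop_to_peak(v: np.ndarray) -> np.ndarray:
    """Cut the series at its global maximum, inclusive; ties break earliest."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise DegenerateSprintError("empty velocity series")
    imax = int(np.argmax(v))
    if imax == 0:
        raise DegenerateSprintError("maximum velocity at the first sample; not a sprint")
    return v[: imax + 1]


def time_normalize(
    t: np.ndarray, v: np.ndarray, n: int = N_NORMALIZED
) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling onto ``n`` uniform points over ``[t[0], t[-1]]``.

    Real time in seconds is retained; only the sample count is normalized.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 2:
        raise DegenerateSprintError("need at least 2 samples to resample")
    tu = np.linspace(t[0], t[-1], n)
    return tu, np.interp(tu, t, v)


def process_trace(
    trace: GyroTrace,
    wheel_radius: float,
    threshold: float = ONSET_THRESHOLD_DPS,
    fc: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
    n: int = N_NORMALIZED,
) -> SprintKinematics:
    """Full kinematics pipeline: convert, filter, crop, resample.

    Orientation fixing and filtering operate on the whole trace (the filter
    sees maximal context, keeping edge transients away from the sprint);
    cropping then selects onset-to-peak and rebases time to 0 at onset.
    """
    onset = detect_onset(trace, threshold=threshold)
    omega = DEG2RAD * trace.gyro_y
    if np.sum(omega) < 0:  # sensor on the opposite hub
        omega = -omega
    v_full = omega * wheel_radius
    v_filt = lowpass_velocity(v_full, trace.fs, order=order, fc=fc)

    seg = v_filt[onset:]
    cropped = crop_to_peak(seg)
    t_seg = trace.time[onset : onset + len(cropped)] - trace.time[onset]
    tu, vu = time_normalize(t_seg, cropped, n=n)
    omega_u = np.interp(tu, t_seg, omega[onset : onset + len(cropped)])
    return SprintKinematics(
        time=tu,
        velocity=vu,
        angular_velocity=omega_u,
        fs=trace.fs,
        provenance={"raw", "filtered", "cropped", "resampled"},
    )


def export_kinematics_csv(kin: SprintKinematics, path) -> None:
    """Write the cleaned velocity trace as ``t_s,v_mps`` CSV."""
    import pandas as pd

    pd.DataFrame({"t_s": kin.time, "v_mps": kin.velocity}).to_csv(path, index=False)
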