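import numpy as np
import pytest

import wheelfv as w


@pytest.fixture
def rugby_system() -> w.AthleteChairSystem:
    """Cohort-mean athlete: 69.51 kg body + 18.15 kg chair, 1.1905 m seated."""
    return w.AthleteChairSystem.from_parts(
        body_mass=69.51, chair_mass=18.15, stature=1.1905, wheel_radius=0.30,
        athlete_id="mean",
    )


@pytest.fixture
def indoor_env() -> w.EnvironmentConditions:
    return w.EnvironmentConditions(temperature=20.0, pressure=760.0, wind_velocity=0.0)


@pytest.fixture
def clean_sprint_trace() -> w.GyroTrace:
    """Noise-free synthetic sprint: Vmax 4.6 m/s, tau 1.2 s, r 0.30 m, 8 s."""
    cfg = w.SyntheticSprintConfig(
        vmax=4.6, tau=1.2, wheel_radius=0.30, duration=8.0, gyro_noise_sd=0.0, seed=1
    )
    return w.simulate_sprint(cfg)


@pytest.fixture
def clean_fit(clean_sprint_trace) -> w.MonoExpFit:
    kin = w.process_trace(clean_sprint_trace, 0.30)
    return w.fit_monoexponential(kin)


def make_noisy_fit(seed: int, vmax=4.6, tau=1.4, radius=0.28, noise=100.0) -> w.MonoExpFit:
    cfg = w.SyntheticSprintConfig(
        vmax=vmax, tau=tau, wheel_radius=radius, duration=8.0,
        gyro_noise_sd=noise, seed=seed,
    )
    kin = w.process_trace(w.simulate_sprint(cfg), radius)
    return w.fit_monoexponential(kin)


@pytest.fixture
def ideal_kinematics() -> w.SprintKinematics:
    """Analytic mono-exponential velocity sampled directly (no gyro stage)."""
    t = np.linspace(0.0, 8.0, 1000)
    v = 4.6 * (1.0 - np.exp(-t / 1.2))
    return w.SprintKinematics(
        time=t, velocity=v, angular_velocity=v / 0.30, fs=60.0,
        provenance={"resampled"},
    )
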