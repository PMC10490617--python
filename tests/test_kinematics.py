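import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wheelfv as w
from wheelfv.errors import DegenerateSprintError, FilterLengthError, NoSprintDetectedError
from wheelfv.kinematics import crop_to_peak, lowpass_velocity, time_normalize


def trace_from(gyro, fs=60.0):
    g = np.asarray(gyro, dtype=float)
    return w.GyroTrace(time=np.arange(len(g)) / fs, gyro_y=g, fs=fs)


class TestOnset:
    def test_first_exceedance(self):
        assert w.detect_onset(trace_from([0, 5, 9, 11, 40])) == 3

    def test_all_below_threshold_errors(self):
        with pytest.raises(NoSprintDetectedError):
            w.detect_onset(trace_from([0, 3, 9, 10]))

    def test_negative_mount_uses_absolute_value(self):
        assert w.detect_onset(trace_from([-3, -12, -80])) == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-500, 500, allow_nan=False), min_size=2, max_size=60))
    def test_matches_brute_force_first_index(self, gyro):
        tr = trace_from(gyro)
        expected = next((i for i, g in enumerate(gyro) if abs(g) > 10.0), None)
        if expected is None:
            with pytest.raises(NoSprintDetectedError):
                w.detect_onset(tr)
        else:
            assert w.detect_onset(tr) == expected


class TestUnitConversion:
    @pytest.mark.parametrize(
        "dps, radius, expected",
        [(180.0, 1.0, np.pi), (0.0, 0.3, 0.0), (573.0, 0.30, 3.00022)],
    )
    def test_known_values(self, dps, radius, expected):
        v = w.angular_to_translational(np.array([dps, dps]), radius)
        assert v[0] == pytest.approx(expected, abs=1e-4)

    def test_orientation_flip_for_left_hub(self):
        v = w.angular_to_translational(np.array([-100.0, -200.0]), 0.3)
        assert np.all(v > 0)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        v = np.full(200, 2.0)
        assert lowpass_velocity(v, 60.0) == pytest.approx(v)

    def test_stopband_9hz_attenuated(self):
        t = np.arange(0, 10, 1 / 60)
        out = lowpass_velocity(np.sin(2 * np.pi * 9 * t), 60.0)
        # squared 5th-order magnitude at 2x cutoff is (1+2^10)^-1 ~ 1e-3
        assert np.abs(out[60:-60]).max() <= 0.01

    def test_passband_0p1hz_preserved(self):
        t = np.arange(0, 30, 1 / 60)
        out = lowpass_velocity(np.sin(2 * np.pi * 0.1 * t), 60.0)
        assert np.abs(out[120:-120]).max() == pytest.approx(1.0, rel=0.01)

    def test_too_short_series(self):
        with pytest.raises(FilterLengthError):
            lowpass_velocity(np.ones(10), 60.0)

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(ValueError):
            lowpass_velocity(np.ones(100), 8.0)


class TestCropResample:
    def test_cut_at_argmax_inclusive(self):
        assert list(crop_to_peak(np.array([0, 1, 2, 3, 2, 1.0]))) == [0, 1, 2, 3]

    def test_monotone_rising_unchanged(self):
        v = np.arange(5.0)
        assert list(crop_to_peak(v)) == list(v)

    def test_tie_breaks_at_first_maximum(self):
        assert len(crop_to_peak(np.array([0, 1, 3, 2, 3.0]))) == 3

    def test_peak_at_start_is_degenerate(self):
        with pytest.raises(DegenerateSprintError):
            crop_to_peak(np.array([5.0, 1.0, 0.0]))

    def test_linear_ramp_interpolates_exactly(self):
        t = np.linspace(0, 3, 181)
        tu, vu = time_normalize(t, t)
        assert len(vu) == 1000
        assert np.max(np.abs(vu - tu)) < 1e-12

    def test_monoexp_interpolation_error_bound(self):
        t = np.arange(0, 6, 1 / 60)
        v = 4.6 * (1 - np.exp(-t / 1.2))
        tu, vu = time_normalize(t, v)
        exact = 4.6 * (1 - np.exp(-tu / 1.2))
        # analytic linear-interp bound: h^2 * max|v''| / 8 at 60 Hz
        bound = (1 / 60) ** 2 * (4.6 / 1.2**2) / 8
        assert np.max(np.abs(vu - exact)) <= bound


class TestPipeline:
    @pytest.mark.parametrize("sign", [1.0, -1.0], ids=["right-hub", "left-hub"])
    def test_noise_free_peak_preserved_either_mount(self, sign):
        cfg = w.SyntheticSprintConfig(vmax=4.6, tau=1.2, wheel_radius=0.30,
                                      duration=8.0, gyro_noise_sd=0.0, seed=1)
        tr = w.simulate_sprint(cfg)
        tr = w.GyroTrace(time=tr.time, gyro_y=sign * tr.gyro_y, fs=tr.fs)
        kin = w.process_trace(tr, 0.30)
        expected_peak = 4.6 * (1 - np.exp(-8.0 / 1.2))
        assert kin.n_samples == 1000
        assert kin.velocity.max() == pytest.approx(expected_peak, rel=0.005)
        assert np.all(np.diff(kin.time) > 0)

    def test_orientation_fix_makes_velocity_nonnegative(self):
        cfg = w.SyntheticSprintConfig(vmax=4.0, tau=1.4, wheel_radius=0.28,
                                      duration=8.0, gyro_noise_sd=100.0, seed=9)
        tr = w.simulate_sprint(cfg)
        flipped = w.GyroTrace(time=tr.time, gyro_y=-tr.gyro_y, fs=tr.fs)
        for t in (tr, flipped):
            kin = w.process_trace(t, 0.28)
            assert np.mean(kin.velocity >= 0) >= 0.99

    def test_export_csv(self, tmp_path, clean_sprint_trace):
        kin = w.process_trace(clean_sprint_trace, 0.30)
        out = tmp_path / "kin.csv"
        w.kinematics.export_kinematics_csv(kin, out)
        header = out.read_text().splitlines()[0]
        assert header == "t_s,v_mps"
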