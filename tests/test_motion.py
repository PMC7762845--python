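import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoqc import (
    BrainMask,
    MotionTrace,
    Volume4D,
    compute_dvars,
    compute_fd,
    dvars_outliers,
    fd_outliers,
)
from neoqc.motion import FrameSeries


def trace_with_step(t, frame, column, size):
    params = np.zeros((t, 6))
    params[frame:, column] = size
    return MotionTrace(params)


class TestFD:
    def test_constant_trace_gives_zeros(self):
        fd = compute_fd(MotionTrace(np.ones((8, 6))))
        np.testing.assert_array_equal(fd.values, np.zeros(8))

    def test_translation_step_is_sixth_of_step(self):
        # one 0.3 mm x-translation step: only 1 of 6 differences nonzero
        fd = compute_fd(trace_with_step(10, 4, column=3, size=0.3))
        assert fd.values[4] == pytest.approx(0.3 / 6)
        assert np.count_nonzero(fd.values) == 1

    def test_rotation_step_converts_to_arc_length(self):
        fd = compute_fd(trace_with_step(10, 4, column=0, size=0.01),
                        head_radius=50.0)
        assert fd.values[4] == pytest.approx(0.01 * 50 / 6)

    def test_sum_mode_is_six_times_mean_mode(self, rng):
        trace = MotionTrace(rng.normal(size=(20, 6)))
        mean = compute_fd(trace, mode="mean").values
        total = compute_fd(trace, mode="sum").values
        np.testing.assert_allclose(total, 6 * mean)

    def test_raw_mode_skips_rotation_conversion(self):
        fd = compute_fd(trace_with_step(6, 2, column=0, size=0.01),
                        convert_rotations=False)
        assert fd.values[2] == pytest.approx(0.01 / 6)

    def test_time_reversal_reverses_body(self, rng):
        trace = MotionTrace(rng.normal(size=(15, 6)))
        fwd = compute_fd(trace).values
        rev = compute_fd(MotionTrace(trace.params[::-1])).values
        np.testing.assert_allclose(rev[1:], fwd[1:][::-1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fd_always_nonnegative_and_zero_first(self, seed):
        params = np.random.default_rng(seed).normal(size=(12, 6))
        fd = compute_fd(MotionTrace(params))
        assert fd.values[0] == 0
        assert (fd.values >= 0).all()


class TestFDOutliers:
    def test_paper_default_threshold_flags_above_quarter_mm(self):
        flags = fd_outliers(FrameSeries(np.array([0.0, 0.1, 0.3])))
        np.testing.assert_array_equal(flags.flags, [False, False, True])
        assert flags.threshold == 0.25

    def test_exact_threshold_not_flagged(self):
        flags = fd_outliers(FrameSeries(np.array([0.0, 0.25, 0.2500001])))
        np.testing.assert_array_equal(flags.flags, [False, False, True])

    def test_zero_fd_never_flagged(self):
        assert fd_outliers(FrameSeries(np.zeros(10))).count == 0


class TestDVARS:
    def make_vol(self, series):
        """series: V x T list -> volume with a V-voxel mask."""
        arr = np.asarray(series, dtype=float)
        v, t = arr.shape
        data = np.zeros((v, 1, 1, t))
        data[:, 0, 0, :] = arr
        return Volume4D(data), BrainMask(np.ones((v, 1, 1), dtype=bool))

    def test_constant_series_gives_zeros(self):
        vol, mask = self.make_vol(np.tile([[5.0, 5.0, 5.0]], (4, 1)))
        np.testing.assert_array_equal(compute_dvars(vol, mask).values,
                                      np.zeros(3))

    def test_two_voxel_closed_form(self):
        # frames (0,0) -> (3,4): RMS = sqrt((9+16)/2)
        vol, mask = self.make_vol([[0.0, 3.0], [0.0, 4.0]])
        dvars = compute_dvars(vol, mask)
        assert dvars.values[1] == pytest.approx(np.sqrt(12.5))

    def test_intensity_scaling_homogeneity(self, rng):
        data = rng.normal(size=(3, 2, 2, 8))
        mask = BrainMask(np.ones((3, 2, 2), dtype=bool))
        one = compute_dvars(Volume4D(data), mask).values
        two = compute_dvars(Volume4D(2 * data), mask).values
        np.testing.assert_allclose(two, 2 * one)

    def test_voxel_permutation_invariance(self, rng):
        data = rng.normal(size=(6, 1, 1, 10))
        mask = BrainMask(np.ones((6, 1, 1), dtype=bool))
        perm = np.random.default_rng(0).permutation(6)
        base = compute_dvars(Volume4D(data), mask).values
        shuf = compute_dvars(Volume4D(data[perm]), mask).values
        np.testing.assert_allclose(shuf, base)


class TestDVARSOutliers:
    def test_constant_series_flags_nothing(self):
        flags = dvars_outliers(FrameSeries(np.array([0.0, 2, 2, 2, 2])))
        assert flags.count == 0
        assert flags.threshold == pytest.approx(2.0)

    def test_quantile_oracle_five_values(self):
        # body (1,1,1,1,10): P75 = 1, IQR = 0 -> threshold 1, only 10 flagged
        flags = dvars_outliers(FrameSeries(np.array([0.0, 1, 1, 1, 1, 10])))
        assert flags.threshold == pytest.approx(1.0)
        np.testing.assert_array_equal(flags.frames, [5])

    def test_against_bruteforce_threshold(self, rng):
        values = np.concatenate([[0.0], rng.gamma(2.0, 1.0, size=40)])
        flags = dvars_outliers(FrameSeries(values))
        body = np.sort(values[1:])
        q1, q3 = np.percentile(body, [25, 75])
        expected = q3 + 1.5 * (q3 - q1)
        assert flags.threshold == pytest.approx(expected)
        np.testing.assert_array_equal(
            flags.flags, np.concatenate([[False], values[1:] > expected])
        )

    def test_monotone_series_with_spike_flags_spike(self):
        values = np.concatenate([[0.0], np.linspace(1, 2, 30), [50.0]])
        flags = dvars_outliers(FrameSeries(values))
        assert 31 in flags.frames


class TestOnSyntheticScan:
    def test_fd_flags_cover_all_injected_spikes(self, tiny_config):
        from neoqc import simulate_scan

        for seed in range(5):
            scan = simulate_scan(tiny_config, seed=seed,
                                 spike_magnitude_mm=0.5)
            flags = fd_outliers(compute_fd(scan.motion))
            assert set(scan.artefact_frames) <= set(flags.frames)

    def test_dvars_flags_cover_all_injected_spikes(self, default_scan):
        dvars = compute_dvars(default_scan.volume, default_scan.mask)
        flags = dvars_outliers(dvars)
        assert set(default_scan.artefact_frames) <= set(flags.frames)
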