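import numpy as np
import pytest

from neoqc import (
    DegenerateInputError,
    DesignMatrixError,
    MotionTrace,
    Volume4D,
    build_nuisance_matrix,
    highpass_filter,
    regress_nuisance,
)
from neoqc.denoise import NuisanceMatrix
from neoqc.motion import OutlierFlags
from neoqc.types import ICDecomposition


def series_vol(arr, tr=0.392):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return Volume4D(arr[:, None, None, :], tr=tr)


class TestHighpassFilter:
    def test_linear_trend_removed_mean_kept(self):
        t = np.arange(300, dtype=float)
        vol = series_vol(5.0 + 0.1 * t)
        out = highpass_filter(vol, 150.0).data[0, 0, 0]
        assert out.mean() == pytest.approx(vol.data[0, 0, 0].mean(), rel=1e-9)
        # residual trend amplitude under 1% of the input's
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 0.001 * 0.1 * len(t)

    @pytest.mark.parametrize(
        "period_s, check",
        [(300.0, lambda ratio: ratio < 0.2), (20.0, lambda ratio: ratio > 0.9)],
    )
    def test_empirical_transfer_ratio(self, period_s, check):
        tr, t = 0.392, 2300
        time = np.arange(t) * tr
        y = np.sin(2 * np.pi * time / period_s)
        out = highpass_filter(series_vol(y, tr), 150.0).data[0, 0, 0]
        core = slice(t // 4, 3 * t // 4)  # avoid edge effects
        ratio = np.ptp(out[core]) / np.ptp(y[core])
        assert check(ratio)

    def test_mean_restored_per_voxel(self, rng):
        data = rng.normal(100, 5, size=(3, 3, 2, 200))
        vol = Volume4D(data, tr=0.5)
        out = highpass_filter(vol, 60.0)
        np.testing.assert_allclose(
            out.data.mean(axis=3), data.mean(axis=3), rtol=1e-6
        )

    def test_cutoff_below_nyquist_bound_rejected(self):
        with pytest.raises(DegenerateInputError):
            highpass_filter(series_vol(np.zeros(50), tr=1.0), 1.5)


class TestBuildNuisanceMatrix:
    def make_ics(self, rng, t=30, k=5, noise=(0, 2, 4)):
        labels = ["noise" if i in noise else "signal" for i in range(k)]
        return ICDecomposition(
            rng.normal(size=(4, 4, 3, k)), rng.normal(size=(t, k)), labels
        )

    def test_column_accounting_noise_ics_plus_motion(self, rng):
        design = build_nuisance_matrix(
            self.make_ics(rng), MotionTrace(rng.normal(size=(30, 6)))
        )
        assert design.n_regressors == 3 + 6
        assert sum(t.startswith("noise_ic:") for t in design.tags) == 3
        np.testing.assert_allclose(design.columns.mean(axis=0), 0, atol=1e-12)

    def test_spike_columns_one_hot_and_demeaned(self, rng):
        flags = np.zeros(30, bool)
        flags[[10, 20]] = True
        design = build_nuisance_matrix(
            self.make_ics(rng),
            include_spikes=True,
            fd_flags=OutlierFlags(flags, 0.25),
        )
        assert design.n_regressors == 3 + 2
        spike = design.columns[:, design.tags.index("spike:10")]
        assert spike[10] == pytest.approx(1 - 1 / 30)
        assert spike[0] == pytest.approx(-1 / 30)

    def test_fd_and_dvars_flags_merged_by_union(self, rng):
        fd = np.zeros(30, bool)
        fd[[10, 15]] = True
        dv = np.zeros(30, bool)
        dv[[10, 25]] = True
        design = build_nuisance_matrix(
            self.make_ics(rng),
            include_spikes=True,
            fd_flags=OutlierFlags(fd, 0.25),
            dvars_flags=OutlierFlags(dv, 9.0),
        )
        spikes = sorted(t for t in design.tags if t.startswith("spike:"))
        assert spikes == ["spike:10", "spike:15", "spike:25"]

    def test_empty_design_rejected(self):
        with pytest.raises(DesignMatrixError, match="empty design"):
            build_nuisance_matrix(None, None)


class TestRegressNuisance:
    def test_orthogonal_design_is_noop(self):
        t = 40
        x = np.zeros((t, 1))
        x[::2, 0] = 1.0
        x -= x.mean()
        design = NuisanceMatrix(x, ["noise_ic:1"])
        series = np.sin(np.pi * np.arange(t) / t)  # even-symmetric-ish
        series = series - (series @ x[:, 0]) / (x[:, 0] @ x[:, 0]) * x[:, 0]
        vol = series_vol(series + 3.0)
        out = regress_nuisance(vol, design)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-8)

    def test_design_column_plus_constant_fully_removed(self, rng):
        col = rng.normal(size=50)
        col -= col.mean()
        design = NuisanceMatrix(col[:, None], ["noise_ic:1"])
        vol = series_vol(2.5 * col + 7.0)
        out = regress_nuisance(vol, design)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-10)

    def test_residual_orthogonal_to_design(self, rng):
        design = NuisanceMatrix(
            rng.normal(size=(60, 4)) - 0,
            [f"noise_ic:{i}" for i in range(4)],
        )
        data = rng.normal(size=(5, 4, 3, 60))
        out = regress_nuisance(Volume4D(data), design)
        resid = out.data.reshape(-1, 60)
        resid = resid - resid.mean(axis=1, keepdims=True)
        inner = resid @ design.columns
        assert np.abs(inner).max() < 1e-8

    def test_idempotence_and_variance_reduction(self, rng):
        design = NuisanceMatrix(
            rng.normal(size=(40, 3)), [f"noise_ic:{i}" for i in range(3)]
        )
        data = rng.normal(size=(4, 4, 2, 40))
        vol = Volume4D(data)
        once = regress_nuisance(vol, design)
        twice = regress_nuisance(once, design)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-8)
        var_in = data.var(axis=3)
        var_out = once.data.var(axis=3)
        assert (var_out <= var_in + 1e-12).all()
        np.testing.assert_allclose(
            once.data.mean(axis=3), data.mean(axis=3), atol=1e-10
        )

    def test_collinear_design_names_offenders(self, rng):
        col = rng.normal(size=(30, 1))
        design = NuisanceMatrix(
            np.hstack([col, 2 * col]), ["noise_ic:1", "noise_ic:2"]
        )
        with pytest.raises(DesignMatrixError, match="noise_ic:2"):
            regress_nuisance(Volume4D(rng.normal(size=(2, 2, 2, 30))), design)

    def test_nonaggressive_preserves_shared_signal_variance(self, rng):
        t = 100
        signal = rng.normal(size=(t, 1))
        noise = 0.6 * signal + 0.8 * rng.normal(size=(t, 1))  # correlated
        design = NuisanceMatrix(noise - noise.mean(), ["noise_ic:1"])
        voxel = 5.0 * signal[:, 0] + 10.0
        vol = series_vol(voxel)
        aggr = regress_nuisance(vol, design, "aggressive")
        nonaggr = regress_nuisance(
            vol, design, "nonaggressive", signal_mixing=signal
        )
        # nonaggressive keeps the signal exactly (voxel is pure signal)
        np.testing.assert_allclose(nonaggr.data, vol.data, atol=1e-8)
        # aggressive removes the shared part: output differs from input
        assert np.abs(aggr.data - vol.data).max() > 0.1

    def test_soft_censoring_reduces_spike_dvars_not_to_zero(
        self, default_scan, filtered_scan, denoised_scan
    ):
        from neoqc import compute_dvars

        pre = compute_dvars(filtered_scan, default_scan.mask).values
        post = compute_dvars(denoised_scan, default_scan.mask).values
        spikes = default_scan.artefact_frames
        assert (post[spikes] < pre[spikes]).all()
        assert (post[spikes] > 0).all()
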