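import numpy as np
import pytest

from neoqc import (
    BrainMask,
    DegenerateInputError,
    NetMat,
    Volume4D,
    dual_regression,
    group_average_netmat,
    netmat_similarity,
    partial_netmat,
    simulate_scan,
    spatial_similarity,
)
from neoqc.similarity import TimecourseSet, _pearson


def netmat_from_upper(upper, k=3):
    m = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    m[iu] = upper
    return NetMat(m + m.T)


class TestDualRegression:
    def test_hand_example_matches_pseudoinverse_oracle(self, rng):
        # 3-voxel, 4-frame, 2-map instance solved by explicit normal equations
        maps = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        tcs_true = rng.normal(size=(4, 2))
        data = maps @ tcs_true.T  # 3 x 4
        vol = Volume4D(data[:, None, None, :])
        mask = BrainMask(np.ones((3, 1, 1), bool))
        maps4d = maps[:, None, None, :]
        tcs, subject_maps = dual_regression(maps4d, vol, mask, normalise=False)
        md = maps - maps.mean(axis=0)
        dt = data - data.mean(axis=1, keepdims=True)
        ds = dt - dt.mean(axis=0, keepdims=True)
        tcs_oracle = (np.linalg.pinv(md) @ ds).T
        np.testing.assert_allclose(tcs.tcs, tcs_oracle, atol=1e-10)
        xo = tcs_oracle - tcs_oracle.mean(axis=0, keepdims=True)
        maps_oracle = dt @ np.linalg.pinv(xo).T
        np.testing.assert_allclose(subject_maps[:, 0, 0, :], maps_oracle,
                                   atol=1e-10)

    def test_noiseless_scan_recovers_timecourses(self, tiny_config):
        scan = simulate_scan(tiny_config, noise_sd=0.0, n_motion_spikes=0,
                             stripe_amplitude=0.0, drift_amplitude=0.0)
        tcs, _ = dual_regression(scan.truth_maps, scan.volume, scan.mask)
        for j in range(tcs.n_components):
            r = np.corrcoef(tcs.tcs[:, j], scan.truth_timecourses[:, j])[0, 1]
            assert r > 0.999

    def test_noiseless_scan_recovers_spatial_maps(self, tiny_config):
        scan = simulate_scan(tiny_config, noise_sd=0.0, n_motion_spikes=0,
                             stripe_amplitude=0.0, drift_amplitude=0.0)
        _, subject_maps = dual_regression(scan.truth_maps, scan.volume,
                                          scan.mask)
        sims = spatial_similarity(subject_maps, scan.truth_maps, scan.mask)
        assert (sims > 0.99).all()

    def test_rank_k_reconstruction_to_precision(self, rng):
        v, t, k = 50, 30, 3
        maps = rng.normal(size=(v, k))
        data = maps @ rng.normal(size=(t, k)).T
        vol = Volume4D(data[:, None, None, :])
        mask = BrainMask(np.ones((v, 1, 1), bool))
        tcs, subject_maps = dual_regression(maps[:, None, None, :], vol, mask)
        recon = subject_maps[:, 0, 0, :] @ tcs.tcs.T
        dd = data - data.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(recon, dd, atol=1e-8)


class TestSpatialSimilarity:
    def test_self_and_negation(self, rng):
        maps = rng.normal(size=(4, 4, 3, 2))
        mask = BrainMask(np.ones((4, 4, 3), bool))
        np.testing.assert_allclose(
            spatial_similarity(maps, maps, mask), [1.0, 1.0], atol=1e-12
        )
        np.testing.assert_allclose(
            spatial_similarity(-maps, maps, mask), [-1.0, -1.0], atol=1e-12
        )

    def test_closed_form_pearson(self):
        # (1,2,3) vs (1,2,4) -> 0.981981
        assert _pearson(np.array([1.0, 2, 3]), np.array([1.0, 2, 4])) == (
            pytest.approx(0.9819805061)
        )


class TestPartialNetmat:
    def test_two_components_equal_full_correlation(self, rng):
        tcs = rng.normal(size=(100, 2))
        nm = partial_netmat(TimecourseSet(tcs))
        r = np.corrcoef(tcs.T)[0, 1]
        assert nm.values[0, 1] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_collider_induces_negative_partial(self, rng):
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        x3 = x1 + x2 + 0.3 * rng.normal(size=500)
        nm = partial_netmat(TimecourseSet(np.column_stack([x1, x2, x3])))
        assert np.tanh(nm.values[0, 1]) < -0.5
        assert abs(np.corrcoef(x1, x2)[0, 1]) < 0.15

    def test_matches_regression_residual_oracle(self, rng):
        tcs = rng.normal(size=(80, 4))
        nm = partial_netmat(TimecourseSet(tcs))
        # oracle: correlate residuals after regressing out the others
        i, j = 1, 3
        others = tcs[:, [0, 2]]
        others = np.column_stack([others, np.ones(80)])
        proj = others @ np.linalg.lstsq(others, tcs[:, [i, j]], rcond=None)[0]
        resid = tcs[:, [i, j]] - proj
        r = np.corrcoef(resid.T)[0, 1]
        assert nm.values[i, j] == pytest.approx(np.arctanh(r), abs=1e-8)

    def test_symmetric_zero_diagonal(self, rng):
        nm = partial_netmat(TimecourseSet(rng.normal(size=(50, 4))))
        np.testing.assert_allclose(nm.values, nm.values.T)
        np.testing.assert_array_equal(np.diag(nm.values), np.zeros(4))

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            partial_netmat(TimecourseSet(rng.normal(size=(4, 4))))


class TestNetmatSimilarity:
    def test_identical_netmats_score_one(self, rng):
        nm = netmat_from_upper([0.1, -0.4, 0.3])
        assert netmat_similarity(nm, nm) == pytest.approx(1.0)

    def test_closed_form_on_three_by_three(self):
        a = netmat_from_upper([0.1, 0.2, 0.3])
        b = netmat_from_upper([0.1, 0.2, 0.4])
        assert netmat_similarity(a, b) == pytest.approx(0.9819805061)

    def test_k_two_rejected(self):
        nm = NetMat(np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(DegenerateInputError):
            netmat_similarity(nm, nm)


class TestGroupAverage:
    def test_single_netmat_is_identity_operation(self):
        nm = netmat_from_upper([0.2, 0.1, -0.3])
        np.testing.assert_allclose(group_average_netmat([nm]).values, nm.values)

    def test_mean_in_z_space(self):
        a = netmat_from_upper([0.2, 0.2, 0.2])
        b = netmat_from_upper([0.4, 0.4, 0.4])
        avg = group_average_netmat([a, b])
        np.testing.assert_allclose(avg.upper_triangle(), [0.3, 0.3, 0.3])

    def test_netmat_and_negation_average_to_zero(self):
        a = netmat_from_upper([0.2, -0.1, 0.5])
        b = NetMat(-a.values)
        np.testing.assert_allclose(group_average_netmat([a, b]).values, 0.0)
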