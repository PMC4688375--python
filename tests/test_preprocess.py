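"""Preprocessing chain: residualization, DCT filter, scaling, z-scoring, smoothing."""

import numpy as np
import pandas as pd
import pytest

from scandecode.paradigm import AcquisitionParams, build_alternating_run
from scandecode.preprocess import (
    PreprocConfig,
    ScalingError,
    dct_basis,
    drop_dummy_scans,
    gaussian_smooth,
    grand_mean_scale,
    highpass_dct,
    preprocess_day,
    regress_nuisance,
    smooth_run,
    standardize_day,
)
from scandecode.synthsim import BoldRun, NoiseConfig, make_ground_truth, simulate_run
from conftest import NOISELESS


def tiny_run(n_scans=20, grid=(4, 4, 3), seed=0, data=None):
    """Hand-built run with arbitrary data for unit-level preprocessing checks."""
    acq = AcquisitionParams(n_dummy_scans=0, grid_shape=grid)
    # a 20-scan alternating schedule: 1 cycle of 8 s task / 12 s rest
    sched = build_alternating_run(acq, n_cycles=1, task_seconds=8.0, rest_seconds=12.0)
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.normal(100.0, 5.0, size=grid + (sched.n_scans,))
    conf = pd.DataFrame(
        rng.normal(size=(sched.n_scans, 9)),
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
                 "wm_mean", "csf_mean", "global_mean"],
    )
    return BoldRun(data=data, schedule=sched, confounds=conf), np.ones(grid, dtype=bool)


class TestRegressNuisance:
    def test_confound_column_maps_to_zero(self):
        run, mask = tiny_run()
        col = run.confounds["trans_x"].to_numpy()
        run.data[1, 1, 1, :] = col
        out = regress_nuisance(run, mask)
        assert np.abs(out.data[1, 1, 1]).max() < 1e-10

    def test_residuals_orthogonal_to_all_regressors(self):
        run, mask = tiny_run(seed=5)
        out = regress_nuisance(run, mask)
        X = np.column_stack([run.confounds.to_numpy(), np.ones(run.n_scans)])
        resid = out.data[mask].T
        assert np.abs(resid.T @ X).max() < 1e-8

    def test_matches_projection_matrix_oracle(self):
        # independent oracle: residual = (I - X (X'X)^-1 X') y
        rng = np.random.default_rng(1)
        X3 = rng.normal(size=(20, 3))
        run, mask = tiny_run(seed=2)
        out = regress_nuisance(run, mask, regressors=X3, add_constant=False)
        Xf = X3
        P = np.eye(20) - Xf @ np.linalg.inv(Xf.T @ Xf) @ Xf.T
        y = run.data[2, 2, 1]
        np.testing.assert_allclose(out.data[2, 2, 1], P @ y, atol=1e-10)

    def test_rank_deficient_warns(self):
        run, mask = tiny_run()
        X = np.ones((run.n_scans, 2))  # duplicated constant
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_nuisance(run, mask, regressors=X, add_constant=True)


class TestHighpassDct:
    def test_regressor_count_at_paper_cutoff(self):
        # 288 s of data at 0.008 Hz: j/(2*288) < 0.008 keeps j = 1..4
        assert dct_basis(144, 2.0, 0.008).shape[1] == 4
        assert dct_basis(144, 2.0, 0.0078).shape[1] == 4

    def test_slow_cosine_removed(self):
        run, mask = tiny_run(n_scans=20)
        acq = AcquisitionParams(n_dummy_scans=0, grid_shape=(4, 4, 3))
        sched = build_alternating_run(acq, n_cycles=3, task_seconds=40.0, rest_seconds=40.0)
        n = sched.n_scans  # 240 scans = 480 s
        # drift component at ~0.002 Hz (j=2 of the cosine basis, 2/(2*480) Hz)
        t = np.arange(n)
        slow = np.cos(np.pi * (2 * t + 1) * 2 / (2 * n))
        data = np.tile(slow, (4, 4, 3, 1))
        conf = pd.DataFrame(np.zeros((n, 9)), columns=run.confounds.columns)
        r = BoldRun(data=data, schedule=sched, confounds=conf)
        out = highpass_dct(r, np.ones((4, 4, 3), bool), 0.008)
        assert np.abs(out.data).max() < 1e-8 * np.abs(data).max()

    def test_nyquist_signal_untouched(self):
        run, mask = tiny_run()
        alt = np.tile(np.resize([1.0, -1.0], run.n_scans), (4, 4, 3, 1))
        r = BoldRun(data=alt, schedule=run.schedule, confounds=run.confounds)
        out = highpass_dct(r, mask, 0.008)
        np.testing.assert_allclose(out.data, alt, atol=1e-10)


class TestGrandMeanScale:
    def test_halves_data_with_mean_200(self):
        run, mask = tiny_run()
        run.data[mask] = 200.0 + 0.0 * run.data[mask]
        out = grand_mean_scale(run, mask, 100.0)
        np.testing.assert_allclose(out.data[mask], 100.0)

    def test_grand_mean_hits_target(self):
        run, mask = tiny_run(seed=3)
        out = grand_mean_scale(run, mask, 100.0)
        assert out.data[mask].mean() == pytest.approx(100.0, abs=1e-8)

    def test_voxel_ratios_preserved(self):
        run, mask = tiny_run(seed=4)
        out = grand_mean_scale(run, mask, 100.0)
        before = run.data[1, 1, 1] / run.data[2, 2, 2]
        after = out.data[1, 1, 1] / out.data[2, 2, 2]
        np.testing.assert_allclose(before, after, rtol=1e-10)

    def test_nonpositive_mean_rejected(self):
        run, mask = tiny_run()
        run.data[...] = -5.0
        with pytest.raises(ScalingError):
            grand_mean_scale(run, mask, 100.0)


class TestStandardizeDay:
    def test_day_pooling_keeps_between_run_differences(self):
        r1, mask = tiny_run(seed=6)
        r2, _ = tiny_run(seed=7)
        r1.data[1, 1, 1, :] = 10.0
        r2.data[1, 1, 1, :] = 20.0
        out1, out2 = standardize_day([r1, r2], mask)
        # constant within each run but different between runs -> nonzero output
        assert np.all(out1.data[1, 1, 1] < 0) and np.all(out2.data[1, 1, 1] > 0)

    def test_pooled_mean_zero_sd_one(self):
        r1, mask = tiny_run(seed=8)
        r2, _ = tiny_run(seed=9)
        out = standardize_day([r1, r2], mask)
        concat = np.concatenate([o.data[mask] for o in out], axis=1)
        np.testing.assert_allclose(concat.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(concat.std(axis=1), 1.0, atol=1e-8)

    def test_single_run_equals_per_run_zscore(self):
        r, mask = tiny_run(seed=10)
        (out,) = standardize_day([r], mask)
        v = r.data[1, 2, 1]
        np.testing.assert_allclose(out.data[1, 2, 1], (v - v.mean()) / v.std(), atol=1e-10)

    def test_idempotent(self):
        r1, mask = tiny_run(seed=11)
        r2, _ = tiny_run(seed=12)
        once = standardize_day([r1, r2], mask)
        twice = standardize_day(once, mask)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.data, b.data, atol=1e-8)

    def test_zero_variance_voxel_zeroed_with_warning(self):
        r, mask = tiny_run(seed=13)
        r.data[0, 0, 0, :] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            (out,) = standardize_day([r], mask)
        assert np.all(out.data[0, 0, 0] == 0.0)


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(8, 8, 6))
        np.testing.assert_array_equal(gaussian_smooth(v, 0.0, (3, 3, 5)), v)

    def test_total_sum_preserved(self):
        rng = np.random.default_rng(1)
        v = np.zeros((24, 24, 16))
        v[10:14, 10:14, 6:10] = rng.uniform(1.0, 2.0, size=(4, 4, 4))  # deep interior support
        out = gaussian_smooth(v, 8.0, (3.0, 3.0, 5.0))
        assert out.sum() == pytest.approx(v.sum(), abs=1e-6 * v.sum())

    def test_impulse_matches_direct_convolution_oracle(self):
        # oracle: explicit separable Gaussian product evaluated on the grid
        v = np.zeros((15, 15, 11))
        v[7, 7, 5] = 1.0
        fwhm, vox = 8.0, (3.0, 3.0, 5.0)
        out = gaussian_smooth(v, fwhm, vox)
        sig = [fwhm / (2 * np.sqrt(2 * np.log(2))) / s for s in vox]
        axes = [np.arange(d) - c for d, c in (((15), 7), ((15), 7), ((11), 5))]
        g = [np.exp(-(ax**2) / (2 * s**2)) for ax, s in zip(axes, sig)]
        g = [gi / gi.sum() for gi in g]
        oracle = g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        np.testing.assert_allclose(out, oracle, atol=1e-8)


class TestChain:
    def test_order_recorded_in_provenance(self, acq, truth):
        from scandecode.synthsim import ExperimentProtocol, simulate_experiment

        exp = simulate_experiment(
            ExperimentProtocol(n_day1_runs=2, n_day2_alt_runs=0, n_day2_binary_runs=0),
            truth, seed=0,
        )
        out = preprocess_day(exp.day1, truth.brain_mask)
        steps = out[0].provenance["preprocessing"]
        wanted = ["drop_dummy_scans", "regress_nuisance", "restore_session_mean",
                  "highpass_dct", "grand_mean_scale", "standardize_day"]
        assert [s.split("(")[0] for s in steps] == wanted

    def test_out_of_mask_voxels_untouched(self, acq, truth):
        from scandecode.synthsim import ExperimentProtocol, simulate_experiment

        exp = simulate_experiment(
            ExperimentProtocol(n_day1_runs=1, n_day2_alt_runs=0, n_day2_binary_runs=0),
            truth, seed=1,
        )
        raw = exp.day1[0]
        out = preprocess_day([raw], truth.brain_mask)[0]
        outside = ~truth.brain_mask
        nd = raw.schedule.acquisition.n_dummy_scans
        np.testing.assert_array_equal(out.data[outside], raw.data[outside][:, nd:])

    def test_dummy_scans_dropped_once(self, default_experiment, truth):
        run = drop_dummy_scans(default_experiment.day1[0])
        assert run.n_scans == 144 and run.t_offset_scans == 3
        again = drop_dummy_scans(run)
        assert again.n_scans == 144

    def test_invalid_cutoff_rejected(self, default_experiment, truth):
        with pytest.raises(ValueError, match="hp_cutoff"):
            preprocess_day(default_experiment.day1[:1], truth.brain_mask,
                           PreprocConfig(hp_cutoff_hz=0.5))
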