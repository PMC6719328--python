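import itertools

import numpy as np
import pytest

from verdict_mri.dictionary import (
    ModelConfig,
    build_dictionary,
    correct_rician_bias,
    estimate_rician_sigma,
    fit_voxel,
    fit_volume,
    normalise_shells,
)
from verdict_mri.models import TissueParams, ball_signal, sphere_signal, voxel_signal

from conftest import noiseless_measurements


class TestBuildDictionary:
    def test_shape_contract(self, protocol):
        cfg = ModelConfig(radius_grid=np.array([5.0]), d_ees_grid=(2e-9,))
        D = build_dictionary(protocol, cfg)
        assert D.matrix.shape == (protocol.n_measurements, 2)
        assert D.n_sphere == 1 and D.n_ball == 1

    def test_b0_rows_are_ones(self, dictionary, protocol):
        b0_rows = [r for r, (_, is_b0) in enumerate(protocol.measurement_layout()) if is_b0]
        assert np.all(dictionary.matrix[b0_rows] == 1.0)

    def test_columns_reproduce_forward_models(self, dictionary, protocol):
        layout = protocol.measurement_layout()
        for j, R in enumerate(dictionary.radius_grid[::7]):
            col = dictionary.matrix[:, list(dictionary.radius_grid).index(R)]
            for row, (ishell, is_b0) in enumerate(layout):
                expected = 1.0 if is_b0 else sphere_signal(protocol.shells[ishell], R)
                assert col[row] == pytest.approx(expected, abs=1e-10)
        for j, d in enumerate(dictionary.d_ees_grid):
            col = dictionary.matrix[:, dictionary.n_sphere + j]
            for row, (ishell, is_b0) in enumerate(layout):
                expected = 1.0 if is_b0 else ball_signal(protocol.shells[ishell], d)
                assert col[row] == pytest.approx(expected, abs=1e-10)

    def test_tiny_radius_column_is_all_ones(self, protocol):
        cfg = ModelConfig(radius_grid=np.array([0.01, 5.0]))
        D = build_dictionary(protocol, cfg)
        assert np.allclose(D.matrix[:, 0], 1.0, atol=1e-4)

    def test_deterministic(self, protocol):
        a = build_dictionary(protocol).matrix
        b = build_dictionary(protocol).matrix
        assert np.array_equal(a, b)


class TestNormaliseShells:
    def test_signal_equal_to_b0_gives_one(self, protocol):
        n = protocol.n_measurements
        dwi = np.full((3, 3, 2, n), 7.5)
        out, valid = normalise_shells(dwi, protocol)
        assert np.all(out == 1.0) and valid.all()

    def test_noiseless_forward_round_trip(self, protocol):
        params = TissueParams(f_ic=0.2, f_ec=0.75, R=8.0, d_ees=1.3e-9)
        meas = noiseless_measurements(protocol, params)
        # scale each shell by a distinct fake T2 weighting
        layout = protocol.measurement_layout()
        s0 = {i: 0.5 + 0.1 * i for i in range(len(protocol))}
        raw = np.array([meas[r] * s0[ishell] for r, (ishell, _) in enumerate(layout)])
        dwi = np.tile(raw, (2, 2, 1, 1))
        out, valid = normalise_shells(dwi, protocol)
        assert valid.all()
        assert np.allclose(out[0, 0, 0], meas, atol=1e-12)

    def test_zero_b0_voxels_masked(self, protocol):
        n = protocol.n_measurements
        dwi = np.ones((2, 2, 1, n))
        dwi[0, 0, 0, 0] = 0.0  # first b0 volume
        out, valid = normalise_shells(dwi, protocol)
        assert not valid[0, 0, 0] and valid[1, 1, 0]
        assert np.isnan(out[0, 0, 0]).all()

    def test_volume_count_mismatch_rejected(self, protocol):
        with pytest.raises(ValueError, match="volumes"):
            normalise_shells(np.ones((2, 2, 2, 3)), protocol)


class TestRicianHandling:
    def test_sigma_recovered_from_rayleigh_background(self, protocol):
        rng = np.random.default_rng(1)
        n = protocol.n_measurements
        sigma = 0.04
        bg = np.sqrt(
            rng.normal(0, sigma, (40, 40, 8, n)) ** 2 + rng.normal(0, sigma, (40, 40, 8, n)) ** 2
        )
        est = estimate_rician_sigma(bg, np.ones((40, 40, 8), dtype=bool))
        assert est == pytest.approx(sigma, rel=0.02)

    def test_floor_correction_restores_signal_scale(self):
        rng = np.random.default_rng(2)
        s_true, sigma = 0.06, 0.02
        m = np.sqrt(
            rng.normal(s_true, sigma, 200_000) ** 2 + rng.normal(0, sigma, 200_000) ** 2
        )
        assert m.mean() > s_true * 1.03  # raw magnitude is floor-biased
        corrected = correct_rician_bias(m, sigma)
        assert np.sqrt(np.mean(corrected**2)) == pytest.approx(s_true, rel=0.02)


class TestFitVoxel:
    def test_noiseless_grid_representable_recovery(self, protocol, dictionary):
        params = TissueParams(f_ic=0.3, f_ec=0.7, R=7.0, d_ees=1.5e-9)
        s = noiseless_measurements(protocol, params)
        res = fit_voxel(s, dictionary, lam=0.0)
        assert res.f_ic == pytest.approx(0.3, abs=0.02)
        assert res.f_ec == pytest.approx(0.7, abs=0.02)
        assert res.R_hat == pytest.approx(7.0, abs=0.5)
        assert res.residual < 1e-8

    def test_pure_ball_yields_no_intracellular_weight(self, protocol, dictionary):
        params = TissueParams(f_ic=0.0, f_ec=1.0, R=5.0, d_ees=2.0e-9)
        s = noiseless_measurements(protocol, params)
        res = fit_voxel(s, dictionary, lam=0.0)
        assert res.f_ic <= 0.02
        assert np.isnan(res.R_hat) or res.f_ic > 0

    def test_objective_matches_brute_force_on_small_instance(self, protocol):
        cfg = ModelConfig(radius_grid=np.array([4.0, 9.0]), d_ees_grid=(1.5e-9,), lam=1e-3)
        D = build_dictionary(protocol, cfg)
        params = TissueParams(f_ic=0.25, f_ec=0.7, R=6.0, d_ees=1.2e-9)
        s = noiseless_measurements(protocol, params)
        res = fit_voxel(s, D, keep_weights=True)
        lam = cfg.lam

        def objective(w):
            return np.sum((D.matrix @ w - s) ** 2) + lam * np.sum(w**2)

        # exhaustive grid search over discretised non-negative weights,
        # coarse pass then local refinement
        grid = np.arange(0.0, 1.0001, 0.02)
        best, best_w = np.inf, None
        for w in itertools.product(grid, repeat=3):
            val = objective(np.array(w))
            if val < best:
                best, best_w = val, np.array(w)
        fine = [np.arange(max(0, wi - 0.02), wi + 0.0201, 0.001) for wi in best_w]
        for w in itertools.product(*fine):
            best = min(best, objective(np.array(w)))
        assert objective(res.weights) <= best + 1e-4

    def test_ball_atom_permutation_leaves_estimates_unchanged(self, protocol):
        base = ModelConfig(d_ees_grid=(0.8e-9, 1.4e-9, 2.2e-9))
        perm = ModelConfig(d_ees_grid=(2.2e-9, 0.8e-9, 1.4e-9))
        s = noiseless_measurements(
            protocol, TissueParams(f_ic=0.15, f_ec=0.8, R=6.5, d_ees=1.4e-9)
        )
        r1 = fit_voxel(s, build_dictionary(protocol, base))
        r2 = fit_voxel(s, build_dictionary(protocol, perm))
        assert r1.f_ic == pytest.approx(r2.f_ic, abs=1e-8)
        assert r1.f_ec == pytest.approx(r2.f_ec, abs=1e-8)
        assert r1.R_hat == pytest.approx(r2.R_hat, abs=1e-6)

    def test_fractions_nonnegative_and_sum_unconstrained(self, protocol, dictionary):
        # a voxel whose signal everywhere exceeds any unit-fraction model:
        # the fit must be free to exceed f_ic + f_ec = 1
        s = 1.12 * noiseless_measurements(
            protocol, TissueParams(f_ic=0.2, f_ec=0.8, R=6.0, d_ees=1.2e-9)
        )
        res = fit_voxel(s, dictionary, lam=0.0)
        assert res.f_ic >= 0 and res.f_ec >= 0
        assert res.total_fraction == pytest.approx(1.12, abs=0.02)

    def test_nan_signal_rejected(self, protocol, dictionary):
        s = noiseless_measurements(protocol, TissueParams(f_ic=0.2, f_ec=0.8, R=6.0))
        s[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_voxel(s, dictionary)


class TestFitVolume:
    def test_matches_per_voxel_calls(self, protocol, dictionary):
        rng = np.random.default_rng(0)
        shape = (4, 3, 2)
        layout = protocol.measurement_layout()
        dwi = np.empty(shape + (len(layout),))
        truth = {}
        for idx in np.ndindex(shape):
            p = TissueParams(
                f_ic=rng.uniform(0.05, 0.4),
                f_ec=rng.uniform(0.5, 0.9),
                R=rng.uniform(3, 12),
                d_ees=rng.uniform(0.8e-9, 2.5e-9),
            )
            truth[idx] = p
            dwi[idx] = noiseless_measurements(protocol, p)
        mask = np.ones(shape, dtype=bool)
        maps = fit_volume(dwi, mask, dictionary)
        norm, _ = normalise_shells(dwi, protocol)
        for idx in [(0, 0, 0), (3, 2, 1), (1, 1, 1)]:
            res = fit_voxel(norm[idx], dictionary)
            assert maps.f_ic[idx] == pytest.approx(res.f_ic, abs=1e-12)
            assert maps.radius[idx] == pytest.approx(res.R_hat, abs=1e-9, nan_ok=True)

    def test_empty_mask_is_an_error(self, protocol, dictionary):
        dwi = np.ones((2, 2, 2, protocol.n_measurements))
        with pytest.raises(ValueError, match="empty"):
            fit_volume(dwi, np.zeros((2, 2, 2), dtype=bool), dictionary)

    def test_recovery_rmse_degrades_monotonically_with_noise(self, protocol, dictionary):
        """More noise can only hurt: f_ic RMSE is non-decreasing as SNR drops."""
        rng = np.random.default_rng(11)
        n_vox = 160
        params = [
            TissueParams(
                f_ic=rng.uniform(0.05, 0.35),
                f_ec=rng.uniform(0.55, 0.9),
                R=rng.uniform(4, 11),
                d_ees=rng.uniform(1.0e-9, 2.0e-9),
            )
            for _ in range(n_vox)
        ]
        clean = np.stack([noiseless_measurements(protocol, p) for p in params])
        rmses = []
        for snr in (np.inf, 100, 50, 20):
            noisy = clean if np.isinf(snr) else np.sqrt(
                (clean + rng.normal(0, 1 / snr, clean.shape)) ** 2
                + rng.normal(0, 1 / snr, clean.shape) ** 2
            )
            if not np.isinf(snr):
                noisy = correct_rician_bias(noisy, 1 / snr)
            errs = [
                fit_voxel(noisy[i], dictionary).f_ic - params[i].f_ic
                for i in range(n_vox)
            ]
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert all(a <= b + 1e-6 for a, b in zip(rmses, rmses[1:])), rmses
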