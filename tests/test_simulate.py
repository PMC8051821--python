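import numpy as np
import pytest

import rsndyn as r
from rsndyn.simulate import companion_spectral_radius, replicator_rhs


class TestVarGeneration:
    def test_unstable_coefficients_refused_with_radius(self):
        with pytest.raises(ValueError, match="spectral radius"):
            r.gen_var_session(np.eye(3) * 1.05, 208, seed=0)

    def test_determinism(self):
        a = r.gen_var_session(np.eye(3) * 0.3, 208, seed=5)
        b = r.gen_var_session(np.eye(3) * 0.3, 208, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_diagonal_model_has_no_cross_correlation(self):
        ts = r.gen_var_session(np.eye(3) * 0.3, 2000, seed=1)
        corr = np.corrcoef(ts.values, rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.2)

    def test_planted_lag1_coupling_matches_yule_walker(self):
        """corr(x1[t-1], x2[t]) approaches the closed-form VAR(1) value."""
        a, c = 0.3, 0.5
        A = np.array([[a, 0.0], [c, a]])
        # Yule-Walker oracle: solve the discrete Lyapunov equation for the
        # stationary covariance, then lag-1 cross-covariance = A @ Sigma.
        from scipy.linalg import solve_discrete_lyapunov

        Sigma = solve_discrete_lyapunov(A, np.eye(2))
        lag1 = A @ Sigma  # cov(x[t], x[t-1])
        rho_expect = lag1[1, 0] / np.sqrt(Sigma[0, 0] * Sigma[1, 1])
        ts = r.gen_var_session(A, 2000, seed=2)
        x = ts.values
        rho = np.corrcoef(x[:-1, 0], x[1:, 1])[0, 1]
        assert rho > 0.3
        assert abs(rho - rho_expect) < 0.08

    def test_companion_radius_multilag(self):
        A = np.zeros((2, 2, 2))
        A[0] = np.eye(2) * 0.5
        A[1] = np.eye(2) * 0.3
        # scalar AR(2) root oracle: x^2 = 0.5 x + 0.3
        root = max(abs(np.roots([1, -0.5, -0.3])))
        assert companion_spectral_radius(A) == pytest.approx(root, abs=1e-12)


class TestPhaseLockedPair:
    def test_full_coherence_no_noise_identical(self):
        ts = r.gen_phase_locked_pair(20.0, 1.0, 0.0, T=208, dt=2.0, noise_sd=0.0, seed=0)
        assert np.allclose(ts.values[:, 0], ts.values[:, 1])

    def test_antiphase_offset_flips_sign(self):
        ts = r.gen_phase_locked_pair(20.0, 1.0, np.pi, T=208, dt=2.0, noise_sd=0.0, seed=0)
        corr = np.corrcoef(ts.values[:, 0], ts.values[:, 1])[0, 1]
        assert corr < -0.95

    def test_unresolvable_period_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            r.gen_phase_locked_pair(3.0, 1.0, 0.0, T=208, dt=2.0)
        with pytest.raises(ValueError, match="resolvable"):
            r.gen_phase_locked_pair(300.0, 1.0, 0.0, T=208, dt=2.0)

    def test_window_covers_requested_fraction(self):
        ts = r.gen_phase_locked_pair(20.0, 0.5, 0.0, T=208, dt=2.0, noise_sd=0.0, seed=0)
        active = np.abs(ts.values[:, 0]) > 1e-12
        assert abs(active.mean() - 0.5) < 0.05


class TestEgnTrajectory:
    def test_zero_matrix_is_fixed_point(self):
        x0 = np.array([0.3, 0.6, 0.4])
        ts = r.gen_egn_trajectory(np.zeros((3, 3)), x0, T=64, dt=1.0, noise_sd=0.0, seed=0)
        assert np.allclose(ts.values, x0[None, :])

    def test_boundary_initial_state_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            r.gen_egn_trajectory(np.zeros((2, 2)), np.array([0.0, 0.5]), T=64)

    def test_two_node_dynamics_match_fine_step_oracle(self):
        """Euler trajectory tracks an independent fine-step integration."""
        A = np.array([[0.0, 0.4], [0.0, 0.0]])
        x0 = np.array([0.4, 0.8])
        dt, T = 0.5, 64
        ts = r.gen_egn_trajectory(A, x0, T=T, dt=dt, noise_sd=0.0, seed=0)
        # oracle: 50 sub-steps per output step, independent loop
        sub = 50
        x = x0.copy()
        fine = [x.copy()]
        for _ in range(T - 1):
            for _ in range(sub):
                x = x + (dt / sub) * (x * (1 - x) * (A @ (2 * x - 1)))
            fine.append(x.copy())
        fine = np.array(fine)
        # x2 > 1/2 and a12 > 0: x1 rises monotonically toward saturation
        d = np.diff(ts.values[:, 0])
        assert np.all(d >= -1e-12)
        assert np.allclose(ts.values, fine, atol=0.02)

    def test_determinism_with_noise(self):
        A = np.array([[0.0, 0.2], [-0.2, 0.0]])
        kw = dict(x0=np.array([0.5, 0.5]), T=64, dt=1.0, noise_sd=0.05, seed=9)
        assert np.array_equal(r.gen_egn_trajectory(A, **kw).values, r.gen_egn_trajectory(A, **kw).values)


class TestBenchmarkDataset:
    def test_shapes_and_roster(self):
        rs1, rs2 = r.gen_benchmark_dataset(0)
        for cohort in (rs1, rs2):
            assert len(cohort) == 24
            assert all(ts.values.shape == (208, 14) for ts in cohort)
            assert cohort.network_labels == r.DEFAULT_NETWORKS
        groups = [ts.group for ts in rs1]
        assert groups.count("ACA") == 10 and groups.count("CONTROL") == 14

    def test_seed_determinism_and_subject_stability(self):
        rs1a, _ = r.gen_benchmark_dataset(4)
        rs1b, _ = r.gen_benchmark_dataset(4)
        for a, b in zip(rs1a, rs1b):
            assert np.array_equal(a.values, b.values)
        # adding subjects does not perturb existing streams
        small = r.SimulationConfig(n_controls=3, n_patients=2, seed=4, effects=r.simulate.default_benchmark_effects())
        rs1c, _ = r.gen_benchmark_dataset(4, small)
        assert np.array_equal(rs1c.session("ctrl01", "RS1").values, rs1a.session("ctrl01", "RS1").values)

    def test_effect_validation_rejects_unknown_networks(self):
        eff = (r.PlantedEffect("var_coupling", {"source": "NOPE", "target": "DMN", "coeff": 0.3}),)
        with pytest.raises(ValueError, match="unknown network"):
            r.SimulationConfig(effects=eff)


class TestFeatureTableGenerator:
    def test_planted_shift_and_exchangeability(self):
        table = r.gen_feature_table(50, 50, 3, effect_sizes={"f0000": 2.0}, seed=0)
        g = table.groups
        x = table.matrix()
        shift = x[g == "ACA", 0].mean() - x[g == "CONTROL", 0].mean()
        assert abs(shift - 2.0) < 0.5
        assert abs(x[g == "ACA", 1].mean() - x[g == "CONTROL", 1].mean()) < 0.5
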