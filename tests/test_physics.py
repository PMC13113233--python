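"""Physics pathway: SG differentiation, SPD inertia, Newton-Euler residuals."""

import numpy as np
import pytest

from gaitdistill.gait_sim import (
    GaitSimConfig,
    generate_kinematics,
    ground_truth_torque,
)
from gaitdistill.physics import (
    GravityModel,
    InertiaCholesky,
    KinematicCycle,
    SGConfig,
    fit_inertia,
    gravity_torque,
    newton_euler_torque,
    physics_loss,
    raw_for_factor,
    sg_smooth_derivative,
    spd_from_cholesky,
)


def _quiescent(T=101, dt=0.011):
    return KinematicCycle(
        theta=np.zeros(T), omega=np.zeros((T, 3)), omega_dot=np.zeros((T, 3)), dt=dt
    )


class TestSavitzkyGolay:
    def test_derivative_of_constant_is_zero(self):
        x = np.full((50, 2), 3.7)
        d = sg_smooth_derivative(x, SGConfig(11, 3, 1), dt=0.01)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_linear_ramp_slope(self):
        dt = 0.01
        t = np.arange(60) * dt
        d = sg_smooth_derivative(2.0 * t, SGConfig(11, 3, 1), dt=dt)
        assert np.allclose(d[5:-5], 2.0, atol=1e-10)

    def test_cubic_polynomial_derivative_exact_at_interior(self):
        # window 11, polyorder 3: exact for cubics
        dt = 0.011
        t = np.arange(101) * dt
        x = 0.3 * t**3 - 1.2 * t**2 + 0.5 * t - 2.0
        dx_true = 0.9 * t**2 - 2.4 * t + 0.5
        d = sg_smooth_derivative(x, SGConfig(11, 3, 1), dt=dt)
        assert np.abs(d[5:-5] - dx_true[5:-5]).max() < 1e-8

    def test_linearity_of_the_operator(self, rng):
        cfg = SGConfig(11, 5, 1)
        a, b = rng.standard_normal(80), rng.standard_normal(80)
        lhs = sg_smooth_derivative(2.0 * a + 3.0 * b, cfg, 0.01)
        rhs = 2.0 * sg_smooth_derivative(a, cfg, 0.01) + 3.0 * sg_smooth_derivative(
            b, cfg, 0.01
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_too_short_trajectory_reports_minimum(self):
        with pytest.raises(ValueError, match="at least 11"):
            sg_smooth_derivative(np.zeros(7), SGConfig(11, 3, 1), 0.01)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SGConfig(10, 3, 0)

    def test_polyorder_must_be_below_window(self):
        with pytest.raises(ValueError, match="polyorder"):
            SGConfig(5, 5, 0)


class TestInertiaCholesky:
    def test_identity_factor_gives_identity_tensor(self):
        raw = raw_for_factor(np.eye(3))
        assert np.allclose(spd_from_cholesky(raw), np.eye(3), atol=1e-9)

    def test_diagonal_factor_squares(self):
        raw = raw_for_factor(np.diag([2.0, 3.0, 0.5]))
        assert np.allclose(
            spd_from_cholesky(raw), np.diag([4.0, 9.0, 0.25]), atol=1e-9
        )

    def test_spd_for_1000_random_raw_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            raw = rng.standard_normal(6) * 3.0
            i_eff = spd_from_cholesky(raw)
            assert np.allclose(i_eff, i_eff.T)
            # min eig of L L^T = sigma_min(L)^2, computed from the factor to
            # avoid the squared conditioning of eigvalsh on the product
            factor = InertiaCholesky(raw, trainable=False).factor
            assert np.linalg.svd(factor, compute_uv=False).min() ** 2 > 0.0

    def test_nonfinite_raw_rejected(self):
        raw = np.zeros(6)
        raw[2] = np.inf
        with pytest.raises(ValueError, match="finite"):
            spd_from_cholesky(raw)

    def test_mapping_is_differentiable(self, rng):
        raw = rng.standard_normal(6)
        inertia = InertiaCholesky(raw)
        loss = (inertia.i_eff_tensor() ** 2.0).sum()
        loss.backward()
        assert inertia.raw.grad is not None
        assert np.all(np.isfinite(inertia.raw.grad))

    def test_report_round_trips_tensor(self):
        inertia = InertiaCholesky(raw_for_factor(np.diag([1.0, 2.0, 3.0])))
        rep = inertia.report()
        assert np.allclose(rep["i_eff"], inertia.i_eff)
        assert min(rep["eigenvalues"]) > 0


class TestNewtonEuler:
    def test_quiescent_state_zero_torque(self):
        tau = newton_euler_torque(
            InertiaCholesky(trainable=False), _quiescent(), GravityModel.disabled()
        )
        assert np.allclose(tau, 0.0)

    def test_isotropic_inertia_kills_gyroscopic_term(self, rng):
        kin = _quiescent()
        kin.omega = np.tile(rng.standard_normal(3), (101, 1))
        kin.omega_dot = rng.standard_normal((101, 3))
        c = 2.0
        inertia = InertiaCholesky(raw_for_factor(np.sqrt(c) * np.eye(3)), trainable=False)
        tau = newton_euler_torque(inertia, kin, GravityModel.disabled())
        assert np.allclose(tau, c * kin.omega_dot, atol=1e-9)

    def test_hand_cross_product_case(self):
        # I = diag(1,2,3), omega = (1,1,1), omega_dot = 0
        # => tau = (1,1,1) x (1,2,3) = (1, -2, 1)
        kin = _quiescent(T=5)
        kin.omega = np.ones((5, 3))
        inertia = InertiaCholesky(
            raw_for_factor(np.diag(np.sqrt([1.0, 2.0, 3.0]))), trainable=False
        )
        tau = newton_euler_torque(inertia, kin, GravityModel.disabled())
        assert np.allclose(tau, np.tile([1.0, -2.0, 1.0], (5, 1)), atol=1e-9)

    def test_shape_mismatch_raises(self):
        kin = _quiescent()
        kin.omega_dot = np.zeros((50, 3))
        kin.omega = np.zeros((101, 3))
        with pytest.raises(ValueError, match="shape"):
            newton_euler_torque(
                InertiaCholesky(trainable=False), kin, GravityModel.disabled()
            )


class TestGravity:
    def test_disabled_model_returns_zeros(self):
        g = GravityModel.disabled()
        assert np.allclose(gravity_torque(np.linspace(0, 1, 7), g), 0.0)

    def test_sin_peak_at_quarter_turn(self):
        g = GravityModel(a_sin=np.array([1.0, 2.0, 3.0]), a_cos=np.zeros(3))
        out = gravity_torque(np.array([np.pi / 2]), g)
        assert np.allclose(out, [[1.0, 2.0, 3.0]], atol=1e-12)

    def test_hand_trigonometric_evaluation(self):
        g = GravityModel(a_sin=np.array([1.0, 0.0, 2.0]), a_cos=np.array([0.0, 1.0, 0.0]))
        out = gravity_torque(np.array([0.3]), g)
        expected = [np.sin(0.3), np.cos(0.3), 2 * np.sin(0.3)]
        assert np.allclose(out, [expected], atol=1e-12)


class TestPhysicsLoss:
    def test_forward_inverse_self_consistency_on_polynomials(self):
        # polynomial kinematics are transparent to the SG operators, so the
        # loss of the module's own forward torque is numerically zero
        dt = 0.01
        t = np.arange(101) * dt
        omega = np.stack([0.5 * t**2, t**3 - t, 2.0 * t], axis=1)
        omega_dot = np.stack([t, 3 * t**2 - 1.0, np.full_like(t, 2.0)], axis=1)
        kin = KinematicCycle(theta=t.copy(), omega=omega, omega_dot=omega_dot, dt=dt)
        inertia = InertiaCholesky(
            raw_for_factor(np.linalg.cholesky(np.diag([0.12, 0.1, 0.05]))),
            trainable=False,
        )
        g = GravityModel.disabled()
        sg = SGConfig(11, 3, 0)
        from gaitdistill.physics import filter_kinematics

        filter_kinematics(kin, sg)
        tau = newton_euler_torque(inertia, kin, g, use_filtered=True)
        assert physics_loss(tau, kin, inertia, g, sg) < 1e-6

    def test_zero_residual_on_quiescent_cycle(self):
        loss = physics_loss(
            np.zeros((101, 3)),
            _quiescent(),
            InertiaCholesky(trainable=False),
            GravityModel.disabled(),
        )
        assert loss == 0.0

    def test_squared_norm_homogeneity(self):
        tau = np.random.default_rng(5).standard_normal((101, 3))
        kin = _quiescent()
        args = (InertiaCholesky(trainable=False), GravityModel.disabled())
        assert physics_loss(2 * tau, kin, *args) == pytest.approx(
            4 * physics_loss(tau, kin, *args), rel=1e-12
        )

    def test_cycle_shorter_than_window_raises(self):
        kin = _quiescent(T=8)
        with pytest.raises(ValueError):
            physics_loss(
                np.zeros((8, 3)), kin, InertiaCholesky(trainable=False),
                GravityModel.disabled(),
            )

    def test_gradient_wrt_raw_inertia_matches_finite_differences(self, rng):
        cfg = GaitSimConfig(excitation="full_3d", seed=5)
        kin = generate_kinematics(cfg, 0, 0, "hip")
        tau = ground_truth_torque(kin, cfg, "hip").tau
        raw0 = rng.standard_normal(6) * 0.5
        g = GravityModel.disabled()

        def loss_at(raw):
            k = generate_kinematics(cfg, 0, 0, "hip")
            out = physics_loss(tau, k, InertiaCholesky(raw.copy(), trainable=False), g)
            return float(out)

        inertia = InertiaCholesky(raw0.copy())
        kin2 = generate_kinematics(cfg, 0, 0, "hip")
        loss = physics_loss(tau, kin2, inertia, g)
        loss.backward()
        eps = 1e-6
        num = np.array(
            [
                (loss_at(raw0 + eps * e) - loss_at(raw0 - eps * e)) / (2 * eps)
                for e in np.eye(6)
            ]
        )
        assert np.allclose(inertia.raw.grad, num, rtol=1e-4, atol=1e-8)


@pytest.fixture(scope="module")
def excited_cycles():
    cfg = GaitSimConfig(excitation="full_3d", seed=3)
    return cfg, [
        (
            generate_kinematics(cfg, 0, c, "hip"),
            ground_truth_torque(generate_kinematics(cfg, 0, c, "hip"), cfg, "hip").tau,
        )
        for c in range(50)
    ]


class TestFitInertia:
    def test_recovers_generating_tensor_noiseless_within_1pct(self, excited_cycles):
        cfg, cycles = excited_cycles
        fitted, _ = fit_inertia(
            cycles, GravityModel.trainable(np.random.default_rng(5)), seed=1
        )
        i_true = cfg.inertia_matrix()
        err = np.linalg.norm(fitted.i_eff - i_true) / np.linalg.norm(i_true)
        assert err < 0.01

    def test_recovers_within_5pct_under_gyro_noise(self, excited_cycles):
        cfg, cycles = excited_cycles
        noise_rng = np.random.default_rng(7)
        noisy = []
        for kin, tau in cycles:
            k = generate_kinematics(cfg, 0, len(noisy), "hip")
            k.omega = k.omega + 0.01 * noise_rng.standard_normal(k.omega.shape)
            noisy.append((k, tau))
        fitted, _ = fit_inertia(
            noisy, GravityModel.trainable(np.random.default_rng(5)), seed=1
        )
        i_true = cfg.inertia_matrix()
        err = np.linalg.norm(fitted.i_eff - i_true) / np.linalg.norm(i_true)
        assert err < 0.05

    def test_single_axis_excitation_leaves_out_of_axis_entries_flat(self):
        # omega = (0, 0, w(t)): the residual cannot see I[0,1], I[0,2] changes
        # confined to axes never excited, so the loss is flat along them
        dt = 0.01
        t = np.arange(101) * dt
        w = np.sin(2 * np.pi * t)
        omega = np.zeros((101, 3))
        omega[:, 2] = w
        omega_dot = np.zeros((101, 3))
        omega_dot[:, 2] = 2 * np.pi * np.cos(2 * np.pi * t)
        kin = KinematicCycle(theta=t, omega=omega, omega_dot=omega_dot, dt=dt)
        i_true = np.diag([0.12, 0.1, 0.05])
        tau = omega_dot @ i_true + np.cross(omega, omega @ i_true)
        g = GravityModel.disabled()

        def loss_at(raw):
            k = KinematicCycle(theta=t, omega=omega, omega_dot=omega_dot, dt=dt)
            return float(
                physics_loss(tau, k, InertiaCholesky(raw, trainable=False), g)
            )

        raw = raw_for_factor(np.linalg.cholesky(i_true + 1e-6 * np.eye(3)))
        base = loss_at(raw)
        bumped = raw.copy()
        bumped[3] += 0.5  # L[1,0]: only touches the x/y block
        assert loss_at(bumped) == pytest.approx(base, abs=1e-10)

    def test_empty_cycle_list_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_inertia([], GravityModel.disabled())
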