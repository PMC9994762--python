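"""Shell scanning: sampling laws, gamma statistics, verdicts, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sloppyscan as ss
from sloppyscan.ballscan import deviation_vectors
from sloppyscan.models import predictor_experiment


class TestShellRadii:
    def test_equal_segments(self):
        np.testing.assert_allclose(ss.shell_radii(0.3, 3), [0.1, 0.2, 0.3])

    def test_single_shell(self):
        np.testing.assert_allclose(ss.shell_radii(1.0, 1), [1.0])

    @given(
        delta=st.floats(1e-6, 1e3, allow_nan=False),
        l=st.integers(1, 200),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_last_radius_exact(self, delta, l):
        radii = ss.shell_radii(delta, l)
        assert radii[-1] == delta
        assert np.all(np.diff(radii) > 0)


class TestSampleBall:
    def test_containment_and_determinism(self):
        center = np.array([1.0, -2.0, 0.5])
        a = ss.sample_ball(center, 0.7, 500, seed=42)
        b = ss.sample_ball(center, 0.7, 500, seed=42)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.linalg.norm(a - center, axis=1) <= 0.7 + 1e-12)

    @pytest.mark.parametrize("n", [2, 8])
    def test_uniform_ball_radius_law(self, n):
        """Mean distance from the centre is n/(n+1) * radius for uniform-in-ball
        (reference value from the known radial density, checked once against a
        rejection sampler)."""
        center = np.zeros(n)
        pts = ss.sample_ball(center, 1.0, 100_000, seed=7)
        mean_r = np.linalg.norm(pts, axis=1).mean()
        assert mean_r == pytest.approx(n / (n + 1), abs=3e-3)

    def test_rejection_sampler_cross_check(self):
        """Independent oracle: uniform-in-cube rejection sampling, n = 2."""
        rng = np.random.default_rng(123)
        pts = rng.uniform(-1, 1, size=(200_000, 2))
        inside = pts[np.linalg.norm(pts, axis=1) <= 1.0]
        oracle = np.linalg.norm(inside, axis=1).mean()
        ours = np.linalg.norm(ss.sample_ball(np.zeros(2), 1.0, 100_000, 7), axis=1).mean()
        assert ours == pytest.approx(oracle, abs=5e-3)

    def test_invalid_radius(self):
        with pytest.raises(ss.ModelValidationError):
            ss.sample_ball(np.zeros(2), 0.0, 10, 0)


class TestUpdateSampleSize:
    @pytest.mark.parametrize(
        "N, alpha, ratio, n, expected",
        [
            (100_000, 1000, 1.0, 2, 101_000),
            (100_000, 1000, 1.0, 8, 101_000),
            (1000, 10, 2.0, 3, 1080),
        ],
    )
    def test_growth_rule(self, N, alpha, ratio, n, expected):
        assert ss.update_sample_size(N, alpha, ratio, n) == expected

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ss.ModelValidationError):
            ss.update_sample_size(10, 1.0, 0.5, 2)


class TestGamma:
    def test_identical_is_zero(self):
        t = np.arange(3.0)
        y = ss.Trajectory(t, np.ones((3, 1)))
        assert ss.gamma(y, y) == 0.0

    def test_hand_value(self):
        t = np.array([0.0, 1.0])
        a = ss.Trajectory(t, np.array([[1.0], [2.0]]))
        b = ss.Trajectory(t, np.zeros((2, 1)))
        assert ss.gamma(a, b) == 5.0

    def test_swap_symmetry_zero(self, lti_model, toy_experiment):
        a = ss.simulate(lti_model, [0.4, 0.5], toy_experiment)
        b = ss.simulate(lti_model, [0.5, 0.4], toy_experiment)
        assert ss.gamma(a, b) == 0.0

    def test_grid_mismatch(self):
        a = ss.Trajectory(np.arange(3.0), np.zeros((3, 1)))
        b = ss.Trajectory(np.arange(4.0), np.zeros((4, 1)))
        with pytest.raises(ss.ModelValidationError):
            ss.gamma(a, b)


class TestSensitivityIndex:
    @pytest.mark.parametrize(
        "gmin, gmax, expected", [(2.0, 2.0, 0.0), (0.0, 3.0, 1.0), (1.0, 4.0, 0.75)]
    )
    def test_values(self, gmin, gmax, expected):
        assert ss.sensitivity_index(gmin, gmax) == pytest.approx(expected)

    def test_degenerate_is_zero(self):
        assert ss.sensitivity_index(0.0, 0.0) == 0.0

    @given(
        gmin=st.floats(0, 1e6, allow_nan=False),
        spread=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded(self, gmin, spread):
        psi = ss.sensitivity_index(gmin, gmin + spread)
        assert 0.0 <= psi <= 1.0


class TestScan:
    def test_determinism(self, lti_model, toy_experiment):
        cfg = dict(
            theta_ref=np.array([0.4, 1.0]), delta_total=0.2, n_shells=5,
            N0=400, alpha=50.0, seed=9,
        )
        a = ss.scan(lti_model, toy_experiment, ss.ShellScanConfig(**cfg))
        b = ss.scan(lti_model, toy_experiment, ss.ShellScanConfig(**cfg))
        np.testing.assert_array_equal(a.gamma_min, b.gamma_min)
        np.testing.assert_array_equal(a.gamma_max, b.gamma_max)
        np.testing.assert_array_equal(a.argmin_params, b.argmin_params)

    def test_annulus_convention(self, lti_model, toy_experiment):
        """Per-shell extrema lie inside their own annulus."""
        cfg = ss.ShellScanConfig(
            theta_ref=np.array([0.4, 1.0]), delta_total=0.3, n_shells=6,
            N0=500, alpha=0.0, seed=3, refine=False,
        )
        res = ss.scan(lti_model, toy_experiment, cfg)
        edges = np.concatenate([[0.0], res.shell_radii])
        for k in range(6):
            for params in (res.argmin_params[k], res.argmax_params[k]):
                d = np.linalg.norm(params - cfg.theta_ref)
                assert edges[k] < d <= edges[k + 1] + 1e-12

    def test_superset_sampling_monotone(self, lti_model, toy_experiment):
        """Doubling N0 never raises gamma_min nor lowers gamma_max per shell."""
        base = dict(
            theta_ref=np.array([0.4, 1.0]), delta_total=0.3, n_shells=5,
            alpha=100.0, seed=17, refine=False, keep_samples=False,
        )
        small = ss.scan(lti_model, toy_experiment, ss.ShellScanConfig(N0=500, **base))
        big = ss.scan(lti_model, toy_experiment, ss.ShellScanConfig(N0=1000, **base))
        assert np.all(big.gamma_min <= small.gamma_min + 1e-300)
        assert np.all(big.gamma_max >= small.gamma_max - 1e-300)

    def test_psi_bounds_and_gamma_order(self, scan_nonsloppy):
        res = scan_nonsloppy
        assert np.all(res.gamma_min >= 0.0)
        assert np.all(res.gamma_min <= res.gamma_max)
        assert np.all((res.psi >= 0.0) & (res.psi <= 1.0))

    def test_log_scale_samples_positive(self):
        model = ss.make_benchmark("hiv")
        experiment = ss.default_experiment("hiv")
        cfg = ss.ShellScanConfig(
            theta_ref=ss.nominal_theta("hiv"), delta_total=0.3, n_shells=2,
            N0=60, alpha=0.0, seed=5, scale="log", rtol=1e-6, atol=1e-9,
            refine=False,
        )
        res = ss.scan(model, experiment, cfg)
        assert np.all(res.all_samples is not None)
        assert np.all(res.argmin_params > 0)
        # log-scale distances: deviation vectors live in log space within radius
        dev = deviation_vectors(res, "argmax")
        assert np.all(np.linalg.norm(dev, axis=1) <= 0.3 + 1e-9)

    def test_result_serialisation(self, scan_nonsloppy, tmp_path):
        df = scan_nonsloppy.to_frame()
        assert list(df.columns) == ["delta_k", "gamma_min", "gamma_max", "psi", "N_k"]
        payload = scan_nonsloppy.to_json()
        assert "shell_radii" in payload


class TestClassify:
    def test_unidentifiable_radius_matches_swap_distance(self, scan_unidentifiable):
        v = ss.classify(scan_unidentifiable)
        assert not v.locally_identifiable
        # swap image at sqrt(0.02) ~ 0.1414; reported shell centre within a shell width
        assert v.unidentifiability_radius == pytest.approx(np.sqrt(0.02), abs=0.01)

    def test_identifiable_nonsloppy(self, scan_nonsloppy):
        v = ss.classify(scan_nonsloppy, eps=1e-3, delta=0.3)
        assert v.locally_identifiable and not v.eps_delta_sloppy

    def test_identifiable_sloppy(self, scan_sloppy):
        v = ss.classify(scan_sloppy, eps=1e-3, delta=0.3)
        assert v.locally_identifiable and v.eps_delta_sloppy

    def test_eps_delta_contract(self, scan_nonsloppy):
        with pytest.raises(ss.ModelValidationError):
            ss.classify(scan_nonsloppy, eps=0.3, delta=0.3)

    def test_verdict_consistency(self, scan_unidentifiable, scan_nonsloppy):
        for res in (scan_unidentifiable, scan_nonsloppy):
            v = ss.classify(res)
            assert v.locally_identifiable == (v.unidentifiability_radius is None)


class TestProfiles:
    def test_zero_column_profile_flat_zero(self):
        X = np.column_stack([np.linspace(1, 2, 8), np.zeros(8)])
        model = ss.linear_predictor(X)
        cfg = ss.ShellScanConfig(
            theta_ref=np.array([1.0, 1.0]), delta_total=0.5, n_shells=4,
            N0=800, alpha=0.0, seed=21, refine=False,
        )
        exp = predictor_experiment(model)
        res = ss.scan(model, exp, cfg)
        # moving only the dead coefficient leaves the output unchanged
        y_ref = ss.simulate(model, cfg.theta_ref, exp)
        y_moved = ss.simulate(model, cfg.theta_ref + np.array([0.0, 0.4]), exp)
        assert ss.gamma(y_ref, y_moved) == 0.0
        # and its binned gamma_min profile stays deep below the live axis
        profiles = ss.per_parameter_profiles(res)
        a2 = profiles["a2"].dropna(subset=["gamma_min"])
        assert a2["gamma_min"].max() < 1e-3 * res.gamma_max_global
        sens, insens = ss.rank_parameters(profiles, res.gamma_max_global)
        assert insens[0] == "a2"
        assert sens == ["a1"]

    def test_symmetric_profiles_exchangeable(self, lti_model, toy_experiment):
        """With theta* on the diagonal and equal initial conditions the two
        rates play exchangeable roles, so their binned profiles agree within
        Monte-Carlo scatter."""
        cfg = ss.ShellScanConfig(
            theta_ref=np.array([0.45, 0.45]), delta_total=0.2, n_shells=4,
            N0=20000, alpha=0.0, seed=13, refine=False,
        )
        res = ss.scan(lti_model, toy_experiment, cfg)
        profiles = ss.per_parameter_profiles(res, n_bins=6)
        p1, p2 = profiles["theta1"], profiles["theta2"]
        solid = (p1["count"].to_numpy() >= 200) & (p2["count"].to_numpy() >= 200)
        ratio = p1["gamma_max"].to_numpy()[solid] / p2["gamma_max"].to_numpy()[solid]
        assert solid.sum() >= 4
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_requires_samples(self, lti_model, toy_experiment):
        cfg = ss.ShellScanConfig(
            theta_ref=np.array([0.4, 1.0]), delta_total=0.2, n_shells=2,
            N0=50, alpha=0.0, seed=1, keep_samples=False, refine=False,
        )
        res = ss.scan(lti_model, toy_experiment, cfg)
        with pytest.raises(ss.ModelValidationError):
            ss.per_parameter_profiles(res)


class TestDirectionCosines:
    def test_identical_vectors(self):
        V = np.tile([1.0, 2.0], (3, 1))
        np.testing.assert_allclose(ss.direction_cosine_matrix(V), np.ones((3, 3)))

    def test_orthogonal_pair(self):
        C = ss.direction_cosine_matrix(np.array([[1.0, 0.0], [0.0, 2.0]]))
        assert C[0, 1] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_zero_vector_flagged(self):
        C = ss.direction_cosine_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert np.isnan(C[1, 0]) and np.isnan(C[0, 1])

    def test_requires_two_vectors(self):
        with pytest.raises(ss.ModelValidationError):
            ss.direction_cosine_matrix(np.array([[1.0, 2.0]]))
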