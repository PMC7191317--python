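import numpy as np
import pytest

from atriagp.design import latin_hypercube
from atriagp.emulator import train
from atriagp.sensitivity import (
    UncertainInputs,
    emulator_mc_oracle,
    first_order_index,
    main_effect,
    mc_oracle,
    output_uncertainty,
    restitution_surface,
    sensitivity_table,
    total_effect_index,
    uncertainty_sweep,
)


def _measure(p, variances=None, mean=0.5):
    if variances is None:
        variances = [0.02] * p
    return UncertainInputs(
        tuple(f"x{i+1}" for i in range(p)),
        np.full(p, mean),
        np.asarray(variances, dtype=float),
    )


class TestClosedFormRecovery:
    def test_single_active_input(self, linear_emulator):
        u = _measure(2)
        assert first_order_index(linear_emulator, u, 0) == pytest.approx(1.0, abs=1e-6)
        assert first_order_index(linear_emulator, u, 1) == pytest.approx(0.0, abs=1e-6)

    def test_linear_two_input_variance_shares(self):
        X = latin_hypercube(30, 2, seed=3).X
        em = train(X, 1.0 * X[:, 0] + 2.0 * X[:, 1], seed=0, restarts=4)
        u = _measure(2, [0.02, 0.04])
        expect1 = 1.0 * 0.02 / (1.0 * 0.02 + 4.0 * 0.04)
        assert first_order_index(em, u, 0) == pytest.approx(expect1, abs=1e-6)
        assert first_order_index(em, u, 1) == pytest.approx(1 - expect1, abs=1e-6)
        # additive model: total effects equal first-order effects
        assert total_effect_index(em, u, 0) == pytest.approx(expect1, abs=1e-6)
        assert total_effect_index(em, u, 1) == pytest.approx(1 - expect1, abs=1e-6)

    def test_pure_interaction_decomposition(self, interaction_emulator):
        u = _measure(2)
        assert first_order_index(interaction_emulator, u, 0) == pytest.approx(0.0, abs=1e-3)
        assert total_effect_index(interaction_emulator, u, 0) == pytest.approx(1.0, abs=1e-3)
        assert total_effect_index(interaction_emulator, u, 1) == pytest.approx(1.0, abs=1e-3)

    def test_fixed_input_rejected(self, linear_emulator):
        u = _measure(2).fix(1)
        with pytest.raises(ValueError):
            first_order_index(linear_emulator, u, 1)
        with pytest.raises(ValueError):
            total_effect_index(linear_emulator, u, 1)


class TestSobolInequalities:
    @pytest.mark.parametrize("seed", range(6))
    def test_sum_bounds_on_random_emulators(self, seed):
        """0 <= S_w, sum S_w <= 1 <= sum S_Tw (within tolerance)."""
        rng = np.random.default_rng(seed)
        P = 3
        X = latin_hypercube(25, P, seed=seed).X
        a = rng.normal(size=P)
        y = X @ a + np.sin(3 * X[:, 0]) * X[:, 1] + 0.5 * X[:, 2] ** 2
        em = train(X, y, seed=seed, restarts=3)
        u = _measure(P)
        s = np.array([first_order_index(em, u, i) for i in range(P)])
        st = np.array([total_effect_index(em, u, i) for i in range(P)])
        tol = 1e-6
        assert np.all(s >= -tol)
        assert s.sum() <= 1.0 + 1e-3
        assert st.sum() >= s.sum() - 1e-3

    def test_indices_invariant_to_output_rescaling(self):
        X = latin_hypercube(25, 2, seed=12).X
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        u = _measure(2)
        em1 = train(X, y, seed=0, restarts=3)
        em2 = train(X, -4.0 * y + 11.0, seed=0, restarts=3)
        for w in range(2):
            assert first_order_index(em1, u, w) == pytest.approx(
                first_order_index(em2, u, w), abs=1e-5
            )
            assert total_effect_index(em1, u, w) == pytest.approx(
                total_effect_index(em2, u, w), abs=1e-5
            )


class TestMonteCarloOracle:
    def test_deterministic_under_seed(self, interaction_emulator):
        u = _measure(2)
        a = emulator_mc_oracle(interaction_emulator, u, n=2000, seed=9)
        b = emulator_mc_oracle(interaction_emulator, u, n=2000, seed=9)
        assert np.array_equal(a["S"], b["S"])
        assert np.array_equal(a["ST"], b["ST"])

    def test_linear_closed_form_agreement(self):
        u = _measure(2, [0.02, 0.04])
        a = np.array([1.0, 1.0])

        def f(X):
            return X @ a

        est = mc_oracle(f, u, n=100_000, seed=3)
        expect = np.array([0.02, 0.04]) / 0.06
        assert np.all(np.abs(est["S"] - expect) < np.maximum(0.01, 3 * est["S_se"]))
        assert np.all(np.abs(est["ST"] - expect) < np.maximum(0.01, 3 * est["ST_se"]))

    def test_pure_interaction_first_order_vanishes(self):
        u = _measure(2)

        def f(X):
            return (X[:, 0] - 0.5) * (X[:, 1] - 0.5)

        est = mc_oracle(f, u, n=100_000, seed=4)
        assert np.abs(est["S"]).max() < 0.01

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            mc_oracle(lambda X: X[:, 0], _measure(1), n=10)

    @pytest.mark.parametrize("seed", range(20))
    def test_analytic_matches_oracle_on_random_fixtures(self, seed):
        """Closed-form indices agree with pick-freeze MC within 3 s.e."""
        rng = np.random.default_rng(100 + seed)
        P = int(rng.integers(2, 4))
        X = latin_hypercube(22, P, seed=seed).X
        a = rng.normal(size=P)
        y = X @ a
        if rng.random() < 0.7:
            i, j = rng.choice(P, 2, replace=False)
            y = y + rng.normal() * np.sin(3 * X[:, i]) * X[:, j]
        em = train(X, y, seed=seed, restarts=3)
        u = _measure(P, rng.uniform(0.01, 0.06, P))
        est = emulator_mc_oracle(em, u, n=4000, seed=seed)
        for w in range(P):
            s_an = first_order_index(em, u, w)
            t_an = total_effect_index(em, u, w)
            assert abs(s_an - est["S"][w]) <= 3 * est["S_se"][w] + 1e-6
            assert abs(t_an - est["ST"][w]) <= 3 * est["ST_se"][w] + 1e-6


class TestMainEffects:
    def test_linear_main_effect_is_the_line(self, linear_emulator):
        u = _measure(2)
        c = main_effect(linear_emulator, u, 0)
        assert np.allclose(c.expectation, 2 * c.grid + 1, atol=1e-5)
        assert c.gradient_at_center == pytest.approx(2.0, abs=1e-4)
        assert c.sign == 1

    def test_negative_slope_gives_negative_sign(self):
        X = latin_hypercube(20, 2, seed=5).X
        em = train(X, -3.0 * X[:, 1], seed=0, restarts=3)
        c = main_effect(em, _measure(2), 1)
        assert c.sign == -1

    def test_grid_outside_unit_interval_rejected(self, linear_emulator):
        with pytest.raises(ValueError):
            main_effect(linear_emulator, _measure(2), 0, grid=np.array([-0.2, 0.5]))

    def test_sensitivity_table_shape_and_signs(self, linear_emulator):
        res = sensitivity_table(linear_emulator, _measure(2), output="y")
        assert res.inputs == ("x1", "x2")
        assert res.signs[0] == 1
        assert res.sum_abs_s1 == pytest.approx(1.0, abs=1e-5)
        assert res.frame().shape[0] == 2


class TestOutputUncertainty:
    def test_linear_propagation_closed_form(self):
        X = latin_hypercube(30, 2, seed=3).X
        a = np.array([1.0, 2.0])
        em = train(X, X @ a + 3.0, seed=0, restarts=3)
        u = _measure(2, [0.02, 0.04])
        res = output_uncertainty(em, u)
        assert res["mean"] == pytest.approx(3.0 + a @ u.means, abs=1e-6)
        assert res["variance"] == pytest.approx(float(a**2 @ u.variances), abs=1e-6)

    def test_doubling_input_variance_doubles_output_variance(self):
        X = latin_hypercube(30, 2, seed=3).X
        em = train(X, X[:, 0] + X[:, 1], seed=0, restarts=3)
        v1 = output_uncertainty(em, _measure(2, [0.01, 0.01]))["variance"]
        v2 = output_uncertainty(em, _measure(2, [0.02, 0.02]))["variance"]
        assert v2 == pytest.approx(2 * v1, rel=1e-4)

    def test_all_fixed_inputs_leave_only_emulator_variance(self, linear_emulator):
        u = _measure(2).fix_all(0.5)
        res = output_uncertainty(linear_emulator, u)
        assert res["variance"] == 0.0
        assert res["emulator_variance_at_mean"] >= 0.0

    def test_uncertainty_sweep_monotone_for_linear_emulator(self, linear_emulator):
        base = _measure(2)
        sweep = uncertainty_sweep(linear_emulator, base, sds=[0.05, 0.1, 0.2], means=[0.5])
        assert np.all(np.diff(sweep["cv"].values) > 0)


class TestRestitutionSurface:
    @pytest.fixture(scope="class")
    def toy_stage2_emulator(self):
        """Emulator of toy APD_90 on a (3 inputs + DI) Stage-2-style space."""
        from atriagp.pipeline import StageConfig, run_design

        cfg = StageConfig(model="toy", stage=2, seed=3, n_beats=4)
        data = run_design(cfg.resolved(), 60, seed=3)
        em = train(data.X_kept, data.output_column("APD_90"), seed=0, restarts=3)
        return em, data.space

    def test_band_nonnegative_and_small_at_design_points(self, toy_stage2_emulator):
        em, space = toy_stage2_emulator
        fixed = UncertainInputs.from_space(space).fix_all(em.X[0])
        surf = restitution_surface(
            em, fixed, np.array([em.X[0][space.names.index("DI")]]),
            "apd_scale", np.array([em.X[0][space.names.index("apd_scale")]]),
        )
        assert np.all(surf["band_halfwidth"] >= 0)
        sd_scale = np.sqrt(em.hyper.sigma2) * em.y_std
        assert surf["band_halfwidth"][0, 0] < 0.05 * sd_scale + 1e-6

    def test_toy_restitution_mean_nondecreasing_in_di(self, toy_stage2_emulator):
        em, space = toy_stage2_emulator
        fixed = UncertainInputs.from_space(space).fix_all(0.5)
        surf = restitution_surface(
            em, fixed, np.linspace(0.05, 0.95, 10), "apd_scale", np.array([0.5])
        )
        apd = surf["mean"][:, 0]
        assert np.all(np.diff(apd) > -1.0)  # monotone up to emulator noise
        assert apd[-1] > apd[0]

    def test_di_and_second_input_must_differ(self, toy_stage2_emulator):
        em, space = toy_stage2_emulator
        fixed = UncertainInputs.from_space(space).fix_all(0.5)
        with pytest.raises(ValueError):
            restitution_surface(em, fixed, np.array([0.5]), "DI", np.array([0.5]))
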