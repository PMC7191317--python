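import numpy as np
import pytest

from atriagp.design import latin_hypercube
from atriagp.emulator import (
    GPEmulator,
    _neg_restricted_loglik,
    rbf_covariance,
    train,
    validate,
)


class TestRBFCovariance:
    def test_zero_distance_is_one(self):
        x = np.array([0.3, 0.7])
        assert rbf_covariance(x, x, np.array([1.0, 1.0])) == 1.0

    def test_unit_lengthscale_distance(self):
        # one input, |x - x'| = delta -> exp(-1)
        assert rbf_covariance(
            np.array([0.0]), np.array([0.5]), np.array([0.5])
        ) == pytest.approx(np.exp(-1.0))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, d = rng.uniform(0, 1, 3), rng.uniform(0, 1, 3), rng.uniform(0.1, 2, 3)
            c1 = rbf_covariance(a, b, d)
            assert c1 == rbf_covariance(b, a, d)
            assert 0.0 < c1 <= 1.0

    def test_invalid_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            rbf_covariance(np.array([0.0]), np.array([1.0]), np.array([-1.0]))


class TestTraining:
    def test_linear_target_captured_by_mean(self, linear_emulator):
        rng = np.random.default_rng(5)
        Xt = rng.uniform(0, 1, (20, 2))
        mean, _ = linear_emulator.predict(Xt, full=True)
        assert np.abs(mean - (2 * Xt[:, 0] + 1)).max() < 1e-6

    def test_interpolates_design_points(self):
        X = latin_hypercube(15, 2, seed=9).X
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        em = train(X, y, seed=1, restarts=4)
        mean, var = em.predict(X, full=True)
        # interpolation holds up to nugget-induced smoothing (nugget 1e-7
        # amplified by the near-singular correlation matrix)
        assert np.abs(mean - y).max() < 1e-3 * max(1.0, np.abs(y).max())
        assert var.max() <= 10 * em.nugget * em.hyper.sigma2 * em.y_std**2 + 1e-12

    def test_beats_linear_baseline_on_smooth_nonlinear_target(self):
        X = latin_hypercube(20, 1, seed=2).X
        y = np.sin(2 * np.pi * X[:, 0])
        em = train(X, y, seed=0, restarts=4)
        xs = np.linspace(0, 1, 60)[:, None]
        truth = np.sin(2 * np.pi * xs[:, 0])
        gp_rmse = np.sqrt(np.mean((em.predict(xs, full=True)[0] - truth) ** 2))
        # ordinary least-squares linear baseline
        A = np.column_stack([np.ones(20), X[:, 0]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_rmse = np.sqrt(np.mean((coef[0] + coef[1] * xs[:, 0] - truth) ** 2))
        assert gp_rmse < 0.1 * np.std(truth)
        assert gp_rmse < ols_rmse

    def test_best_restart_is_returned(self):
        X = latin_hypercube(15, 2, seed=4).X
        y = np.cos(4 * X[:, 0]) * X[:, 1]
        em = train(X, y, seed=3, restarts=6)
        logliks = [e["loglik"] for e in em.training_log]
        ys = (y - em.y_mean) / em.y_std
        returned = -_neg_restricted_loglik(np.log(em.hyper.delta), X, ys, em.nugget)
        assert returned == pytest.approx(max(logliks), abs=1e-6)
        # and it beats randomly drawn length scales
        rng = np.random.default_rng(0)
        for _ in range(5):
            other = -_neg_restricted_loglik(
                np.log(10.0 ** rng.uniform(-1, 1, 2)), X, ys, em.nugget
            )
            assert returned >= other - 1e-9

    def test_affine_output_rescaling(self):
        X = latin_hypercube(18, 2, seed=6).X
        y = np.sin(3 * X[:, 0]) + X[:, 1]
        em1 = train(X, y, seed=2, restarts=3)
        em2 = train(X, 5.0 * y + 7.0, seed=2, restarts=3)
        Xt = np.array([[0.2, 0.8], [0.6, 0.3]])
        m1, v1 = em1.predict(Xt, full=True)
        m2, v2 = em2.predict(Xt, full=True)
        assert np.allclose(m2, 5.0 * m1 + 7.0, atol=1e-6)
        assert np.allclose(v2, 25.0 * v1, rtol=1e-2, atol=1e-10)

    def test_large_nugget_shrinks_to_linear_fit(self):
        X = latin_hypercube(25, 1, seed=8).X
        y = np.sin(2 * np.pi * X[:, 0]) + 2 * X[:, 0]
        em = train(X, y, nugget=1e4, seed=0, restarts=3)
        ys = (y - em.y_mean) / em.y_std
        A = np.column_stack([np.ones(25), X[:, 0]])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        xs = np.linspace(0, 1, 20)[:, None]
        mean, _ = em.predict(xs, full=True)
        lin = (coef[0] + coef[1] * xs[:, 0]) * em.y_std + em.y_mean
        assert np.abs(mean - lin).max() < 0.05 * np.std(y)

    def test_variance_grows_away_from_design(self):
        X = latin_hypercube(10, 2, seed=1).X
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        em = train(X, y, seed=0, restarts=3)
        _, v_in = em.predict(X[0])
        _, v_out = em.predict(np.array([5.0, 5.0]))  # far extrapolation
        assert v_out > 100 * max(v_in, 1e-12)

    def test_batch_prediction_matches_pointwise(self, linear_emulator):
        Xt = np.array([[0.1, 0.2], [0.9, 0.4], [0.5, 0.5]])
        mb, vb = linear_emulator.predict(Xt, full=True)
        for i in range(3):
            mi, vi = linear_emulator.predict(Xt[i])
            assert mi == pytest.approx(mb[i])
            assert vi == pytest.approx(vb[i], abs=1e-12)

    def test_input_validation(self):
        X = latin_hypercube(10, 2, seed=0).X
        with pytest.raises(ValueError):
            train(X, np.ones(10))  # constant output
        with pytest.raises(ValueError):
            train(np.vstack([X, X[:1]]), np.arange(11.0))  # duplicate row
        with pytest.raises(ValueError):
            train(X[:4], np.arange(4.0))  # too few runs

    def test_json_round_trip(self, linear_emulator, tmp_path):
        path = tmp_path / "em.json"
        linear_emulator.save(path)
        em2 = GPEmulator.load(path)
        Xt = np.array([[0.3, 0.6]])
        assert em2.predict(Xt, full=True)[0] == pytest.approx(
            linear_emulator.predict(Xt, full=True)[0]
        )


class TestValidationMetrics:
    def test_perfect_emulator_scores_zero(self, linear_emulator):
        X = np.array([[0.2, 0.5], [0.7, 0.1]])
        y = 2 * X[:, 0] + 1
        rep = validate(linear_emulator, X, y)
        assert rep.mape == pytest.approx(0.0, abs=1e-6)
        assert np.all(rep.ise < 1e-3)

    def test_mape_fixture_arithmetic(self):
        """y_s=(100,110), y_e=(105,110): MAPE = 100 * 2.5 / 105."""
        em = _FakeEmulator(np.array([105.0, 110.0]), np.array([4.0, 4.0]))
        rep = validate(em, np.zeros((2, 1)), np.array([100.0, 110.0]))
        assert rep.mape == pytest.approx(100.0 * 2.5 / 105.0)

    def test_ise_standard_deviation_convention(self):
        """|error| = 1 with posterior variance 4 gives ISE = 0.5."""
        em = _FakeEmulator(np.array([101.0]), np.array([4.0]))
        rep = validate(em, np.zeros((1, 1)), np.array([100.0]))
        assert rep.ise[0] == pytest.approx(0.5)
        rep_var = validate(
            em, np.zeros((1, 1)), np.array([100.0]), ise_denominator="var"
        )
        assert rep_var.ise[0] == pytest.approx(0.25)

    def test_zero_mean_denominator_rejected(self):
        em = _FakeEmulator(np.array([1.0, -1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ZeroDivisionError):
            validate(em, np.zeros((2, 1)), np.array([1.0, -1.0]))


class _FakeEmulator:
    """Minimal predict() stand-in for metric arithmetic tests (synthetic)."""

    def __init__(self, means, variances):
        self._m = means
        self._v = variances

    def predict(self, X, full=False):
        return self._m, self._v
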