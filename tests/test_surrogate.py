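"""Kriging surface: GCV behaviour, uncertainty, optima, cross-checks."""
import numpy as np
import pytest

from autoassay import (Axis, Condition, ParameterSpace, fit_surface,
                       predict_with_uncertainty, slice_grid,
                       space_filling_design, surface_optimum)
from autoassay.design import denormalize_points, normalize_points
from autoassay.errors import (InsufficientDataError, OutOfRangeError,
                              SingularDesignError)
from autoassay.surrogate import SurfaceModel, _kernel


def smooth_f(c):
    return np.sin(3 * c.values["a"]) + np.cos(2 * c.values["b"]) \
        + c.values["a"] * c.values["b"]


@pytest.fixture(scope="module")
def smooth_fit():
    space = ParameterSpace((Axis("a", 0.0, 1.0), Axis("b", 0.0, 1.0)))
    design = space_filling_design(space, 40, seed=3)
    y = [smooth_f(c) for c in design.conditions]
    model = fit_surface(space, design.conditions, y)
    return space, design, np.asarray(y), model


class TestFit:
    def test_noiseless_near_interpolation(self, smooth_fit):
        """GCV drives the smoothing to ~0 on noise-free smooth data."""
        _, design, y, model = smooth_fit
        preds = predict_with_uncertainty(model, design.conditions)
        for p, yy in zip(preds, y):
            assert abs(p.mean - yy) < 1e-3

    def test_pure_noise_shrinks_to_grand_mean(self, space2d):
        """With zero signal the surface flattens toward the mean response."""
        rng = np.random.default_rng(11)
        design = space_filling_design(space2d, 50, seed=8)
        y = rng.normal(size=50)
        model = fit_surface(space2d, design.conditions, y)
        preds = predict_with_uncertainty(model, design.conditions)
        assert np.var([p.mean for p in preds]) <= 0.10 * np.var(y)

    def test_constant_response_predicts_constant(self, space2d):
        design = space_filling_design(space2d, 10, seed=2)
        model = fit_surface(space2d, design.conditions, np.full(10, 3.7))
        grid = denormalize_points(space2d, np.random.default_rng(0).uniform(size=(20, 2)))
        preds = predict_with_uncertainty(model, grid)
        for p in preds:
            assert abs(p.mean - 3.7) < 1e-8

    def test_lengthscale_recovery_from_gp_draws(self):
        """CV-selected length scale within 3x of truth in >=80% of replicates."""
        space = ParameterSpace((Axis("x", 0.0, 1.0),))
        ls_true = 0.2
        X = np.linspace(0, 1, 60)[:, None]
        K = _kernel(X, X, np.array([ls_true])) + 1e-10 * np.eye(60)
        L = np.linalg.cholesky(K)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            y = L @ rng.normal(size=60) + 0.05 * rng.normal(size=60)
            conds = denormalize_points(space, X)
            model = fit_surface(space, conds, y)
            ratio = model.lengthscales[0] / ls_true
            hits += (1 / 3 <= ratio <= 3)
        assert hits >= 0.8 * n_rep

    def test_insufficient_data(self, space2d):
        design = space_filling_design(space2d, 3, seed=1)
        with pytest.raises(InsufficientDataError):
            fit_surface(space2d, design.conditions, [1.0, 2.0, 3.0])

    def test_singular_design(self, space2d):
        conds = [Condition({"a": 0.5, "b": 0.5}, id=str(i)) for i in range(6)]
        with pytest.raises(SingularDesignError):
            fit_surface(space2d, conds, np.arange(6.0))


class TestPredict:
    def test_finite_mean_and_se_everywhere(self, smooth_fit):
        space, _, _, model = smooth_fit
        grid = denormalize_points(
            space, np.random.default_rng(5).uniform(size=(100, 2)))
        preds = predict_with_uncertainty(model, grid)
        assert all(np.isfinite(p.mean) and np.isfinite(p.se) and p.se >= 0
                   for p in preds)

    def test_se_smaller_at_training_point_than_far_away(self, space2d):
        design = space_filling_design(space2d, 12, seed=9)
        # cluster data in one corner so the far corner is data-starved
        X = 0.3 * normalize_points(space2d, design.conditions)
        conds = denormalize_points(space2d, X)
        y = [np.sin(4 * x[0]) + x[1] for x in X]
        model = fit_surface(space2d, conds, y)
        at_train = predict_with_uncertainty(model, [conds[0]])[0]
        far = predict_with_uncertainty(
            model, [Condition({"a": 1.0, "b": 1.0})])[0]
        centroid = denormalize_points(space2d, X.mean(axis=0)[None, :])
        at_centroid = predict_with_uncertainty(model, centroid)[0]
        assert at_train.se <= far.se
        assert far.se >= at_centroid.se

    def test_out_of_bounds_point(self, smooth_fit):
        space, _, _, model = smooth_fit
        with pytest.raises(OutOfRangeError):
            predict_with_uncertainty(model, [Condition({"a": 1.5, "b": 0.5})])

    def test_mean_invariant_to_scaling_roundtrip(self):
        """Predicting at c and at denorm(norm(c)) gives the same mean."""
        space = ParameterSpace((Axis("c", 0.1, 100.0, "log"),
                                Axis("pH", 4.0, 9.0)))
        design = space_filling_design(space, 15, seed=6)
        y = [np.log10(c.values["c"]) + 0.3 * c.values["pH"]
             for c in design.conditions]
        model = fit_surface(space, design.conditions, y)
        conds = design.conditions[:5]
        X = normalize_points(space, conds)
        round_tripped = denormalize_points(space, X)
        p1 = predict_with_uncertainty(model, conds)
        p2 = predict_with_uncertainty(model, round_tripped)
        for a, b in zip(p1, p2):
            assert a.mean == pytest.approx(b.mean, rel=1e-8, abs=1e-10)

    def test_agreement_with_independent_gp_implementation(self, space2d):
        """Fixed-hyperparameter predictions match sklearn's GP regression."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(25, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        ls, lam = np.array([0.4, 0.4]), 1e-6
        ours = SurfaceModel(space=space2d, X=X, y=y, lengthscales=ls,
                            smoothing=lam, mu=0.0)
        kernel = sklearn_gp.kernels.Matern(length_scale=ls, nu=2.5,
                                           length_scale_bounds="fixed")
        ref = sklearn_gp.GaussianProcessRegressor(
            kernel=kernel, alpha=lam, optimizer=None).fit(X, y)
        Xq = rng.uniform(size=(30, 2))
        mean_ours, _ = ours.predict(Xq)
        np.testing.assert_allclose(mean_ours, ref.predict(Xq),
                                   rtol=1e-6, atol=1e-8)


class TestOptimum:
    def test_recovers_concave_quadratic_maximum(self, space2d):
        m_true = np.array([0.35, 0.65])
        design = space_filling_design(space2d, 35, seed=4)
        X = normalize_points(space2d, design.conditions)
        y = -np.sum((X - m_true) ** 2, axis=1)
        model = fit_surface(space2d, design.conditions, y)
        cond, _ = surface_optimum(model, maximize=True, seed=1)
        x_opt = normalize_points(space2d, [cond])[0]
        assert np.linalg.norm(x_opt - m_true) < 0.05

    def test_monotone_response_pushes_optimum_to_bound(self):
        space = ParameterSpace((Axis("x", 0.0, 2.0),))
        design = space_filling_design(space, 12, seed=2)
        y = [c.values["x"] for c in design.conditions]
        model = fit_surface(space, design.conditions, y)
        cond, _ = surface_optimum(model, maximize=True, seed=0)
        assert cond.values["x"] == pytest.approx(2.0, abs=0.02)

    def test_minimize_on_negated_equals_maximize(self, space2d):
        design = space_filling_design(space2d, 30, seed=10)
        X = normalize_points(space2d, design.conditions)
        y = np.sin(3 * X[:, 0]) * np.cos(2 * X[:, 1])
        m1 = fit_surface(space2d, design.conditions, y)
        m2 = fit_surface(space2d, design.conditions, -y)
        c1, _ = surface_optimum(m1, maximize=True, seed=7)
        c2, _ = surface_optimum(m2, maximize=False, seed=7)
        x1 = normalize_points(space2d, [c1])[0]
        x2 = normalize_points(space2d, [c2])[0]
        assert np.linalg.norm(x1 - x2) < 1e-3


def test_slice_grid_is_smooth_and_finite(smooth_fit):
    _, _, _, model = smooth_fit
    df = slice_grid(model, "a", "b", n=50)
    assert len(df) == 2500
    assert np.isfinite(df["mean"]).all() and np.isfinite(df["se"]).all()


def test_model_json_roundtrip(tmp_path, smooth_fit):
    space, design, _, model = smooth_fit
    path = tmp_path / "model.json"
    model.to_json(path)
    model2 = SurfaceModel.from_json(path)
    p1 = predict_with_uncertainty(model, design.conditions[:5])
    p2 = predict_with_uncertainty(model2, design.conditions[:5])
    for a, b in zip(p1, p2):
        assert a.mean == pytest.approx(b.mean, rel=1e-10)
        assert a.se == pytest.approx(b.se, rel=1e-8, abs=1e-12)
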