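"""Regression machinery: OLS correctness, AARD, the sklearn estimator."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

import sccosol as sc
from sccosol.fitting import CollinearityError


class TestAard:
    def test_perfect_fit_is_zero(self):
        y = np.array([1e-4, 2e-4, 3e-4])
        assert sc.aard(y, y) == 0.0

    def test_hand_computed_value(self):
        # (100/2) * (0.1 + 0.1)
        assert sc.aard([1e-4, 2e-4], [1.1e-4, 1.8e-4]) == \
            pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        ye = rng.uniform(1e-5, 1e-3, 20)
        yc = ye * rng.uniform(0.8, 1.2, 20)
        assert sc.aard(ye, yc) == pytest.approx(
            sc.aard(1e3 * ye, 1e3 * yc), rel=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            sc.aard([], [])
        with pytest.raises(ValueError):
            sc.aard([0.0, 1e-4], [1e-4, 1e-4])
        with pytest.raises(ValueError):
            sc.aard([1e-4], [1e-4, 2e-4])


@pytest.mark.parametrize("model_id", sc.MODEL_IDS)
@pytest.mark.parametrize("objective", ["linear", "relative"])
def test_exact_recovery_on_noiseless_data(noiseless, model_id, objective):
    """Noise-free model-generated surfaces give back (a, b, c) exactly."""
    cfg, ds = noiseless[model_id]
    res = sc.fit(model_id, ds, cfg.provider_id, objective)
    np.testing.assert_allclose(res.params.as_array(),
                               cfg.true_params.as_array(), rtol=1e-6)
    assert res.aard_percent == pytest.approx(0.0, abs=1e-6)


def test_ols_solution_is_the_sse_minimum(decitabine, reference):
    """Independent check of the linear fit against a numeric optimizer.

    The fitted triple must satisfy the normal equations (zero gradient)
    and beat a Powell polish started away from the solution.
    """
    model = sc.get_model("kj")
    T, P, y = decitabine.arrays()
    rho = reference.rho_mass(T, P)
    A = model.design_row(T, rho)
    resp = model.response(T, P, y, rho, 228.21)
    res = sc.fit("kj", decitabine, reference, "linear")
    coef = res.params.as_array()
    # orthogonality of residuals to the design columns
    grad = A.T @ (resp - A @ coef)
    assert np.max(np.abs(grad)) < 1e-6 * np.abs(resp).sum()

    def sse(p):
        return float(np.sum((resp - A @ p) ** 2))

    polish = minimize(sse, coef * np.array([1.1, 0.9, 1.2]),
                      method="Powell",
                      options={"xtol": 1e-12, "ftol": 1e-14,
                               "maxiter": 10000})
    assert sse(coef) <= polish.fun * (1 + 1e-9)


def test_single_temperature_is_collinear(reference):
    recs = tuple(sc.SolubilityRecord(T=318.0, P=p, y=1e-4 * (1 + i))
                 for i, p in enumerate((12.0, 16.0, 20.0, 24.0)))
    ds = sc.SolubilityDataset("x", 228.21, recs)
    with pytest.raises(CollinearityError):
        sc.fit("kj", ds, reference)


def test_refit_on_own_predictions_is_idempotent(decitabine, reference):
    from dataclasses import replace
    res = sc.fit("mst", decitabine, reference, "linear")
    recs = tuple(replace(r, y=c, u_y=None) for r, (_, c) in
                 zip(decitabine.records, res.residuals))
    refit = sc.fit("mst", replace(decitabine, records=recs), reference)
    np.testing.assert_allclose(refit.params.as_array(),
                               res.params.as_array(), rtol=1e-8)


def test_fit_all_sorted_and_kj_lowest(decitabine):
    results = sc.fit_all(decitabine, "reference", "relative")
    aards = [r.aard_percent for r in results]
    assert aards == sorted(aards)
    assert results[0].model_id == "kj"
    assert {r.model_id for r in results} == set(sc.MODEL_IDS)


def test_relative_objective_never_worse_in_aard(decitabine):
    for mid in sc.MODEL_IDS:
        lin = sc.fit(mid, decitabine, "reference", "linear")
        rel = sc.fit(mid, decitabine, "reference", "relative")
        assert rel.aard_percent <= lin.aard_percent + 1e-9


class TestSklearnEstimator:
    def test_clone_and_params_round_trip(self):
        est = sc.SolubilityCorrelation(model="kj", objective="relative")
        cl = clone(est)
        assert cl.get_params()["model"] == "kj"
        cl.set_params(model="mst")
        assert cl.model == "mst"

    def test_fit_predict_shapes(self, decitabine_X):
        X, y = decitabine_X
        est = sc.SolubilityCorrelation(model="kj").fit(X, y)
        pred = est.predict(X)
        assert pred.shape == y.shape
        assert est.n_points_ == 32
        assert est.density_provider_id_ == "reference"
        assert est.score(X, y) > 0.8   # R^2 in y-space

    def test_predict_before_fit_raises(self, decitabine_X):
        X, _ = decitabine_X
        with pytest.raises(NotFittedError):
            sc.SolubilityCorrelation().predict(X)

    def test_rejects_malformed_design(self, decitabine_X):
        X, y = decitabine_X
        with pytest.raises(ValueError):
            sc.SolubilityCorrelation().fit(X[:, :1], y)
        with pytest.raises(ValueError):
            sc.SolubilityCorrelation(objective="bogus").fit(X, y)


def test_fit_report_schema(decitabine):
    d = sc.fit("kj", decitabine, "reference").to_dict()
    assert d["schema_version"] == 1
    assert {"model_id", "a", "b", "c", "aard_percent", "n_points",
            "density_provider_id", "points"} <= d.keys()
    assert len(d["points"]) == d["n_points"] == 32
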