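"""Least-squares fitting of the correlations and AARD% scoring.

The estimator :class:`SolubilityCorrelation` follows the scikit-learn
protocol (``fit(X, y)`` / ``predict(X)`` with ``X`` the (n, 2) array of
[T in K, P in MPa] and ``y`` the mole-fraction solubility), so it
composes with sklearn model selection. The module-level functions
:func:`fit`, :func:`fit_all` and :func:`aard` are thin wrappers working
directly on :class:`~sccosol.datasets.SolubilityDataset` objects.

Two calibration objectives are offered:

``objective="linear"`` (default)
    Ordinary (unweighted) least squares on the model's *linearized*
    response — multiple linear regression on (1, x1, x2).

``objective="relative"``
    Least squares on the relative deviations (y_calc - y_exp)/y_exp in
    mole-fraction space, solved by Levenberg-Marquardt started from the
    OLS solution. This is the calibration that published parameter sets
    in the SC-CO2 solubility literature typically correspond to: it
    nearly minimizes the AARD% by which the fits are judged, and the two
    objectives can differ noticeably because the linearized responses
    weight the low-solubility points differently.

Either way, AARD% is computed in y-space:

    AARD% = (100 / N) * sum |y_calc - y_exp| / y_exp
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import SolubilityDataset
from .density import DensityProvider, get_density_provider
from .models import ModelIdentity, ModelParameters, get_model

SCHEMA_VERSION = 1


class CollinearityError(ValueError):
    """The linearized design matrix is rank-deficient."""


def aard(y_exp, y_calc) -> float:
    """Average absolute relative deviation, percent."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y_exp.size == 0:
        raise ValueError("empty input")
    if y_exp.shape != y_calc.shape:
        raise ValueError("y_exp and y_calc must have equal length")
    if np.any(y_exp <= 0):
        raise ValueError("all experimental mole fractions must be positive")
    return float(100.0 * np.mean(np.abs(y_calc - y_exp) / y_exp))


class SolubilityCorrelation(RegressorMixin, BaseEstimator):
    """One density-based solubility correlation as a sklearn regressor.

    Parameters
    ----------
    model : str
        One of 'chrastil', 'bartle', 'mst', 'kj', 'garlapati_madras'.
    density_provider : str or DensityProvider
        CO2 density source; 'reference' (default) or 'pr-eos'.
    molar_mass : float
        Solute molar mass, g/mol. Only the Chrastil response depends on
        it (mole fraction <-> mass concentration conversion).
    solvent_molar_mass : float
        Solvent molar mass, g/mol (default CO2, 44.01).
    objective : {'linear', 'relative'}
        'linear' fits by OLS on the linearized response; 'relative'
        refines that solution by least squares on the relative
        mole-fraction deviations (see module docstring).

    Attributes
    ----------
    params_ : ModelParameters
        Fitted (a, b, c).
    a_, b_, c_ : float
        The same three values as scalars.
    aard_percent_ : float
        Training-set AARD%.
    n_points_ : int
        Number of training records.

    Examples
    --------
    >>> import numpy as np
    >>> from sccosol import SolubilityCorrelation, decitabine_dataset
    >>> ds = decitabine_dataset()
    >>> T, P, y = ds.arrays()
    >>> est = SolubilityCorrelation(model="kj", molar_mass=228.21)
    >>> est.fit(np.column_stack([T, P]), y).aard_percent_  # doctest: +SKIP
    9.5...
    """

    def __init__(self, model: str = "chrastil",
                 density_provider="reference",
                 molar_mass: float = 228.21,
                 solvent_molar_mass: float = 44.01,
                 objective: str = "linear"):
        self.model = model
        self.density_provider = density_provider
        self.molar_mass = molar_mass
        self.solvent_molar_mass = solvent_molar_mass
        self.objective = objective

    # rank tolerance: relative to largest singular value, generous enough
    # to flag a single-temperature design as collinear
    _RCOND = 1e-10

    def _resolve(self) -> tuple[ModelIdentity, DensityProvider]:
        return get_model(self.model), get_density_provider(
            self.density_provider)

    def fit(self, X, y):
        """Fit (a, b, c) by OLS on the linearized response.

        X is (n, 2): columns T (K) and P (MPa); y is the mole fraction.
        """
        X = check_array(X, ensure_min_samples=4)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly 2 columns: T_K, P_MPa")
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        model, provider = self._resolve()
        T, P = X[:, 0], X[:, 1]
        rho = provider.rho_mass(T, P)
        A = model.design_row(T, rho)
        sv = np.linalg.svd(A / np.linalg.norm(A, axis=0), compute_uv=False)
        if sv[-1] < self._RCOND:
            raise CollinearityError(
                f"design matrix for '{model.model_id}' is rank-deficient "
                "(need >= 2 distinct temperatures and >= 2 distinct "
                "densities)")
        resp = model.response(T, P, y, rho, self.molar_mass,
                              self.solvent_molar_mass)
        coef, *_ = np.linalg.lstsq(A, resp, rcond=None)
        if self.objective == "relative":
            coef = self._refine_relative(model, coef, T, P, y, rho)
        elif self.objective != "linear":
            raise ValueError("objective must be 'linear' or 'relative'")
        self.params_ = ModelParameters(*map(float, coef))
        self.a_, self.b_, self.c_ = coef.tolist()
        self.n_points_ = int(X.shape[0])
        self.n_features_in_ = 2
        self.density_provider_id_ = provider.provider_id
        self.aard_percent_ = aard(y, self.predict(X))
        return self

    def _refine_relative(self, model, coef0, T, P, y, rho):
        from .models import ModelParameters as MP
        from .models import PredictionDomainError

        def residuals(p):
            try:
                y_calc = np.atleast_1d(model.predict_y(
                    MP(*p), T, P, rho, self.molar_mass,
                    self.solvent_molar_mass))
            except PredictionDomainError:
                return np.full_like(y, 1e6)
            return (y_calc - y) / y

        sol = least_squares(residuals, coef0, method="lm",
                            xtol=1e-14, ftol=1e-14, max_nfev=10_000)
        return sol.x

    def predict(self, X):
        """Predicted mole-fraction solubility at the (T, P) rows of X."""
        check_is_fitted(self, "params_")
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly 2 columns: T_K, P_MPa")
        model, provider = self._resolve()
        T, P = X[:, 0], X[:, 1]
        rho = provider.rho_mass(T, P)
        return np.atleast_1d(model.predict_y(
            self.params_, T, P, rho, self.molar_mass,
            self.solvent_molar_mass))


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters and fit quality for one model on one dataset."""

    model_id: str
    params: ModelParameters
    aard_percent: float
    residuals: tuple[tuple[float, float], ...]   # (y_exp, y_calc) pairs
    n_points: int
    density_provider_id: str

    def __post_init__(self):
        if self.aard_percent < 0:
            raise ValueError("AARD% cannot be negative")
        if len(self.residuals) != self.n_points:
            raise ValueError("one residual pair per fitted point required")

    def to_dict(self) -> dict:
        """JSON-serializable fit report (schema_version 1)."""
        return {
            "schema_version": SCHEMA_VERSION,
            "model_id": self.model_id,
            "a": self.params.a,
            "b": self.params.b,
            "c": self.params.c,
            "aard_percent": self.aard_percent,
            "n_points": self.n_points,
            "density_provider_id": self.density_provider_id,
            "points": [{"y_exp": e, "y_calc": c}
                       for e, c in self.residuals],
        }


def fit(model, dataset: SolubilityDataset, provider="reference",
        objective: str = "linear") -> FitResult:
    """Fit one correlation to a dataset; see SolubilityCorrelation."""
    model = get_model(model)
    provider = get_density_provider(provider)
    T, P, y = dataset.arrays()
    est = SolubilityCorrelation(
        model=model.model_id, density_provider=provider,
        molar_mass=dataset.solute_molar_mass,
        solvent_molar_mass=dataset.solvent_molar_mass,
        objective=objective)
    X = np.column_stack([T, P])
    est.fit(X, y)
    y_calc = est.predict(X)
    return FitResult(
        model_id=model.model_id, params=est.params_,
        aard_percent=est.aard_percent_,
        residuals=tuple(zip(y.tolist(), y_calc.tolist())),
        n_points=len(dataset), density_provider_id=provider.provider_id)


def fit_all(dataset: SolubilityDataset, provider="reference",
            objective: str = "linear") -> list[FitResult]:
    """Fit all five correlations; results sorted by ascending AARD%."""
    from .models import MODEL_IDS
    results = [fit(m, dataset, provider, objective) for m in MODEL_IDS]
    return sorted(results, key=lambda r: r.aard_percent)
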