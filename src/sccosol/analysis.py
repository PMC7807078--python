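"""Cross-over pressure, MST self-consistency, and extrapolation tests.

The temperature effect on solubility in a supercritical solvent is a
competition: heating thins the solvent (lower density, lower solubility)
but raises the solute's sublimation pressure (higher solubility). The
*cross-over pressure* is where the second effect takes over. On a
measured T x P grid this shows up as the y-vs-T trend at fixed P
switching from strictly decreasing (density-dominated) to strictly
increasing (sublimation-dominated); the grid-based detector below
reports the smallest tabulated pressure at which strict decrease is
lost. A model-based variant locates the crossing of two fitted
isotherms by bisection instead.

The Mendez-Santiago-Teja *self-consistency test* subtracts the fitted
density term from the MST response, Gamma = T ln(yP/Pref) - c rho; for
data the model describes well, Gamma from every isotherm collapses onto
the single line a + b T, which is the usual evidence that the
correlation may be extrapolated beyond the measured range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datasets import SolubilityDataset
from .density import get_density_provider
from .fitting import FitResult, aard, fit
from .models import P_REF, ModelParameters, get_model

NONE_BELOW = "none_below"   # strictly increasing everywhere on the grid
NONE_ABOVE = "none_above"   # strictly decreasing everywhere on the grid


class GridError(ValueError):
    """The dataset is not the complete T x P grid the analysis needs."""


@dataclass(frozen=True)
class CrossoverReport:
    """Grid-based cross-over pressure and per-pressure trends."""

    crossover_P: float | str   # MPa, or NONE_BELOW / NONE_ABOVE
    per_pressure_trend: dict   # P (MPa) -> trend label

    def to_dict(self) -> dict:
        return {"crossover_P_MPa": self.crossover_P,
                "per_pressure_trend": {
                    f"{p:g}": t
                    for p, t in self.per_pressure_trend.items()}}


def _trend(y: np.ndarray, rel_tol: float = 1e-12) -> str:
    d = np.diff(y)
    tied = np.abs(d) < rel_tol * np.abs(y[:-1])
    if np.all(~tied & (d < 0)):
        return "strictly_decreasing"
    if np.all(~tied & (d > 0)):
        return "strictly_increasing"
    return "non_monotonic"


def crossover_pressure(dataset: SolubilityDataset) -> CrossoverReport:
    """Detect the cross-over pressure on a complete measurement grid.

    Classifies the y-vs-T trend at each tabulated pressure and reports
    the smallest pressure whose trend is not strictly decreasing — the
    transition out of the density-dominated regime. If every pressure
    shares one strict trend, a sentinel is returned instead
    (NONE_BELOW when increasing everywhere, NONE_ABOVE when decreasing
    everywhere).
    """
    if len(dataset.temperatures) < 2:
        raise GridError("need at least two temperatures")
    missing = dataset.missing_grid_cells()
    if missing:
        raise GridError(f"incomplete T x P grid; missing cells: {missing}")
    trends = {}
    for P in dataset.pressures:
        ys = np.array([dataset.lookup(T, P).y for T in dataset.temperatures])
        trends[float(P)] = _trend(ys)
    labels = list(trends.values())
    if all(t == "strictly_increasing" for t in labels):
        return CrossoverReport(NONE_BELOW, trends)
    if all(t == "strictly_decreasing" for t in labels):
        return CrossoverReport(NONE_ABOVE, trends)
    cross = min(p for p, t in trends.items() if t != "strictly_decreasing")
    return CrossoverReport(float(cross), trends)


def model_crossover_pressure(model, params: ModelParameters,
                             provider, T_low: float, T_high: float,
                             M_solute: float,
                             P_bracket: tuple[float, float] = (10.0, 45.0),
                             ) -> float:
    """Model-based cross-over: solve y(T_low, P) = y(T_high, P) for P.

    Secondary, continuous alternative to the grid-based detector:
    bisection on the fitted model's isotherm difference. Raises if the
    two isotherms do not cross inside ``P_bracket``. The lower bracket
    edge should stay above the near-critical region (~8 MPa), where the
    correlations can produce a spurious second crossing.
    """
    model = get_model(model)
    provider = get_density_provider(provider)

    def gap(P: float) -> float:
        y_lo = model.predict_y(params, T_low, P,
                               provider.rho_mass(T_low, P), M_solute)
        y_hi = model.predict_y(params, T_high, P,
                               provider.rho_mass(T_high, P), M_solute)
        return y_hi - y_lo

    lo, hi = P_bracket
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            f"isotherms {T_low} K and {T_high} K do not cross in "
            f"{P_bracket} MPa")
    return float(brentq(gap, lo, hi, xtol=1e-6))


@dataclass(frozen=True)
class ConsistencyReport:
    """MST self-consistency: density-corrected responses vs temperature."""

    collapsed_points: tuple[tuple[float, float], ...]  # (T, Gamma)
    line_fit: tuple[float, float]                      # (intercept, slope)
    r_squared: float
    per_isotherm_mad: dict                             # T -> mean |dev|

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"line_fit": {"intercept": self.line_fit[0],
                             "slope": self.line_fit[1]},
                "r_squared": self.r_squared,
                "per_isotherm_mad": {f"{t:g}": v for t, v
                                     in self.per_isotherm_mad.items()},
                "points": [{"T_K": t, "gamma": g}
                           for t, g in self.collapsed_points]}


def self_consistency(mst_fit: FitResult, dataset: SolubilityDataset,
                     provider="reference") -> ConsistencyReport:
    """Test whether all isotherms collapse onto the MST line.

    Computes Gamma = T ln(yP/Pref) - c rho for every record with the
    fitted c, pools all records into one OLS line Gamma = a + b T, and
    reports R^2 plus each isotherm's mean absolute deviation from the
    line. Requires at least two distinct temperatures.
    """
    if mst_fit.model_id != "mst":
        raise ValueError("self-consistency test requires an MST fit")
    provider = get_density_provider(provider)
    T, P, y = dataset.arrays()
    if np.unique(T).size < 2:
        raise ValueError("degenerate fit: a single isotherm cannot "
                         "separate the slope from the intercept")
    rho = provider.rho_mass(T, P)
    gamma = T * np.log(y * P / P_REF) - mst_fit.params.c * rho
    A = np.column_stack([np.ones_like(T), T])
    coef, *_ = np.linalg.lstsq(A, gamma, rcond=None)
    fitted = A @ coef
    ss_res = float(np.sum((gamma - fitted) ** 2))
    ss_tot = float(np.sum((gamma - gamma.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    mad = {float(t): float(np.mean(np.abs((gamma - fitted)[T == t])))
           for t in np.unique(T)}
    return ConsistencyReport(
        collapsed_points=tuple(zip(T.tolist(), gamma.tolist())),
        line_fit=(float(coef[0]), float(coef[1])),
        r_squared=min(r2, 1.0), per_isotherm_mad=mad)


def extrapolation_test(model, dataset: SolubilityDataset, provider,
                       held_out, objective: str = "linear") -> float:
    """Hold-out AARD%: fit on retained records, score the held-out ones.

    ``held_out`` is a predicate on (T, P) selecting the records to
    withhold from fitting; returns the AARD% of their predictions.
    """
    model = get_model(model)
    provider = get_density_provider(provider)
    n_held = sum(1 for r in dataset.records if held_out(r.T, r.P))
    if 0 < n_held < len(dataset.records):
        train = dataset.subset(lambda t, p: not held_out(t, p))
        test = dataset.subset(held_out)
    else:
        # degenerate split (nothing or everything held out): the
        # hold-out AARD reduces to the training AARD on the full set
        train = test = dataset
    result = fit(model, train, provider, objective)
    T, P, y = test.arrays()
    rho = provider.rho_mass(T, P)
    y_calc = model.predict_y(result.params, T, P, rho,
                             dataset.solute_molar_mass,
                             dataset.solvent_molar_mass)
    return aard(y, np.atleast_1d(y_calc))
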