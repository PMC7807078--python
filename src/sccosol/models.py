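"""The five density-based solubility correlations.

Each model expresses a transform of the solubility as a linear function
of three fitting parameters (a, b, c):

========================  =======================================  =========================
model_id                  response                                 design row (1, x1, x2)
========================  =======================================  =========================
chrastil                  ln s            [s in kg/m3]             (1, 1/T, ln rho)
bartle                    ln(y P / Pref)  [Pref = 0.1 MPa]         (1, 1/T, rho - 700)
mst                       T ln(y P / Pref)                         (1, T, rho)
kj                        ln y                                     (1, 1/T, rho / 44.01)
garlapati_madras          ln y                                     (1, 1/T, ln(rho T))
========================  =======================================  =========================

rho is the mass density of CO2 in kg/m3 except in the Kumar-Johnston
(kj) row, whose density coefficient multiplies the molar density in
kmol/m3. Chrastil's response uses the mass concentration s obtained from
the mole fraction via :func:`sccosol.datasets.mole_fraction_to_mass_conc`;
its c is the association number (solvent molecules per solute molecule),
and b/T carries the total enthalpy (see :mod:`sccosol.thermo`). The
Mendez-Santiago-Teja (mst) model is the one whose density-corrected
response collapses onto a single line in T for a self-consistent data
set (see :mod:`sccosol.analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import M_CO2
from .datasets import mass_conc_to_mole_fraction, mole_fraction_to_mass_conc

P_REF = 0.1       # MPa, reference pressure of the bartle / mst responses
RHO_REF = 700.0   # kg/m3, reference density of the bartle design row

MODEL_IDS = ("chrastil", "bartle", "mst", "kj", "garlapati_madras")


class PredictionDomainError(ValueError):
    """A fitted model extrapolated to a non-physical mole fraction."""


@dataclass(frozen=True)
class ModelParameters:
    """The (a, b, c) triple of one correlation.

    a is intercept-like; b multiplies 1/T (K) for every model except
    mst, where it multiplies T (1/K); c multiplies the model's density
    regressor.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("model parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


def _check_y_P(y, P):
    if np.any(np.asarray(y) <= 0):
        raise ValueError("mole fraction must be positive")
    if np.any(np.asarray(P) <= 0):
        raise ValueError("pressure must be positive")


class ModelIdentity:
    """One correlation: response transform, design row, and prediction."""

    def __init__(self, model_id: str):
        if model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model {model_id!r}; choose from {MODEL_IDS}")
        self.model_id = model_id

    def __repr__(self):
        return f"ModelIdentity({self.model_id!r})"

    def response(self, T, P, y, rho_mass, M_solute, M_solvent=M_CO2):
        """The linearized left-hand side, given measured data."""
        _check_y_P(y, P)
        T = np.asarray(T, dtype=float)
        P = np.asarray(P, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.model_id == "chrastil":
            s = mole_fraction_to_mass_conc(y, rho_mass, M_solute, M_solvent)
            return np.log(s)
        if self.model_id == "bartle":
            return np.log(y * P / P_REF)
        if self.model_id == "mst":
            return T * np.log(y * P / P_REF)
        return np.log(y)  # kj, garlapati_madras

    def design_row(self, T, rho_mass):
        """Columns (1, x1, x2) of the linear system, stacked row-wise."""
        T = np.atleast_1d(np.asarray(T, dtype=float))
        rho = np.atleast_1d(np.asarray(rho_mass, dtype=float))
        T, rho = np.broadcast_arrays(T, rho)
        one = np.ones_like(T)
        if self.model_id == "chrastil":
            cols = (one, 1.0 / T, np.log(rho))
        elif self.model_id == "bartle":
            cols = (one, 1.0 / T, rho - RHO_REF)
        elif self.model_id == "mst":
            cols = (one, T, rho)
        elif self.model_id == "kj":
            cols = (one, 1.0 / T, rho / M_CO2)
        else:  # garlapati_madras
            cols = (one, 1.0 / T, np.log(rho * T))
        return np.column_stack(cols)

    def linear_predictor(self, params: ModelParameters, T, rho_mass):
        """a + b*x1 + c*x2 for this model."""
        return self.design_row(T, rho_mass) @ params.as_array()

    def predict_y(self, params: ModelParameters, T, P, rho_mass,
                  M_solute, M_solvent=M_CO2):
        """Forward solubility prediction as mole fraction.

        Raises :class:`PredictionDomainError` when the correlation
        implies y >= 1 (non-physical extrapolation).
        """
        T = np.asarray(T, dtype=float)
        P = np.asarray(P, dtype=float)
        if np.any(P <= 0):
            raise ValueError("pressure must be positive")
        eta = self.linear_predictor(params, T, rho_mass)
        if self.model_id == "chrastil":
            s = np.exp(eta)
            y = mass_conc_to_mole_fraction(s, rho_mass, M_solute, M_solvent)
        elif self.model_id == "bartle":
            y = np.exp(eta) * P_REF / np.atleast_1d(P)
        elif self.model_id == "mst":
            y = np.exp(eta / np.atleast_1d(T)) * P_REF / np.atleast_1d(P)
        else:
            y = np.exp(eta)
        if np.any(~np.isfinite(y)) or np.any(y >= 1.0):
            raise PredictionDomainError(
                f"{self.model_id} prediction implies mole fraction >= 1; "
                "parameters extrapolated outside their physical domain")
        if np.ndim(T) == 0 and np.ndim(P) == 0 and np.ndim(rho_mass) == 0:
            return float(y[0] if np.ndim(y) else y)
        return y


def get_model(model: str | ModelIdentity) -> ModelIdentity:
    """Resolve a model id or pass an identity through."""
    if isinstance(model, ModelIdentity):
        return model
    return ModelIdentity(model)
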