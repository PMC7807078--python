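"""Enthalpies from fitted temperature coefficients.

The 1/T coefficient b of a van't Hoff-like correlation carries an
enthalpy: dH = -b * R. For Chrastil's model b reflects the *total*
enthalpy of the dissolution process (vaporization + solvation); for the
Bartle model, whose response already removes the pressure effect via the
reference state, b reflects the vaporization enthalpy alone. Hess's law
then gives the solvation enthalpy as the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314  # J/(mol K)


def _enthalpy_from_slope(b: float) -> float:
    if not np.isfinite(b):
        raise ValueError("temperature coefficient must be finite")
    return -b * R_GAS / 1000.0


def total_enthalpy(chrastil_b: float) -> float:
    """dH_total in kJ/mol from the Chrastil 1/T coefficient (K)."""
    return _enthalpy_from_slope(chrastil_b)


def vaporization_enthalpy(bartle_b: float) -> float:
    """dH_vap in kJ/mol from the Bartle 1/T coefficient (K)."""
    return _enthalpy_from_slope(bartle_b)


def solvation_enthalpy(dH_total: float, dH_vap: float) -> float:
    """dH_sol = dH_total - dH_vap (Hess's law), kJ/mol."""
    return dH_total - dH_vap


@dataclass(frozen=True)
class EnthalpyReport:
    """Total, vaporization and solvation enthalpies, kJ/mol."""

    dH_total: float
    dH_vap: float
    dH_sol: float
    R_used: float = R_GAS

    def __post_init__(self):
        if self.dH_sol != self.dH_total - self.dH_vap:
            raise ValueError("Hess identity violated: "
                             "dH_sol must equal dH_total - dH_vap")

    def to_dict(self) -> dict:
        return {"dH_total_kJ_mol": self.dH_total,
                "dH_vap_kJ_mol": self.dH_vap,
                "dH_sol_kJ_mol": self.dH_sol,
                "R_J_mol_K": self.R_used}


def enthalpy_report(chrastil_b: float, bartle_b: float) -> EnthalpyReport:
    """Build the full report from the two fitted 1/T coefficients."""
    dh_t = total_enthalpy(chrastil_b)
    dh_v = vaporization_enthalpy(bartle_b)
    return EnthalpyReport(dH_total=dh_t, dH_vap=dh_v,
                          dH_sol=solvation_enthalpy(dh_t, dh_v))
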