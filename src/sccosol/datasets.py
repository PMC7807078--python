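"""Solubility data model, CSV I/O, and the bundled decitabine table.

Canonical internal units throughout the package: temperature in K,
pressure in MPa, solubility as mole fraction, mass concentration in
kg/m3. Pressures given in bar are converted at ingestion (1 MPa = 10 bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .density import M_CO2


class DatasetError(ValueError):
    """Malformed solubility table or record."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One isothermal solubility measurement.

    T in K, P in MPa, y the mole-fraction solubility, u_y its optional
    absolute standard uncertainty.
    """

    T: float
    P: float
    y: float
    u_y: float | None = None

    def __post_init__(self):
        if not (self.T > 0):
            raise DatasetError(f"temperature must be positive, got {self.T}")
        if not (self.P > 0):
            raise DatasetError(f"pressure must be positive, got {self.P}")
        if not (0 < self.y < 1):
            raise DatasetError(
                f"mole fraction must lie in (0, 1), got {self.y}")
        if self.u_y is not None and not (self.u_y > 0):
            raise DatasetError(
                f"uncertainty must be positive when given, got {self.u_y}")


@dataclass(frozen=True)
class SolubilityDataset:
    """A solute's measurement table plus the metadata the models need."""

    solute_name: str
    solute_molar_mass: float              # g/mol
    records: tuple[SolubilityRecord, ...]
    solvent_molar_mass: float = M_CO2     # g/mol
    T_uncertainty: float | None = None    # K
    P_uncertainty: float | None = None    # MPa
    notes: str = ""

    def __post_init__(self):
        if len(self.records) == 0:
            raise DatasetError("dataset must contain at least one record")
        object.__setattr__(self, "records", tuple(self.records))
        seen = set()
        for r in self.records:
            key = (r.T, r.P)
            if key in seen:
                raise DatasetError(f"duplicate (T, P) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> np.ndarray:
        """Sorted unique temperatures, K."""
        return np.unique([r.T for r in self.records])

    @property
    def pressures(self) -> np.ndarray:
        """Sorted unique pressures, MPa."""
        return np.unique([r.P for r in self.records])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(T, P, y) as parallel float arrays, in record order."""
        T = np.array([r.T for r in self.records])
        P = np.array([r.P for r in self.records])
        y = np.array([r.y for r in self.records])
        return T, P, y

    def lookup(self, T: float, P: float) -> SolubilityRecord:
        for r in self.records:
            if np.isclose(r.T, T) and np.isclose(r.P, P):
                return r
        raise KeyError(f"no record at T={T} K, P={P} MPa")

    def missing_grid_cells(self) -> list[tuple[float, float]]:
        """Cells of the full temperatures x pressures grid with no record."""
        have = {(r.T, r.P) for r in self.records}
        return [(float(t), float(p)) for t in self.temperatures
                for p in self.pressures if (t, p) not in have]

    def subset(self, keep) -> "SolubilityDataset":
        """New dataset with only the records where ``keep(T, P)`` is true."""
        kept = tuple(r for r in self.records if keep(r.T, r.P))
        if not kept:
            raise DatasetError("subset predicate kept no records")
        return replace(self, records=kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temperature_K": [r.T for r in self.records],
            "pressure_MPa": [r.P for r in self.records],
            "mole_fraction": [r.y for r in self.records],
            "u_mole_fraction": [r.u_y for r in self.records],
        })


_REQUIRED = ("temperature_K", "mole_fraction")


def load_dataset(path, *, solute_name: str = "unknown",
                 solute_molar_mass: float = float("nan"),
                 solvent_molar_mass: float = M_CO2) -> SolubilityDataset:
    """Read a solubility table from CSV.

    Expected columns: ``temperature_K``, ``pressure_MPa`` or
    ``pressure_bar`` (exactly one), ``mole_fraction`` and optionally
    ``u_mole_fraction``. Lines starting with '#' are comments. Rows that
    violate record invariants are reported with their row number.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED:
        if col not in df.columns:
            raise DatasetError(f"missing required column '{col}' in {path}")
    has_mpa = "pressure_MPa" in df.columns
    has_bar = "pressure_bar" in df.columns
    if has_mpa == has_bar:
        raise DatasetError(
            "exactly one of 'pressure_MPa' or 'pressure_bar' is required")
    p_col = "pressure_MPa" if has_mpa else "pressure_bar"
    scale = 1.0 if has_mpa else 0.1

    records = []
    for i, row in df.iterrows():
        try:
            vals = [float(row["temperature_K"]), float(row[p_col]),
                    float(row["mole_fraction"])]
            u = row.get("u_mole_fraction")
            u = None if u is None or pd.isna(u) else float(u)
            if any(np.isnan(v) for v in vals):
                raise DatasetError("non-numeric cell")
            records.append(SolubilityRecord(
                T=vals[0], P=vals[1] * scale, y=vals[2], u_y=u))
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"{path}, data row {i + 1}: {exc}") from None
    return SolubilityDataset(
        solute_name=solute_name, solute_molar_mass=solute_molar_mass,
        solvent_molar_mass=solvent_molar_mass, records=tuple(records))


def write_dataset(dataset: SolubilityDataset, path,
                  *, pressure_unit: str = "MPa") -> None:
    """Write the standard CSV schema; round-trips with load_dataset."""
    if pressure_unit not in ("MPa", "bar"):
        raise ValueError("pressure_unit must be 'MPa' or 'bar'")
    scale = 1.0 if pressure_unit == "MPa" else 10.0
    df = dataset.to_frame()
    df["pressure_MPa"] = df["pressure_MPa"] * scale
    df = df.rename(columns={"pressure_MPa": f"pressure_{pressure_unit}"})
    if df["u_mole_fraction"].isna().all():
        df = df.drop(columns=["u_mole_fraction"])
    with open(path, "w") as fh:
        fh.write(f"# solubility of {dataset.solute_name} "
                 f"(M = {dataset.solute_molar_mass} g/mol) in CO2\n")
        df.to_csv(fh, index=False)


def decitabine_dataset() -> SolubilityDataset:
    """The packaged 32-point decitabine / SC-CO2 solubility table.

    Gravimetric measurements on the grid T in {308, 318, 328, 338} K,
    P in {12, 16, 20, 24, 28, 32, 36, 40} MPa, with per-point standard
    uncertainties. The mole-fraction range is 2.84e-5 to 1.07e-3.
    """
    path = resources.files("sccosol.data") / "decitabine_sc_co2.csv"
    with resources.as_file(path) as p:
        ds = load_dataset(p, solute_name="decitabine",
                          solute_molar_mass=228.21)
    return replace(
        ds, T_uncertainty=0.1, P_uncertainty=0.035,
        notes=("u_y at (308 K, 32 MPa) is 5.81e-05 as printed in the "
               "source table (~29% relative, far above the ~8.9% maximum "
               "RSD stated elsewhere); possibly a misprint for 5.81e-06."))


def mole_fraction_to_mass_conc(y, rho, M_solute, M_solvent=M_CO2):
    """Convert mole-fraction solubility to mass concentration s (kg/m3).

    s = rho * (M_solute / M_solvent) * y / (1 - y), the dilute-solution
    relation used with Chrastil's association model; rho is the density
    of the solvent (solute contribution to volume neglected).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y >= 1):
        raise ValueError("mole fraction must lie in [0, 1)")
    out = np.asarray(rho, dtype=float) * (M_solute / M_solvent) * y / (1 - y)
    return float(out) if out.ndim == 0 else out


def mass_conc_to_mole_fraction(s, rho, M_solute, M_solvent=M_CO2):
    """Inverse of :func:`mole_fraction_to_mass_conc`."""
    s = np.asarray(s, dtype=float)
    rho = np.asarray(rho, dtype=float)
    out = s * M_solvent / (s * M_solvent + rho * M_solute)
    return float(out) if out.ndim == 0 else out
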