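"""Generate the bundled CO2 density grid resource.

Computes mass density of pure CO2 on a regular (T, P) grid from the
reference multiparameter Helmholtz equation of state of Span & Wagner
(J. Phys. Chem. Ref. Data 25, 1509 (1996)) — the formulation behind
NIST-quality property tables — and writes it as the CSV resource shipped
with the package (``src/sccosol/data/co2_density_grid.csv``).

The EOS implementation lives here, in a provenance script, on purpose:
the installed package only interpolates the grid. Before writing, the
script verifies the transcribed coefficients against independent anchors:

* critical point: P(Tc, rho_c) = 7.3773 MPa with dP/drho ~ 0;
* vapor-liquid equilibrium (full Maxwell construction) at 273.15 K and
  293.15 K against the well-known saturation pressures 3.485 / 5.729 MPa;
* second virial coefficient B(300 K) ~ -121 cm3/mol;
* ideal-gas limit at 0.1 MPa;
* agreement with a Peng-Robinson EOS within a few percent over the
  supercritical working envelope.

Run from the repository root:  python scripts/make_density_grid.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, fsolve

# --- reference constants (Span & Wagner 1996) ---
TC = 304.1282        # K
PC = 7.3773          # MPa
RHOC = 467.6         # kg/m3
M = 44.0098          # g/mol
R_MOL = 8.31451      # J/(mol K), value used by the reference EOS
R_SPEC = R_MOL / M * 1000.0  # J/(kg K)

# Residual Helmholtz energy: polynomial / exponential terms
_N = np.array([
    0.38856823203161, 2.938547594274, -5.5867188534934, -0.76753199592477,
    0.31729005580416, 0.54803315897767, 0.12279411220335,
    2.1658961543220, 1.5841735109724, -0.23132705405503, 0.058116916431436,
    -0.55369137205382, 0.48946615909422, -0.024275739843501,
    0.062494790501678, -0.12175860225246, -0.37055685270086,
    -0.016775879700426, -0.11960736637987, -0.045619362508778,
    0.035612789270346, -0.0074427727132052, -0.0017395704902432,
    -0.021810121289527, 0.024332166559236, -0.037440133423463,
    0.14338715756878, -0.13491969083286, -0.023151225053480,
    0.012363125492901, 0.0021058321972940, -0.00033958519026368,
    0.0055993651771592, -0.00030335118055646,
])
_D = np.array([1, 1, 1, 1, 2, 2, 3, 1, 2, 4, 5, 5, 5, 6, 6, 6, 1, 1, 4, 4,
               4, 7, 8, 2, 3, 3, 5, 5, 6, 7, 8, 10, 4, 8], dtype=float)
_T = np.array([0.0, 0.75, 1.0, 2.0, 0.75, 2.0, 0.75, 1.5, 1.5, 2.5, 0.0,
               1.5, 2.0, 0.0, 1.0, 2.0, 3.0, 6.0, 3.0, 6.0, 8.0, 6.0, 0.0,
               7.0, 12.0, 16.0, 22.0, 24.0, 16.0, 24.0, 8.0, 2.0, 28.0, 14.0])
_C = np.array([0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2,
               2, 2, 2, 3, 3, 3, 4, 4, 4, 4, 4, 4, 5, 6], dtype=float)

# Gaussian bell terms
_NG = np.array([-213.65488688320, 26641.569149272, -24027.212204557,
                -283.41603423999, 212.47284400179])
_DG = np.array([2.0, 2.0, 2.0, 3.0, 3.0])
_TG = np.array([1.0, 0.0, 1.0, 3.0, 3.0])
_ALPHA = np.array([25.0, 25.0, 25.0, 15.0, 20.0])
_BETA = np.array([325.0, 300.0, 300.0, 275.0, 275.0])
_GAMMA = np.array([1.16, 1.19, 1.19, 1.25, 1.22])
_EPS = np.array([1.0, 1.0, 1.0, 1.0, 1.0])

# Non-analytic critical-region terms
_NN = np.array([-0.66642276540751, 0.72608632349897, 0.055068668612842])
_AN = np.array([3.5, 3.5, 3.0])
_BN = np.array([0.875, 0.925, 0.875])
_BETAN = np.array([0.3, 0.3, 0.3])
_AA = np.array([0.7, 0.7, 0.7])
_BB = np.array([0.3, 0.3, 1.0])
_CN = np.array([10.0, 10.0, 12.5])
_DN = np.array([275.0, 275.0, 275.0])


def alphar(delta: float, tau: float) -> float:
    s = float(np.sum(_N[:7] * delta ** _D[:7] * tau ** _T[:7]))
    s += float(np.sum(_N[7:] * delta ** _D[7:] * tau ** _T[7:]
                      * np.exp(-delta ** _C[7:])))
    s += float(np.sum(_NG * delta ** _DG * tau ** _TG
                      * np.exp(-_ALPHA * (delta - _EPS) ** 2
                               - _BETA * (tau - _GAMMA) ** 2)))
    dm1 = delta - 1.0
    if abs(dm1) < 1e-13:
        dm1 = 1e-13
    theta = (1.0 - tau) + _AA * (dm1 ** 2) ** (1.0 / (2.0 * _BETAN))
    Delta = theta ** 2 + _BB * (dm1 ** 2) ** _AN
    psi = np.exp(-_CN * dm1 ** 2 - _DN * (tau - 1.0) ** 2)
    s += float(np.sum(_NN * Delta ** _BN * delta * psi))
    return s


def alphar_delta(delta: float, tau: float) -> float:
    """d(alpha^r)/d(delta) at constant tau."""
    s = float(np.sum(_N[:7] * _D[:7] * delta ** (_D[:7] - 1) * tau ** _T[:7]))
    e = np.exp(-delta ** _C[7:])
    s += float(np.sum(_N[7:] * e * delta ** (_D[7:] - 1) * tau ** _T[7:]
                      * (_D[7:] - _C[7:] * delta ** _C[7:])))
    g = np.exp(-_ALPHA * (delta - _EPS) ** 2 - _BETA * (tau - _GAMMA) ** 2)
    s += float(np.sum(_NG * g * tau ** _TG * delta ** (_DG - 1)
                      * (_DG - 2.0 * _ALPHA * delta * (delta - _EPS))))
    dm1 = delta - 1.0
    if abs(dm1) < 1e-13:
        dm1 = 1e-13
    theta = (1.0 - tau) + _AA * (dm1 ** 2) ** (1.0 / (2.0 * _BETAN))
    Delta = theta ** 2 + _BB * (dm1 ** 2) ** _AN
    psi = np.exp(-_CN * dm1 ** 2 - _DN * (tau - 1.0) ** 2)
    dpsi = -2.0 * _CN * dm1 * psi
    dDelta = dm1 * (_AA * theta * (2.0 / _BETAN)
                    * (dm1 ** 2) ** (1.0 / (2.0 * _BETAN) - 1.0)
                    + 2.0 * _BB * _AN * (dm1 ** 2) ** (_AN - 1.0))
    s += float(np.sum(_NN * (Delta ** _BN * (psi + delta * dpsi)
                             + _BN * Delta ** (_BN - 1.0) * dDelta
                             * delta * psi)))
    return s


def pressure(T: float, rho: float) -> float:
    """Pressure in MPa from T (K) and mass density rho (kg/m3)."""
    delta = rho / RHOC
    tau = TC / T
    return rho * R_SPEC * T * (1.0 + delta * alphar_delta(delta, tau)) / 1e6


def density(T: float, P: float) -> float:
    """Solve pressure(T, rho) = P on the physically correct branch."""
    if T >= TC:
        return brentq(lambda r: pressure(T, r) - P, 1e-6, 1600.0,
                      xtol=1e-10, rtol=1e-12)
    rho_v, rho_l, p_sat = saturation(T)
    if P < p_sat:
        return brentq(lambda r: pressure(T, r) - P, 1e-6, rho_v,
                      xtol=1e-10, rtol=1e-12)
    return brentq(lambda r: pressure(T, r) - P, rho_l, 1600.0,
                  xtol=1e-10, rtol=1e-12)


def _psat_ancillary(T: float) -> float:
    th = 1.0 - T / TC
    a = [-7.0602087, 1.9391218, -1.6463597, -3.2995634]
    t = [1.0, 1.5, 2.0, 4.0]
    return PC * np.exp(TC / T * sum(ai * th ** ti for ai, ti in zip(a, t)))


def saturation(T: float) -> tuple[float, float, float]:
    """Full Maxwell construction: (rho_vapor, rho_liquid, Psat/MPa)."""
    p0 = _psat_ancillary(T)
    tau = TC / T

    def eqs(x):
        rv, rl = x
        pv, pl = pressure(T, rv), pressure(T, rl)
        # equal pressure and equal Gibbs energy
        g = (np.log(rl / rv) + alphar(rl / RHOC, tau)
             - alphar(rv / RHOC, tau)
             + pv * 1e6 / (R_SPEC * T) * (1.0 / rl - 1.0 / rv))
        return [pv - pl, g]

    rv0 = p0 * 1e6 / (R_SPEC * T) * 1.3          # near-ideal vapor guess
    rl0 = 1100.0 - 2.0 * (T - 216.0)             # crude liquid guess
    rv, rl = fsolve(eqs, [rv0, rl0], xtol=1e-12)
    return float(rv), float(rl), pressure(T, rv)


def second_virial(T: float) -> float:
    """B(T) in cm3/mol."""
    eps = 1e-9
    return alphar_delta(eps, TC / T) / RHOC * M * 1000.0


def pr_density(T: float, P: float) -> float:
    """Volume-corrected Peng-Robinson density, for the cross-check.

    Mirrors the package's analytic fallback provider: largest-Z root plus
    the CO2-specific density-dependent volume correction (see
    sccosol.density.PengRobinsonProvider).
    """
    Tc, Pc_pa, omega = 304.13, 7.377e6, 0.2239
    Rg, Ppa = 8.314462618, P * 1e6
    a = 0.45724 * Rg ** 2 * Tc ** 2 / Pc_pa
    b = 0.07780 * Rg * Tc / Pc_pa
    kappa = 0.37464 + 1.54226 * omega - 0.26992 * omega ** 2
    alpha = (1.0 + kappa * (1.0 - np.sqrt(T / Tc))) ** 2
    A = a * alpha * Ppa / (Rg * T) ** 2
    B = b * Ppa / (Rg * T)
    roots = np.roots([1.0, -(1.0 - B), A - 3 * B ** 2 - 2 * B,
                      -(A * B - B ** 2 - B ** 3)])
    z = max(r.real for r in roots if abs(r.imag) < 1e-10 and r.real > 0)
    v = z * Rg * T / Ppa
    coef = [3.5069732662e-04, -3.2498851091e-04, -4.0972215282e-04,
            3.8989536079e-04, 1.2236525127e-04, -1.1894625351e-04]
    Tr, ivr = T / Tc, 94.12e-6 / v
    c = np.dot(coef, [1.0, Tr, ivr, Tr * ivr, ivr ** 2, Tr * ivr ** 2])
    return (M / 1000.0) / (v - c)


def self_check() -> None:
    ok = True

    p_c = pressure(TC, RHOC * (1 + 1e-7))
    dp = (pressure(TC, RHOC * 1.01) - pressure(TC, RHOC * 0.99))
    print(f"critical: P(Tc, rho_c) = {p_c:.4f} MPa (expect 7.3773), "
          f"dP over +-1% rho = {dp:.4f} MPa")
    ok &= abs(p_c - PC) < 0.003 and abs(dp) < 0.01

    for T, p_ref in [(273.15, 3.4851), (293.15, 5.7291)]:
        _, _, ps = saturation(T)
        print(f"saturation {T} K: {ps:.4f} MPa (expect {p_ref})")
        ok &= abs(ps - p_ref) / p_ref < 0.002

    b300 = second_virial(300.0)
    print(f"B(300 K) = {b300:.1f} cm3/mol (expect about -121)")
    ok &= -127.0 < b300 < -116.0

    rho_ig = density(338.0, 0.1)
    ig = 0.1e6 * (M / 1000.0) / (8.314462618 * 338.0)
    print(f"ideal-gas limit 338 K, 0.1 MPa: {rho_ig:.4f} (PM/RT = {ig:.4f})")
    ok &= abs(rho_ig - ig) / ig < 0.02

    worst = 0.0
    for T in range(308, 339, 5):
        for P in range(12, 41, 4):
            r1, r2 = density(T, P), pr_density(T, P)
            worst = max(worst, abs(r1 - r2) / r1)
    print(f"corrected-PR cross-check, worst rel. dev.: {worst:.3f}")
    ok &= worst < 0.05

    if not ok:
        sys.exit("self-check FAILED — grid not written")
    print("self-check passed")


def main() -> None:
    self_check()
    out = Path(__file__).resolve().parents[1] / "src" / "sccosol" / "data" \
        / "co2_density_grid.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    T_grid = np.arange(303, 344, 1)
    P_grid = np.concatenate([[0.1], np.arange(0.5, 45.01, 0.5)])
    lines = [
        "# CO2 mass density grid, computed from the Span & Wagner (1996)",
        "# reference multiparameter Helmholtz equation of state",
        "# (the formulation behind NIST-quality CO2 property tables).",
        "# Generated by scripts/make_density_grid.py; regular T x P grid.",
        "T_K,P_MPa,rho_kg_m3",
    ]
    for T in T_grid:
        for P in P_grid:
            rho = density(float(T), float(P))
            lines.append(f"{T:d},{P:g},{rho:.2f}")
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out} ({out.stat().st_size / 1024:.1f} KiB, "
          f"{len(T_grid) * len(P_grid)} nodes)")


if __name__ == "__main__":
    main()
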