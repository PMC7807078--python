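# sccosol

Density-based correlation of solute solubility in supercritical CO₂.

Screening a drug for supercritical-CO₂ processing (particle micronization,
anti-solvent crystallization) starts from its saturation solubility y(T, P)
in the fluid. Measured isothermal solubility tables are routinely condensed
into three-parameter, density-based semi-empirical correlations, which this
package implements, fits, and analyzes:

| model id           | linear-in-parameters form                                   |
|--------------------|-------------------------------------------------------------|
| `chrastil`         | ln s = a + b/T + c·ln ρ  (s: mass concentration, kg/m³)     |
| `bartle`           | ln(yP/P_ref) = a + b/T + c·(ρ − 700),  P_ref = 0.1 MPa      |
| `mst`              | T·ln(yP/P_ref) = a + b·T + c·ρ  (Méndez-Santiago–Teja)      |
| `kj`               | ln y = a + b/T + c·ρ_molar  (Kumar–Johnston, kmol/m³)       |
| `garlapati_madras` | ln y = a + b/T + c·ln(ρT)                                   |

with ρ the CO₂ mass density (kg/m³). On top of the fits it derives the
dissolution enthalpies (ΔH_total = −b_chrastil·R, ΔH_vap = −b_bartle·R,
ΔH_sol = ΔH_total − ΔH_vap by Hess's law), detects the cross-over pressure
(where the temperature effect on solubility reverses sign), runs the MST
self-consistency/extrapolation test, and ships:

* the measured 32-point decitabine / SC-CO₂ dataset (308–338 K, 12–40 MPa)
  with per-point uncertainties;
* two CO₂ density providers — a bundled reference-EOS grid (default) and a
  self-contained, volume-corrected Peng–Robinson EOS;
* a synthetic-surface generator with known ground truth for validation.

## Worked example

```python
import sccosol as sc

ds = sc.decitabine_dataset()                      # 32 records
fits = sc.fit_all(ds, "reference", objective="relative")
for r in fits:
    print(f"{r.model_id:18s} a={r.params.a:10.2f} b={r.params.b:9.1f} "
          f"c={r.params.c:7.4f}  AARD={r.aard_percent:5.2f}%")

by = {r.model_id: r for r in fits}
print(sc.enthalpy_report(by["chrastil"].params.b, by["bartle"].params.b))
print(sc.crossover_pressure(ds).crossover_P, "MPa")
```

prints

```
kj                 a=      7.47 b=  -7227.3 c= 0.3497  AARD= 9.01%
mst                a= -12694.72 b=     26.5 c= 3.9008  AARD=12.37%
garlapati_madras   a=    -66.95 b=  -5117.3 c= 5.9615  AARD=12.59%
chrastil           a=    -24.90 b=  -7039.7 c= 6.9604  AARD=12.69%
bartle             a=     25.03 b=  -9483.8 c= 0.0120  AARD=12.87%
EnthalpyReport(dH_total=58.52788985927028, dH_vap=78.84854977861784,
               dH_sol=-20.320659919347555, R_used=8.314)
16.0 MPa
```

The Kumar–Johnston correlation describes the data best (9.0% average
absolute relative deviation); the Chrastil and Bartle temperature slopes
give a total dissolution enthalpy of ≈58.5 kJ/mol and a vaporization
enthalpy of ≈78.8 kJ/mol, hence a solvation enthalpy of ≈−20.3 kJ/mol; and
below 16 MPa heating *reduces* solubility (solvent-density effect) while
above it heating increases solubility (sublimation-pressure effect).

`objective="relative"` calibrates by least squares on relative
mole-fraction deviations — the convention published parameter tables in
this literature correspond to; `objective="linear"` (default) is plain OLS
on the linearized response. See `docs/methods.md` for why they differ.

The same pipeline is scriptable:

```sh
sccosol report --objective relative --out report.json
sccosol simulate --model kj --noise-sigma 0.05 --seed 1 --out sim.csv
sccosol fit --data sim.csv --model kj
```

`SolubilityCorrelation` is a scikit-learn estimator (`fit(X, y)` /
`predict(X)` with `X = [T_K, P_MPa]` columns), so it works with sklearn
model selection and pipelines.

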