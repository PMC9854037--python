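# brachydose

TG-43 dosimetry toolkit for the ⁶⁰Co sources of the GZP3 HDR afterloading
system.

HDR brachytherapy treatment planning needs, for every source model, the
AAPM TG-43/TG-43U1 parameter set: the dose-rate constant Λ, the radial dose
function g(r), the 2D/1D anisotropy functions F(r,θ) and φ_an(r), and
along–away dose-rate tables for QA. The GZP3 afterloader carries two
encapsulated cylindrical ⁶⁰Co source designs (channels 1&2: 1 mm active
core; channel 3: 2 mm). This package provides the full chain for those
sources, for medical physicists and for anyone studying the formalism:

* **`brachydose.mc`** — a kerma-scoring analog photon Monte Carlo
  (two-line ⁶⁰Co spectrum, nested-cylinder source geometry, 30-cm water
  sphere / 3-m air cube, cylindrical-ring track-length scoring, seeded and
  reproducible) that generates dose grids and air-kerma strength,
* **`brachydose.extract`** — inversion of the TG-43 equations
  (Λ = Ḋ(r₀,θ₀)/S_k; g, F, φ_an from scored grids), comparison statistics
  and the quadrature uncertainty budget,
* **`brachydose.gfit`** — deterministic profiled least-squares fitting of
  g(r) = (a0 r⁻² + a1 r⁻¹ + a2 + a3 r + a4 r²)e^(−a5 r),
* **`brachydose.engine`** — forward dose reconstruction
  Ḋ(r,θ) = S_k Λ [G(r,θ)/G(r₀,θ₀)] g(r) F(r,θ) with the line-source
  geometry factor G = β/(L r sinθ), and along–away QA tables,
* **`brachydose.fixtures`** — the published reference tables for these
  sources, shipped as checksummed CSV package data with anomaly flags.

The numbered scripts under `analysis/` walk through the study: fixture
statistics, g(r) fits, simulation, extraction, QA tables, uncertainty
budget. `docs/methods.md` documents the physics, defaults and known
limitations.

## Worked example

```python
from brachydose import (builtin_source, build_scoring_grid,
                        run_water_simulation, run_air_simulation,
                        dose_rate_constant)

spec = builtin_source("1_2")                      # channels 1&2 source
grid = build_scoring_grid([1.0])                  # ring at (r=1 cm, 90°)
water = run_water_simulation(spec, grid, 10_000_000, seed=1)
air = run_air_simulation(spec, 10_000_000, seed=1)  # S_k at 100 cm
lam, rel = dose_rate_constant(water, air)
print(f"S_k = {air.sk_per_bq:.4e} cGy cm2/h per Bq")
print(f"Lambda = {lam:.4f} +- {lam * rel:.4f} cGy/h/U")
```

prints

```
S_k = 2.9798e-07 cGy cm2/h per Bq
Lambda = 1.1048 +- 0.0120 cGy/h/U
```

S_k is the air-kerma rate × distance² per becquerel — within 0.2% of the
published Geant4 value for this source (2.985 × 10⁻⁷). Λ is the water dose
rate at the reference point (1 cm, 90°) per unit air-kerma strength; the
simplified physics lands ~1% below the published 1.115 cGy h⁻¹ U⁻¹, inside
the ±2% band budgeted for a photon-only kerma transport at 10⁷ decays.

The same pipeline from the shell:

```sh
brachydose simulate water --channel 12 --n 1000000 --seed 1 --out w.csv
brachydose simulate air   --channel 12 --n 1000000 --seed 1 --out sk.json
brachydose extract --water w.csv --air sk.json -L 0.1 --out params/
brachydose dose --params params/ --r 2 --theta 45
brachydose table --params params/ --out alongaway.csv
brachydose fit-gr --g params/g.csv
brachydose budget -c stat:1.21:A -c "geom+:1.34:B" -c "geom-:1.24:B"
```

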