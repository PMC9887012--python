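# reefshield

Coral reefs are natural breakwaters: their rough, structurally complex
surfaces dissipate most of the wave energy arriving at tropical
coastlines. When disturbances (predator outbreaks, cyclones, bleaching)
flatten a reef, that protection erodes — extreme wave run-up events on the
shore become both higher and more frequent, even without sea-level rise.
`reefshield` is a Python package for quantifying this chain end to end on
synthetic but statistically realistic data. It is aimed at coastal
hazard and reef-ecology modellers who want a tested, reproducible
implementation of each link:

1. **Reef construction** — coral assemblages are built colony by colony on
   a substrate strip from survey cover and size distributions, and their
   **structural complexity** is measured as the rumple index
   SC = (3D surface area)/(planar area).
2. **Hydraulic roughness** — SC converts to a Nikuradse roughness via the
   reef power law `k_n = 0.01 × SC^2.98`; a spectral-attenuation inversion
   of paired pressure records (energy-flux loss → wave friction factor
   `f_w = exp[5.213 (k_n/a₀)^0.194 − 5.977]` → k_n) closes the loop with
   field-style measurements.
3. **Wave transformation** — a 1D enhanced-Boussinesq solver (B = 1/15
   dispersion, surface-roller breaking, swash eddy viscosity, quadratic
   bed friction, dry-bed run-up) propagates irregular seas from 20 m depth
   across the reef to the beach, yielding nearshore Hs, the run-up series
   and its 2%-exceedance height R₂%.
4. **Probabilistic ensemble** — a weekly (Hs, Tp) climate is reduced to
   percentile conditions with copula-linked peak periods, and one
   simulation runs per (reef state × condition).
5. **Extremes and regression** — generalized-Pareto return curves of R₂%
   per reef state give frequency-amplification factors between healthy
   and degraded reefs, and a Bayesian interaction model
   `RU ~ N((α+σ_ζ)Hs + (β+σ_ζ)SC + (γ+σ_ζ)SC·Hs, σ)` quantifies how the
   protective effect of complexity grows with wave height.

Everything runs from synthetic inputs generated by `reefshield.synthgen`,
so the full pipeline is testable on a workstation without any downloads.

## Worked example

```python
import numpy as np
from reefshield import synthgen, reef3d, roughness, climate, extremes

# survey cycle: healthy -> collapsed -> recovered reef
survey = synthgen.generate_survey_table(seed=3)
bank = synthgen.generate_shape_bank(n_per_taxon=3, seed=1)
strip = reef3d.SubstrateStrip(length=20.0, width=0.5, cell=0.01)
sc = reef3d.complexity_ensemble(survey, strip, bank, n_replicates=5, seed=9)
print(reef3d.summarize_complexity(sc).tail(3).round(3))
#     year  median    q05    q95
#     2014   1.490  1.450  1.514
#     2015   1.632  1.567  1.676
#     2016   1.841  1.799  1.906

# complexity -> hydraulic roughness
print(round(roughness.sc_to_kn(3.86), 3), round(roughness.sc_to_kn(1.58), 4))
# 0.56 0.0391    (metres: healthy vs degraded reef roughness)

# one wave run across the reef transect
from reefshield import boussiflow
bathy = synthgen.generate_bathymetry()
kn = roughness.build_kn_profile(3.86, bathy)
res = boussiflow.run_simulation(bathy, kn, hs=2.0, tp=12.0,
                                duration=300.0, seed=5)
print(round(res.r2, 2), round(res.dissipated_fraction, 2))
# 1.31 0.99    (R_2% in metres; fraction of wave energy absorbed)
```

The SC medians rise through the recovery years; converting the healthy
and degraded medians to roughness spans an order of magnitude; and the
simulation shows the healthy reef absorbing essentially all incoming
energy while limiting 2%-exceedance run-up to well under the offshore
significant wave height. (Printed numbers are from the shown seeds; your exact
values depend only on the seeds.)

The same stages run from the shell:

```bash
reefshield all --profile desk --seed 7 --out runs/demo
reefshield simulate --bathy runs/demo/bathymetry.csv \
    --kn runs/demo/state_kn.csv --hs 2 --tp 12 --duration 600 --seed 7
```

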