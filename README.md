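# soyco2

Analysis chain for photosynthetic down-regulation of soybean (*Glycine
max*) grown across a wide CO₂ gradient (400–1600 ppm) in environmental
growth chambers. The package is aimed at plant ecophysiologists who want
a tested, scriptable version of the standard leaf-level workflow:

1. **FvCB A–Cᵢ curve fitting.** Net assimilation is modelled as the
   minimum of the Rubisco-limited and RuBP-regeneration-limited rates,

   A_c = V_cmax (Cᵢ − Γ*) / (Cᵢ + K_c (1 + O/K_o)) − R_d
   A_j = J (Cᵢ − Γ*) / (4 Cᵢ + 8 Γ*) − R_d,

   fitted to 12-step A_n–Cᵢ ladders by exhaustive limb-partition search
   with exact bounded linear least squares per partition; under
   saturating light the fitted J is reported as J_max. Water-use
   efficiency is WUE = A_n / T_r.
2. **Stomatal morphometrics.** Density (mm⁻²), shape index
   SSI = 100·√SA/SP (capped at 100/(2√π) ≈ 28.21 % by the isoperimetric
   inequality), area index SAI = density × mean stomatal area, and the
   percent-change statistics that compare CO₂ treatments.
3. **Spatial pattern of stomata.** Ripley's K with translation edge
   correction, the L-transform L̂(d) − d = √(K̂/π) − d, pointwise Monte
   Carlo CSR envelopes (100 replicates, 95 %) and per-scale
   regular/random/clustered classification, plus CSR, hard-core and
   Thomas-cluster simulators.
4. **Dose–response optima.** Quadratic OLS per trait with the vertex
   −c₁/(2c₂) as the optimal CO₂ concentration, linear fits, and one-way /
   balanced two-way fixed-effects ANOVA.
5. **Tissue chemistry.** C/N ratios and total non-structural
   carbohydrates (TNC = soluble sugar + starch) per tissue × treatment.

Because no raw chamber data are publicly deposited, a seeded
synthetic-study generator (`soyco2.simulate`) emulates the full design —
7 treatments × 5 pots, the cuvette ladder 50…1600 ppm, 30 stomatal fields
of 0.16 mm² per surface with hard-core regularity, and trait tables drawn
around the published treatment means/SDs — so every stage runs and is
testable end to end, with the generating truth retained for recovery
checks.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_fit_aci_curves.py
python analysis/03_dose_response.py
```

prints

```
wrote study (seed=1) to results/data
  35 A-Ci curves x 12 steps
  2100 stomatal fields, 19193 stomatal coordinates
fitted 35 curves -> results/aci_fits.csv
  median |Vcmax error| = 1.92 %
  median |Jmax  error| = 1.26 %
  median fit R^2       = 0.9988
  vcmax              R^2=0.96  maximum at 590 ppm
  jmax               R^2=0.98  maximum at 423 ppm
  an_growth          R^2=0.97  maximum at 678 ppm
```

i.e. the FvCB fits recover each pot's generating V_cmax and J_max to
within ~2 %, and the quadratic dose–response places the V_cmax optimum at
590 ppm — the generator's truth profile peaks at 600 ppm — while J_max
peaks near its 390 ppm truth. `04_stomatal_traits.py`,
`05_stomatal_pattern.py` and `06_tissue_chemistry.py` continue the chain
(trait tables with ANOVAs, Ripley envelopes per field, chemistry
summaries). The same chain is available as a CLI (`soyco2 simulate`,
`soyco2 fit-aci`, `soyco2 ripley`, `soyco2 report`, …) and as one call,
`soyco2.pipeline.run_pipeline`, which writes a deterministic
`report.json`.

The library is importable directly:

```python
from soyco2 import FvCBParams, fvcb_assimilation, percent_change
fvcb_assimilation(FvCBParams(vcmax=100, j=150, rd=1.5), ci=300)
# (23.524, 'rubp')
percent_change(92.6, 126.4)   # adaxial stomatal area, 400 -> 1200 ppm
# 37.0
```

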