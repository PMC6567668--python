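# Methods

This note documents the models, estimators and numerical choices behind
`soyco2`, the defaults that matter, what the synthetic-study generator
does and does not emulate, and the known limitations.

## FvCB model and A–Cᵢ estimation

Net assimilation is the minimum of two limitation limbs,

    A_c = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko)) − Rd        (Rubisco)
    A_j = J (Ci − Γ*) / (4 Ci + 8 Γ*) − Rd                   (RuBP regeneration)

with mesophyll conductance taken as infinite (C_c = Cᵢ): the data are
A_n–Cᵢ ladders, not A_n–C_c, and fitting on Cᵢ matches the standard
field workflow. Kinetic constants default to the usual 25 °C values
Kc = 404.9 μbar, Ko = 278.4 mbar, Γ* = 42.75 μbar, O = 210 mbar
(measurements are made at 25 °C growth temperature); all are
configurable, and Cᵢ in μmol mol⁻¹ is treated as μbar (ambient
pressure). The triose-phosphate-limited limb and Arrhenius temperature
scaling are deliberately out of scope.

**Estimation.** For each candidate transition between consecutive
observed Cᵢ values with at least three points per limb, points below the
transition are assigned to A_c and points above to A_j. With the kinetic
constants fixed, the partitioned model is *linear* in (Vcmax, J, Rd), so
each partition is solved exactly by bounded linear least squares
(`scipy.optimize.lsq_linear`, BVLS, bounds Vcmax, J ∈ (0, 2000],
Rd ∈ [0, 10] μmol m⁻² s⁻¹). This replaces the common multi-start
nonlinear search: the per-partition optimum is global and deterministic,
so no starting-value policy is needed. The partition with minimal SSE
wins; exact ties break toward the lower transition Cᵢ, which is reported
as the midpoint of the straddling cuvette steps. R² is 1 − SSE/SST,
clamped to [0, 1].

**Rd policy.** Dark respiration measured separately may either be fixed
(`rd_policy="measured"`) or, by default, estimated jointly within
[0, 10]; which of the two a given lab used is rarely stated, so both are
first-class.

**J vs J_max.** Curves are measured at saturating PPFD
(1500 μmol m⁻² s⁻¹), so the fitted J is reported as J_max. For
non-saturating light, `jmax_from_j` inverts the non-rectangular
hyperbola (defaults θ = 0.9, α = 0.3) as an opt-in correction.

## Stomatal morphometrics

Density = count / field area (fields are 0.16 mm², read as 400 × 400 μm;
configurable). SSI = 100 √SA / SP is computed per stoma and averaged
("mean of ratios", the default) because published per-treatment SSI
agrees with that order of aggregation; the ratio-of-means variant is
kept and the two differ by < 10 % for realistic size variation
(CV ≤ 0.3). SAI implements the literal definition density × mean stoma
area with explicit μm² → mm² conversion, which yields fractions of a
percent; published SAI tables are ~60× larger (a per-field or per-section
normalisation that is never stated), so an optional `scale` factor exists
and the discrepancy is surfaced rather than silently corrected. Percent
changes round half-up (away from zero), so 36.50 % prints as 37 %.
Per-stoma records enforce the isoperimetric inequality SP² ≥ 4π SA;
traced outlines that violate it are data errors.

## Ripley's K / L analysis

K̂(d) = |W| / (n(n−1)) Σ_{i≠j} w_ij 1(d_ij ≤ d), with translation
edge-correction weights w_ij = |W| / ((W−|dx|)(H−|dy|)) by default
(`none` is kept for oracle tests). The transform L̂(d) − d = √(K̂/π) − d
is zero in expectation under complete spatial randomness; negative
values indicate regularity (inhibition), positive values clustering.
Distances beyond half the shorter window side — where the translation
correction loses validity — are NaN with a warning. The default grid is
0–200 μm in 2 μm steps.

Envelopes are **pointwise**, conditional on the observed n (binomial
CSR, not estimated-intensity Poisson), from 100 seeded simulations at
α = 0.05. Quantiles use the Weibull plotting position (rank p(m+1)), so
a fresh CSR realisation falls outside each bound with probability α/2 in
expectation; measured two-sided exceedance is ≈ 5 % (±2 points over 200
trials). Scales are labelled regular below the lower bound, clustered
above the upper, random between; the "regular range" is the longest
contiguous regular run. Simultaneous (global) envelopes and the pair
correlation function are out of scope.

Simulators: binomial CSR; simple sequential inhibition for hard-core
patterns (rejection sampling with a packing feasibility pre-check at the
0.547 random-sequential-adsorption jamming bound and a proposal budget);
Thomas cluster process (Poisson parents, Poisson(μ) Gaussian-displaced
children, edge children discarded). Exactly coincident digitised points
are deterministically nudged apart by ≤ 0.01 μm with a warning, since
K is undefined at zero distances.

## Dose–response and ANOVA

Trait optima are quadratic OLS vertices x_opt = −c₁/(2c₂); a vertex
outside the dosed range widened by half its span is flagged
`extrapolated`, never suppressed. Linear fits report the two-sided slope
p-value. One-way ANOVA is the classical F = MSB/MSW on (k−1, N−k) df;
two-way ANOVA implements the balanced complete decomposition with
interaction (closed form — this keeps 1000-replicate null simulations
cheap; the design is balanced by construction, which avoids
sum-of-squares-type ambiguity, and unbalanced inputs are rejected with
instructions to aggregate). A term with zero sum of squares reports
F = 0, p = 1 even when the residual mean square is also zero. No
multiple-testing correction is applied (per-trait testing at p < 0.05).

## Tissue chemistry

Concentrations are dry-weight based (mg g⁻¹). C/N and TNC = soluble
sugar + starch are computed per sample, then averaged across pots —
statistically preferable to ratios of means, and the two orders agree to
rounding for the published tables. Cells with one sample report a
missing SD; empty cells are missing rows, not errors.

## Synthetic-study generator

The generator reproduces the study design: 7 CO₂ treatments (400–1600
ppm by 200) × 5 pots; one 12-step A–Cᵢ ladder per pot at the cuvette
levels 50, 100, 150, 200, 300, 400, 600, 800, 1000, 1200, 1400,
1600 ppm; 30 coordinate fields of 0.16 mm² per surface and pot; 6
measured stomata per surface and pot; chemistry and anatomy per pot.
Defaults:

* **FvCB truth** follows quadratic profiles — Vcmax = 120 − 8·10⁻⁵(C−600)²,
  J = 190 − 9·10⁻⁵(C−390)², Rd = 2.2 − 2·10⁻⁶(C−900)² μmol m⁻² s⁻¹ —
  peaking at 600 / 390 / 900 ppm respectively, so that downstream vertex
  estimation has an interior optimum to recover. Pot-level truth is the
  profile times a 5 % CV Gaussian factor.
* **Gas-exchange noise** is i.i.d. Gaussian, SD 0.5 μmol m⁻² s⁻¹ on A_n.
  G_s and T_r are filled by a simple empirical coupling (G_s increasing
  with A_n; T_r = G_s·VPD/P at VPD 1.2 kPa) so the schema is complete.
* **Stomatal fields**: per-field counts are Poisson at the published
  density × 0.16 mm²; positions are hard-core with inhibition radius
  30 μm (adaxial) / 20 μm (abaxial), falling back to CSR with a warning
  if packing ever became infeasible. All other stomatal, anatomical and
  chemical traits are lookups at the published treatment means with
  noise at the published SDs (lognormal for sizes, Gaussian otherwise).
  Per-stoma perimeters derive from a truncated-normal shape index, which
  guarantees the isoperimetric constraint by construction.

The cuvette ladder is used directly as the Cᵢ grid; real Cᵢ sits below
cuvette CO₂, but only the grid's realism matters to the estimator. The
generator does **not** emulate chamber microclimate, growth through
time, within-leaf spatial trends in density, correlated trait errors, or
between- vs within-pot variance partition (a single noise level per
trait). Passing recovery tests therefore demonstrate estimator
correctness under the assumed error model, not robustness to every
failure mode of real gas-exchange or microscopy data.

All randomness flows from a single study seed through named
`SeedSequence` substreams per stage, so any one table can be regenerated
without running the others.

## Problem sizes and runtime defaults

The pipeline analyses 35 curves (7 × 5) and, for the spatial stage, 2
fields per treatment × surface with ≥ 8 points (adaxial fields at the
published densities often carry too few stomata for a meaningful K, and
n < 8 has essentially no envelope power). Calibration experiments use
200 envelope trials, 50 hard-core detection runs, 100 noisy-curve
recoveries and 1000 ANOVA null replicates; these sizes give Monte Carlo
error comfortably inside the asserted tolerances.

## Known limitations

* No TPU limb or temperature response; fits at one leaf temperature.
* The exhaustive-partition fit assigns each point wholly to one limb;
  near the transition the true minimum-limb model blends, which can
  bias the transition Cᵢ by up to one cuvette step (parameters are
  unaffected on noiseless data).
* Pointwise envelopes test each scale marginally; the regular-range
  summary inherits the usual multiple-scale caveat.
* The published SAI normalisation and adaxial/abaxial-ratio basis cannot
  be reconstructed from the stated definitions; the package reports the
  literal formulas and surfaces the discrepancy.
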