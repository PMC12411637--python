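# Methods

This note documents the dose-assessment model implemented by `normdose`,
its assumptions, parameter choices and known limitations.

## Scope and pathway model

The package computes annual effective doses to a reference worker from
three pathways — external gamma radiation, inhalation of radioactive
dust, and inhalation of radon and its progeny — and sums them per
scenario. Ingestion of material is excluded by construction: with
standard occupational hygiene (gloves, hand washing, no eating in work
areas) its contribution is negligible, and no ingestion pathway is
modelled. Specific activities are treated as static measured inputs;
no decay-chain ingrowth (Bateman) computation is performed, which is
appropriate on occupational timescales for the long-lived nuclides
involved.

The packaged material vectors are averages for Pacific nodules (bulk),
with per-nuclide relative uncertainties of 13–45%, and the two enriched
process streams derived from them. Natural background is embedded in the
measured values; no separate background term is added or subtracted,
which errs on the conservative side.

## External gamma

For bulk NORM the gamma field is driven by Ra-226, standing proxy for
its short-lived daughters Pb-214/Bi-214 with which it is largely in
secular equilibrium; the Th-232 series (at natural-background levels in
nodules) and airborne radon progeny are neglected as gamma sources. The
ambient dose equivalent rate is taken proportional to the Ra-226
specific activity with a tabulated geometry factor (µSv/h per Bq/g):
0.5 for a laterally infinite surface, 0.4/0.2 for a stockpile cone
(surface / 1 m), 0.3/0.07 for a 1 m³ big bag, 0.3/0.15 for two big
bags. These factors are data, not computed: no photon transport,
buildup or attenuation physics is modelled. A helper applies
inverse-square fall-off for distances beyond the lateral source
dimensions; nearer the source the tabulated values take precedence.
Shielding enters as a scalar transmitted fraction a_s (0.5 for the
2 cm steel separating an engine room from a cargo hold). H*(10) is
converted to effective dose with f_con = 0.6.

## Dust inhalation

Committed effective dose uses the AMAD-5 µm occupational inhalation
coefficients (µSv/Bq) for the twelve dose-relevant nuclides above the
0.1 µSv/Bq cutoff — S absorption class for thorium isotopes, F for
Ac-227, M otherwise. Nuclides absent from the coefficient table
contribute zero (they are below the cutoff) and are logged. Breathing
rate defaults to 1.2 m³/h; dust concentrations default to the workplace
limits of 1.25 mg/m³ (routine areas) and 3 mg/m³ (occasional exposure,
e.g. filter maintenance). Dust is assumed to carry the bulk material's
nuclide vector — no size-fraction enrichment, aerosol physics or lung
deposition modelling. Respiratory protection enters as a removed
fraction f_inh (0 by default; an FFP-2 mask removes up to 94%).

## Process-stream enrichment

All non-volatile nuclides are assumed to transfer completely into the
slag of the third reduction stage (3.0 → 1.374 Mt/a, enrichment 2.183,
reported as 2.2); Pb-210 and Po-210 volatilize at smelting temperature
and collect quantitatively in the first-stage filter dust
(3.0 → 0.297 Mt/a, factor 10.10, reported as 10.1). Both assumptions
are conservative bounds, not thermochemical predictions. By default the
volatiles are additionally retained ("double-counted") in the slag
vector so slag doses are not underestimated; this intentionally breaks
activity conservation for those two nuclides. Two arithmetic modes are
provided: full precision (exact mass-ratio factors; activity exactly
conserved for non-volatiles) and a printed-rounding mode (factors
rounded to one decimal, activities to integer Bq/kg) that reproduces the
reference activity table to within ±1 Bq/kg per nuclide. The rounded
slag factor 2.2 exceeds the exact 2.183 by 0.8%, an accepted
conservatism of the reporting convention; trace activities (e.g. 3 Bq/kg
U-235) are dominated by integer rounding in that mode. Slags of the
first/second reduction and dryer dust carry significantly lower
concentrations and are not assessed by default, though arbitrary streams
can be constructed.

## Radon

The exhalation model treats a nodule layer thicker than a few diffusion
lengths (> 3 m) as a semi-infinite extended source: radon produced by
Ra-226 decay escapes the grains with emanation probability E(Θ) = 0.36
(dry; moisture-dependent, and roughly half for water-saturated material
— wet scenarios need a user-supplied value) and diffuses through the
pore space with D_bulk = D_MA · porosity = 1·10⁻⁵ × 0.6 = 6·10⁻⁶ m²/s,
giving surface flux P = C_Ra-226 · E · ρ · √(D_bulk/λ) · λ with bulk
density ρ = 3300 kg/m³. The Rn-222 decay constant is fixed at
2.1·10⁻⁶ s⁻¹, the rounded value used throughout the reference
calculations (the unrounded 2.0993·10⁻⁶ changes results below the
reporting precision).

Indoor accumulation follows a single-zone mass balance
dC/dt = e′ + v·C_a − (λ + v)·C with entry rate e′ = P·A/V for surface
exhalation — the effective exhaling area being the pile footprint, since
only the top surface feeds the head space when diffusion is the sole
transport mechanism in the voids — or e′ = R·f_indoor/V for the
comminution source R = C_Ra-226 · f_com · pc (release fraction
f_com = 0.3 of the stored radon at a processing capacity pc ≈ 95 kg/s,
half of it indoors). The steady state C = e′/(λ + v) and the transient
exponential relaxation are evaluated in closed form; rate conversions
use the exact 1/3600, not rounded per-second figures, which matters at
the hundreds-of-Bq/m³ level. No multi-zone ventilation network and no
progeny attachment/plate-out are modelled — the equilibrium factor
F = 0.4 subsumes progeny behaviour.

Dose uses E = C · t_exp · F · DCF with the ICRP-65-consistent
DCF = 7.8·10⁻⁶ mSv·m³/(Bq·h), consistent with the regulatory
equivalence of 0.32 MBq·h/m³ per mSv at F = 0.4. The roughly twofold
larger ICRP-137 coefficient is exposed as a named constant but is not
the default, since it has not been adopted by the regulations this
assessment follows.

## Scenario engine

A scenario binds pathway configurations to named materials. The radon
contribution is reported separately from the gamma+dust subtotal because
its concentration input reflects facility design and ventilation rather
than the material vector. The ×3 surface-layer sensitivity multiplier
scales the material activities — and hence, by linearity, the gamma and
dust doses exactly threefold — while a fixed radon concentration is left
untouched. Reports keep full-precision values; rounding (two significant
figures) happens only at the display layer. Classification compares the
total against 1 mSv/a (occupationally exposed) and 20 mSv/a (annual
limit). The exposure-time budgets are deliberately independent per
pathway (2000 h transport gamma; 400+400 h storage gamma; 1000 h dust;
24 h maintenance; 2000 h radon), mirroring the conservative convention
of assessing each pathway at its own bounding occupancy.

## Synthetic scenarios / Monte Carlo

The generator emulates the measured data's statistical structure:
each specific activity is sampled from a lognormal parameterized so the
*arithmetic mean* equals the tabulated activity and the CV equals the
tabulated relative uncertainty. The mean-preserving (rather than
median-preserving) parameterization is a deliberate choice: all pathways
are linear in the activities, so the expected Monte Carlo dose equals
the deterministic dose, which anchors the propagation to the central
case. Nuclides are sampled independently by default; a shared uniform
surface-layer multiplier (study range 1–3) serves as an optional
common-mode factor for correlated enrichment, and bounded multiplicative
perturbations are available for dust concentration, exposure times and
shielding. The derived process-stream fixtures inherit the bulk
per-nuclide relative uncertainties, since relative errors pass unchanged
through linear mass-ratio enrichment. Randomness comes from one
explicitly seeded generator per run — no global state — making summary
statistics reproducible across platforms. What this generator does *not*
emulate: spatial variability between mining fields, correlated
measurement error across nuclides sharing a decay series, or
non-lognormal tails; passing tests therefore demonstrate correct
propagation of the stated uncertainty model, not validated field-scale
dose distributions. This is forward propagation only — no Bayesian
calibration against measurements.

Default problem sizes (10,000 draws for moment-recovery checks, 5,000
for dose mean-recovery, a few hundred for distribution-shape checks)
were chosen so sampling error sits well below the tested tolerances
while the whole suite completes in seconds.

## Numerical and degenerate-input conventions

All activities are stored in Bq/kg, coefficients in µSv/Bq, doses
reported in mSv/a; every unit conversion lives in one module. Inputs are
validated at construction (negative activities, transmitted fractions
outside [0,1], non-positive volumes, λ + v = 0 sinks all raise). An
empty nuclide vector is valid and yields zero dose; nuclides without
dose coefficients contribute zero dust dose. The transient radon
solution handles t = 0 exactly and relaxes to the steady state; the
degenerate no-sink case is rejected rather than returning infinity.

## Known limitations

- Gamma geometry factors are order-of-magnitude tabulations; site
  geometries outside the four tabulated cases need a user-supplied
  factor.
- The printed-rounding flowsheet mode reproduces the reference table's
  display arithmetic, which conserves activity only approximately (see
  above); use full-precision mode for mass-balance work.
- Laboratory-scale handling scenarios (small samples, fume hoods) are
  out of scope; the packaged scenarios are industrial-scale bounding
  cases.
- The radon model is single-zone and steady-state/first-order; it cannot
  represent stratification, short-circuiting ventilation or progeny
  dynamics beyond the fixed equilibrium factor.
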