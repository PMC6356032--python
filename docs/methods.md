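# Methods

## Scope and model structure

`owbscreen` is a deterministic screening model: no probabilistic layer, no
dermal-absorption modelling (DNELs are external doses), and no
route-to-route extrapolation. Exposure for each contributing scenario of
the four generic exposure scenarios (professional spray; professional seed
and granular application; consumer spray; consumer spreading) is predicted
from unit exposures — mg of substance reaching a route per kg handled — and
all permutations of the exposure determinants are enumerated so the worst
case per reporting group can be selected transparently.

## Unit-exposure calibration

The built-in BBA unit exposures were back-derived from the reference output
tables of the OWB v3.3 tool (`UE = E · reference / Q`, with reference = 70
kg body weight for the dermal route and 10 m³ breathing volume per work day
for inhalation). The calibration is anchored on the tractor-boom rows at a
daily amount of 23.12 kg, which together with the printed daily amounts
9.25 kg (air-blast) and 0.77 kg (hand-held) fixes

* effective application rates 1.156 kg/ha (tractor) and 0.768 kg/ha
  (hand-held) — the printed "1.16" and "0.77" are display rounding;
* daily treated areas of 20 ha (boom), 8 ha (air-blast) and 1 ha
  (hand-held);
* a breathing volume of 10 m³ per work day (1.25 m³/h × 8 h light work),
  the unique value making the inhalation rows consistent with the dermal
  rows.

These choices are mutually consistent: the boom-calibrated loading unit
exposures reproduce the air-assisted loading rows at Q = 9.25 kg/day to the
printed precision, which the test suite asserts for every formulation and
route. Loading unit exposures are shared between boom and air-blast
equipment (the same transfer task); application unit exposures are
per-technique and formulation-independent, since dilution in water occurs
before spraying.

One rounding artifact is knowingly tolerated: the reference table prints a
total RCR of 0.188 for the hand-held WP loading row, but its own printed
route exposures give 0.549/3 + 0.0614/11 = 0.1886 → 0.189 at three
decimals (the tool rounded unrounded internal exposures that cannot be
recovered from the printed output). The tests assert 0.189.

## Greenhouse vapour term (constant rate release model)

For hand-held spraying indoors, substances with vapour pressure above the
0.1 Pa threshold add a vapour inhalation term from a well-mixed single-zone
balance `dC/dt = S − q·C` with constant source `S = 100·AR/(h·t_r)`
(mg/m³/h; the factor 100 converts kg·ha⁻¹·m⁻¹ to mg/m³). Integrating the
concentration over the worker exposure time `t ≤ t_r` and averaging over
`T` gives

    TWA = (100/T) · AR/(q·h·t_r) · [ t + expm1(−q·t)/q ]

implemented with `expm1` because the naive form loses all precision in the
weak-ventilation limit, where the bracket collapses to `q·t²/2` and the TWA
tends to `100·AR·t²/(2·h·t_r·T)`. The closed form is property-tested
against independent numeric ODE integration (relative error < 1e−6 across a
randomized parameter sweep) and against that limit. Exposure times beyond
the release duration are rejected: the model covers the release phase only.
The defaults (q = 1 h⁻¹, h = 4 m, t_r = t = T = 8 h) are representative
registry values; the declared greenhouse volume V is informational only,
the height h carrying the geometry. Whether the TWA should be averaged
over T = 8 h or the task duration is an open choice; the registry default
documents T = 8 h.

## Re-entry and bystander models

Re-entry dermal exposure is `DFR₀ · n · AR · TC · duration / (bw · 1000)`
with n = 2 applications, TC = 5000 cm²/h (a EUROPOEM-style upper transfer
coefficient), 8 h work and 70 kg body weight; the residue-per-rate constant
DFR₀ was back-calibrated (0.6644 µg/cm² per kg/ha per application) so the
model reproduces the reference row (0.8778 mg/kg bw/day) at the tractor
rate of 1.156 kg/ha — which rate underlies the published row is not stated,
and the tractor rate is the choice that reproduces it with these transfer
defaults. Volatile substances (≥ 0.1 Pa) are assigned zero re-entry
exposure (complete evaporation within a day). Note the deliberate
asymmetry of the comparison operators as specified per model: re-entry uses
≥ 0.1 Pa, the greenhouse and bystander vapour add-ons use > 0.1 Pa; the
registry stores a single threshold and each model applies its own operator.

Bystander dermal exposure converts the rate to an areal deposit (1 kg/ha =
0.01 mg/cm², a dimensional identity) scaled by the drift fraction, a 17500
cm² whole-body area and 60 kg body weight; inhalation uses a bystander unit
exposure per kg handled over the boom day, divided by the inhaled volume
(1.25 m³/h × 8 h). Drift fraction (0.0448) and the inhalation unit
exposure (0.00441) were back-calibrated against the reference row
(0.1512 / 0.0102 at 1.156 kg/ha). Bystander RCRs always use the
general-population DNELs, and the bystander (and re-entry) constraints
participate in the use-rate maximization of both technique groups at each
group's own candidate rate.

## Correlated tasks and use-rate maximization

Mixing/loading and application are performed by the same workers, so the
binding quantity is the per-technique combined RCR: worst loading
formulation for that technique plus that technique's worst application
variant. On RCR ties between the hand-held outdoor and indoor application
variants the greenhouse variant is preferred — the vapour add-on makes
indoor ≥ outdoor identically, so this is the conservative stable
representative. The group worst case is the maximum over techniques, never
the cross-technique sum of per-scenario maxima (which would over-predict).

Every exposure pathway is homogeneous of degree one in the application
rate, so the maximized rate per technique group is exactly
`target_rcr / max_c slope_c` over the constraints (combined per technique,
re-entry, bystander), with slopes measured at a 1 kg/ha probe. The test
suite cross-checks this closed form against independent bisection
(`brentq`) to 1e−9 relative on randomized substances, and verifies that the
binding constraint sits on the target while a 0.1 % larger rate exceeds it.
Maximization operates on unrounded RCRs; rounding is display-only
(half-away-from-zero, as in the reference tables). Per-group rates are
independent; a `single_rate` convenience flag collapses them to the global
minimum. If no constraint has positive slope the rate is reported as
unbounded, not as a number.

GES2 correlation is restricted to two pairs — seed-treatment loading with
bagging, and granule loading with dispersal — because seed treatment and
dispersal are not performed by the same individuals; no RCR is ever
combined across those groups.

## Registry values and their status

Constants fall into three provenance classes, each tagged in
`data/default_registry.yaml`:

1. **Back-derived** from the reference output tables (all BBA unit
   exposures, DFR₀, drift fraction, bystander inhalation UE). These carry
   the reproduction tests and the acceptance quantities.
2. **Standard defaults** stated directly by the model description (body
   weights 70/60 kg, 0.1 Pa threshold, 200 m²/day consumer cap, 2 re-entry
   applications).
3. **Synthetic defaults** for constants whose originals are in non-public
   supplementary material (greenhouse parameters, PHED dispersal and
   bagging surrogates, the 75th-percentile spray series, residential
   spreading values, seed-treatment daily amount, bystander vapour term).
   These are representative order-of-magnitude values, clearly labelled
   `synthetic default`. Tests against them are structural — linearity,
   monotone banding, percentile dominance, LEV arithmetic, lookup
   round-trips against the registry itself — and demonstrate the
   machinery, not the absolute exposure levels real supplementary constants
   would produce.

Protection is a screening simplification: gloves (PF 10) and coveralls
(PF 5) divide the whole-body dermal estimate multiplicatively (no per-body-
part split), RPE divides inhalation by 10 or 20, and LEV (90 % reduction)
applies only where the scenario supports it (bagging). Protection can be
applied to an estimate exactly once; provenance records the applied
selection. The PHED values already assume working clothes, so no
additional coverall credit is layered on top by default. Consumer
scenarios accept no protection at all, use 60 kg body weight, cap the daily
treated area at 0.02 ha, and use the 75th-percentile series, stored as a
distinct percentile series rather than a scalar multiplier on the geometric
means.

## Numerical choices and degenerate inputs

* Display rounding is half-away-from-zero via `decimal`, applied only at
  serialization; all internal arithmetic is double precision, unrounded.
* Worst-case ties break deterministically on canonical enumeration order
  (techniques boom, air-blast, hand-held; formulations liquid, WP, WG;
  first maximum wins), exercised by the all-zero-rate case.
* Zero application rate is valid everywhere and yields exactly zero
  estimates; negative rates, non-positive calibration amounts, double
  protection, indoor non-hand-held application, separate hand-held-loader
  estimates and cross-population combination are rejected with typed
  errors.
* Assessments are pure functions of their inputs; re-running a request is
  bit-identical, and the writers emit byte-stable CSV/JSON/text.

## Problem sizes

All computations are closed-form algebra over at most a few dozen
permutations; a full four-GES assessment plus maximization runs in
milliseconds. The property sweeps (CRRM vs. ODE oracle, bisection vs.
closed form) use 100 and ~20 randomized cases respectively, chosen as
comfortably exhaustive for smooth one-dimensional checks.

## Known limitations

* Absolute GES2/consumer exposures depend on synthetic registry defaults
  (class 3 above) until users supply their own registry document.
* The BBA data reflect 1980s application technology and aerosol exposure;
  predictions for volatile co-formulants are conservative for dermal
  (no evaporation from skin or spray) and the vapour add-on applies only to
  the greenhouse and bystander pathways, not tractor-mounted spraying.
* No resident (long-term) scenario, no multi-day residue dissipation beyond
  the two-application assumption, no children/toddler post-application
  scenarios, no aggregate worker+consumer exposure, and no dust-drift model
  for granules.
* The optional area-based dermal DNEL (mg/cm²) path computes a dermal-load
  RCR from a registry exposed-area constant but has no reference output to
  validate against.
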