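# owbscreen

A screening-level (tier 1) implementation of the ECPA operator, worker and
bystander (OWB) exposure model for **co-formulants in plant protection
products (PPP)**, as used in REACH chemical safety assessments. It is aimed
at risk assessors who need conservative dermal and inhalation exposure
estimates for the generic exposure scenarios (GES) of PPP use — professional
spray application (mixing/loading, spraying, greenhouses, worker re-entry,
bystanders), seed treatment and granule dispersal, and the consumer
analogues — without the many exposure determinants of the higher-tier PPP
models.

## The model

The empirical kernel is the **unit exposure** (UE): mg of substance reaching
a route per kg of substance handled, taken from the German BBA operator
model (geometric means) for spraying and from the US EPA PHED surrogate
table for granules and seeds. For an application rate *AR* (kg/ha) and a
technique treating *A* ha per work day, the daily amount handled is
*Q = AR·A* and

```
dermal     = UE_dermal · Q / bw            [mg/kg bw/day],  bw = 70 kg (worker)
inhalation = UE_inhal  · Q / V_breath      [mg/m³],         V_breath = 10 m³/day
```

Risk is characterized by the **risk characterization ratio**
`RCR = dermal/DNEL_dermal + inhalation/DNEL_inhalation`, with worker or
general-population DNELs as appropriate (bystanders and consumers always use
the general-population DNELs).

For hand-held spraying in greenhouses, volatile substances (vapour pressure
> 0.1 Pa) receive an additional inhalation term from the **constant rate
release model** — a well-mixed single zone ventilated at *q* air changes per
hour, with the sprayed amount released over *t_r* hours into an airspace of
height *h*:

```
T-hour TWA = (100/T) · AR/(q·h·t_r) · [ t + (e^(−q·t) − 1)/q ]    [mg/m³]
```

Worker re-entry uses a dislodgeable-foliar-residue × transfer-coefficient
model (zero for substances ≥ 0.1 Pa, which evaporate from foliage);
bystander exposure combines drift deposition on skin with an inhalation unit
exposure.

Mixing/loading and application are **correlated tasks** (the same workers do
both), so risk is managed on the per-technique *combined* RCR, never on the
cross-technique sum of the per-scenario worst cases. Because every model is
linear in the application rate, the **maximum use rate** for a target RCR
has the closed form `rate = target / max_c slope_c` over the combined,
re-entry and bystander constraint slopes.

Every constant lives in a YAML parameter registry with per-constant
provenance tags; constants whose published originals are not in the open
literature are clearly tagged as synthetic defaults.

## Worked example

Maximize the use rate of a hypothetical solid co-formulant (vapour pressure
0.001 Pa; worker DNELs 3 mg/kg bw/day dermal, 11 mg/m³ inhalation; general
DNELs 1.5 and 2.6) against a target RCR of 0.9, with no PPE:

```sh
owb maximize -c examples/reference_substance.yaml -o out/
```

```
wrote 4 files to out/
max use rate (hand_held): 0.768 kg/ha
max use rate (tractor): 1.156 kg/ha
```

The tractor group is bound by the trailed-boom combination (loading of the
wettable-powder formulation, RCR 0.675 at the returned rate, plus boom
application, RCR 0.225 — combined 0.900), even though the single worst
application task is air-blast spraying (RCR 0.508): the boom *combination*
exceeds the air-blast combination (0.778). The hand-held group is bound by
liquid knapsack loading (0.750) plus greenhouse application (0.150). At the
returned rates the air-blast daily amount handled is 9.25 kg/day.
`out/report.txt` lists every permutation row, the flagged worst cases and
the binding constraints; `out/*.csv` hold the permutation tables and
`out/assessment.json` the full-precision bundle.

The same runs are available as library calls (`run_full_assessment`,
`maximize_use_rate`, `ml_spray_exposure`, …) — see the module docstrings.

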