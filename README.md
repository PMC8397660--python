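# neutrosim

Quantitative systems pharmacology (QSP) simulation of neutropenia induced by
CELMoD-class drugs (cereblon E3-ligase modulators such as avadomide), for
pharmacometricians and modelers exploring dose/schedule trade-offs *in
silico*.

Unlike classic chemotherapy myelosuppression, CELMoDs do not kill
proliferating precursors: they reversibly **block late neutrophil
maturation**. The package models this mechanism end to end:

* a six-pool neutrophil **life-cycle ODE model** — proliferating precursors,
  three maturation transit stages, a bone-marrow reservoir of mature cells,
  and circulating neutrophils (the clinical ANC) — with the drug effect
  applied to the transit-2 → transit-3 maturation flux;
* **two-compartment oral PK** under multiple dosing (closed-form
  superposition) driving an **inhibitory sigmoid-Emax PD** effect;
* **direct-search fitting** (Nelder–Mead) of patient-level parameters from
  sparse longitudinal ANC tables;
* **virtual patient populations**: Anderson–Darling normality screening,
  Gaussian-KDE smoothing of fitted-parameter samples, independent sampling;
* **virtual dose/schedule trials** scored with CTCAE neutropenia endpoints
  (grade-3/4 incidence, ≥7-day events, recovery above grade 2, time to
  nadir);
* **two-sample Kolmogorov–Smirnov validation** of virtual cohorts against
  clinical-format ANC snapshots, and **PRCC global sensitivity analysis**.

## Model

States are concentrations (cells/L); time is hours; rates are 1/h.

```
dProl/dt    = k_prol · (T2₀/T2)^γ · Prol − k_tr1 · Prol
dT1/dt      = k_tr1 · Prol − (k_tr2 + k_d) · T1
dT2/dt      = k_tr2 · T1 − Vmax·E(C)·T2/(K_M + T2) − k_d · T2
dT3/dt      = Vmax·E(C)·T2/(K_M + T2) − (k_tr4 + k_d) · T3
dReserv/dt  = k_tr4 · T3 − (k_d + k_out·(Circ₀/Circ)^β) · Reserv
dCirc/dt    = k_out · (Circ₀/Circ)^β · Reserv − k_elim · Circ
```

with drug effect `E(C) = 1 − Emax·Cⁿ/(EC50ⁿ + Cⁿ)` evaluated on the central
PK concentration. Under the homeostasis assumption all transit/egress rates
are back-calculated from four patient-level traits — baseline ANC, the
reservoir/blood ratio, the Michaelis-constant fraction `K_M,fraction`, and
the proliferation-feedback exponent γ — plus the circulating half-life
(30 h) and a small maturing-cell apoptosis rate (0.001/h). The saturating
(Michaelis–Menten) maturation flux is what lets a maturation *block*
accumulate cells upstream without first-order compensation masking the drug
effect; the steep egress feedback (β = 20) holds the ANC at baseline until
the marrow reservoir is nearly exhausted, reproducing the clinically
observed 8–12 day latency before ANC decline.

## Worked example

Fit the three marrow traits of one patient from a sparse ANC profile
(days 1, 8, 15, 22, 28; 3 mg on a 5-days-on/2-off weekly schedule):

```python
import pandas as pd
from neutrosim import NeutropeniaModel

obs = pd.DataFrame({
    "patient_id": "PT01",
    "day": [1, 8, 15, 22, 28],
    "anc_cells_per_l": [4.500e9, 4.190e9, 2.539e9, 2.405e9, 1.943e9],
})
model = NeutropeniaModel.from_dataframe(obs, "3mg 5/7")
fit = model.fit(free=("gamma", "ratio_reserv0_circ0", "km_fraction"))
print(fit.summary())
```

```
Neutrophil life-cycle model fit (Nelder-Mead, weighted |normalized diff|)
==========================================================================
groups: 1   observations: 5   objective: 4.31334e-06
converged: True   iterations: 800   function evals: 2917
--------------------------------------------------------------------------
parameter                     estimate                    bounds
gamma                        0.0130229  [0.0001, 1]
ratio_reserv0_circ0            2.19994  [0.2, 20]
km_fraction                   0.130008  [0.005, 5]
--------------------------------------------------------------------------
fixed: circ0=4.5e+09, t_half_h=30, k_d_per_h=0.001, beta=20, ec50=15, n_hill=2
residuals (sim-obs)/obs: mean -0.0000, max|.| 0.0000
```

The objective is the weighted sum of absolute normalized differences between
simulation and data; `ratio_reserv0_circ0 ≈ 2.2` says this patient stores
about 2.2 blood-equivalents of mature neutrophils in marrow, and the small
γ ≈ 0.013 means a weak proliferative compensation — both typical lymphoma-
cohort values. (This profile was generated by the model itself with
ratio 2.2, γ 0.013, K_M fraction 0.13, so the fit recovers the truth.)

A virtual dose/schedule trial from the shell:

```bash
neutrosim synth --n 30 --dose 3 --schedule 5/7 --seed 42 \
    --out anc.csv --truth truth.csv
neutrosim vpop sample --traits truth.csv --n 200 --seed 1 --out cohort.csv
neutrosim trial --cohort cohort.csv --doses 4,6 --schedules "5/7,21/28" \
    --seed 1 --out summary.csv
```

yields one row per scenario (the same 200 virtual patients in each):

```
dose_mg schedule  gr3_single_pct  gr4_single_pct  gr3_7day_pct  recovered_gr3_pct  modal_nadir_day
    4.0      5/7            18.5             2.0           7.0                0.0               27
    6.0      5/7            33.0             7.0          14.0                0.0               27
    4.0    21/28            33.5             7.0          32.5               30.5               21
    6.0    21/28            52.0            14.0          49.5               48.5               21
```

The qualitative pattern matches clinical experience with intermittent CELMoD
dosing: 21 consecutive dosing days push more patients into prolonged
grade-3/4 neutropenia with the nadir locked to day 21, but the 7-day holiday
lets a large fraction recover above grade 2 within the cycle, whereas the
5/7 schedule mitigates incidence yet its 2-day holidays allow essentially no
recovery.

## Layout

| module | contents |
| --- | --- |
| `neutrosim.lifecycle` | states, traits, homeostatic cascade, ODE right-hand side |
| `neutrosim.pkpd` | PK/PD parameter sets, regimens, dosing expansion, exposure |
| `neutrosim.simulate` | patient/cohort simulation (LSODA, hourly effect grid) |
| `neutrosim.fitting` | objective, Nelder–Mead patient and multi-group fits |
| `neutrosim.model` | `NeutropeniaModel` / `NeutropeniaResults` facade |
| `neutrosim.vpop` | normality screen, KDE, virtual-cohort sampling |
| `neutrosim.endpoints` | CTCAE grading, recovery, nadir, scenario grids |
| `neutrosim.validation` | two-sample K-S validation, PRCC sensitivity |
| `neutrosim.synthetic` | synthetic clinical-format studies with known truth |
| `neutrosim.io`, `neutrosim.cli` | tables, parameter files, manifests, CLI |

See `docs/methods.md` for the modeling assumptions, parameter provenance,
numerical choices, and known limitations.
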