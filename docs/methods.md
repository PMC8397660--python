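# Methods

## Model structure and assumptions

The neutrophil life cycle is represented by six well-mixed pools:
proliferating precursors, three maturation transit stages, a bone-marrow
reservoir of mature cells, and circulating neutrophils. All pools carry
concentration units (cells/L) so the circulation pool maps directly onto a
clinical absolute neutrophil count. The structure encodes four biological
commitments:

1. **Maturation block, not cytotoxicity.** The drug scales the
   transit-2 → transit-3 flux by the PD effect and touches no other rate.
   That flux is Michaelis–Menten, `Vmax·E·T2/(K_M + T2)`: under a block,
   cells accumulating in transit 2 cannot push the flux back up once T2 ≫
   K_M, so a sustained block starves the downstream pools — a first-order
   transit would instead compensate and mask the drug effect.
2. **Reservoir buffering.** Mature cells are stored in marrow and released
   on demand. The egress feedback `(Circ₀/Circ)^β` with β = 20 acts almost
   as a switch: the ANC stays at baseline while the reservoir lasts, then
   falls quickly. This reproduces the characteristic 8–12 day latency of
   CELMoD neutropenia and makes the reservoir/blood ratio the dominant
   patient-level determinant of nadir timing and depth.
3. **Weak proliferative compensation.** Proliferation responds to transit-2
   depletion via `(T2₀/T2)^γ` with small fitted γ (~0.01–0.02), i.e. the
   marrow's compensatory drive is deliberately mild; proliferation is not
   driven by the circulating count.
4. **Homeostasis fixes the cascade.** With a circulating half-life
   `t½ = 30 h` (a mid-range literature value doubled for the neutropenic
   state; results are insensitive within the plausible range because all
   transit rates co-scale) and a small maturing-cell apoptosis rate
   `k_d = 0.001/h`, steady state determines every other rate from the four
   patient traits. The derived initial state is an exact fixed point of the
   drug-free system, which the test suite verifies to 0.1% over 28 days.

Patient individuality lives entirely in four traits: baseline ANC `Circ₀`,
reservoir ratio `Reserv₀/Circ₀`, `K_M,fraction` (K_M as a fraction of the
homeostatic transit-2 level), and γ. Everything else is shared.

Analysis is restricted to the first 28-day treatment cycle; multi-cycle
carry-over, G-CSF pharmacology, marginated pools, and population PK
variability are out of scope (clinically rescued observations are censored,
not modeled).

## PK/PD parameterization

Avadomide-like PK is a linear two-compartment oral model; multiple dosing is
evaluated by superposition of the closed-form single-dose solution on an
hourly grid (verified against direct ODE integration to 1e-6). The PD effect
`E(C) = 1 − Emax·Cⁿ/(EC50ⁿ+Cⁿ)` uses Emax = 0.9 (fixed), EC50 = 15 ng/mL and
n = 2 (reference values regressed from treatment-naive-cohort data; the
fitting module can re-estimate them, and the test suite demonstrates
recovery of both from three synthetic dose groups).

The source compound's PK constants are not public, so the package ships two
calibrated sets and a loader for user-supplied values:

* **`pk_default.json`** — oral kinetics of plausible magnitude (ka 0.5/h,
  CL/F 3 L/h, Q 2 L/h, Vp 40 L) with the central volume solved so cycle-1
  Cmax on 6 mg 5/7 is 143 ng/mL (23.83 ng/mL per mg), the published peak
  scale. CL/F was chosen, before any test was frozen, so that the simulated
  lymphoma cohort reproduces the published qualitative toxicity pattern
  (monotone dose–incidence on 5/7, recovery only with ≥7-day holidays,
  schedule-locked nadirs). This is the set used for all simulation.
* **`pk_exposure_calibrated.json`** — clearance solved so the trapezoidal
  cycle-1 AUC is 236.17 ng/mL·h per mg on 5/7 (1417 ng/mL·h at 6 mg),
  matching the published exposure table; use it when reproducing exposure
  numbers.

Two sets are necessary because the published AUC and Cmax columns are
mutually inconsistent for any concentration profile on an hourly grid
(20 doses peaking at 143 ng/mL contribute ≥ ~2860 ng·h/mL of trapezoid area
against a printed cycle AUC of 1417), and a profile matching the printed AUC
cannot produce any neutropenia at EC50 = 15 ng/mL — its time-averaged
maturation block is bounded by a few percent. The printed AUC is therefore
treated as a reporting scale rather than the PD-driving exposure.

## Numerical choices

* **Integration.** LSODA over the full horizon from the homeostatic initial
  state; the PD effect is precomputed on the 1 h PK grid and consumed as a
  piecewise-linear interpolant (the drug→marrow coupling is one-way). Oral
  absorption makes the forcing continuous, so no per-dose event segmentation
  is needed; `hmax = 4 h` guarantees daily peaks are sampled. Defaults
  rtol 1e-8, atol 1 cell/L; cohort screening and fitting use rtol 1e-6,
  atol 1e3 cells/L (max observed deviation 3e-4 relative). A jitted
  right-hand side is used when numba is importable; a pure-python closure is
  the reference implementation, and a fixed-step RK4 oracle test pins both
  to 0.01%.
* **Feedback safeguards.** Feedback ratios divide by state variables, so
  arguments are floored at 1 cell/L, and both multipliers are capped at 1e3.
  With β = 20 the uncapped egress feedback overflows double precision once
  the ANC falls below about half of baseline; at the cap the implied egress
  timescale (~minutes) is already far below every other timescale, so the
  quasi-steady-state ANC — set by flux balance — is unchanged while the
  stiffness stays bounded.
* **Optimization.** Nelder–Mead (the classic *fminsearch* workflow) in
  log-parameter space (positivity by construction), declared boxes enforced
  by a quadratic penalty and a final clip, plus one fresh-simplex restart:
  direct search stalls in this objective's weakly identified γ direction,
  and a deterministic restart is the standard remedy. The objective is the
  weighted sum of absolute normalized differences (weights default to 1;
  zero-valued observations are skipped, censored ones excluded).
* **Daily endpoint reduction.** Hourly ANC is reduced to per-day minima
  (day d = hours [24(d−1), 24d), last day closed); a neutropenic day is a
  day whose minimum is below threshold; the 7-day endpoint needs 7
  consecutive such days. Grade thresholds: 1e9 (grade 3), 5e8 (grade 4),
  recovery above 1.5e9 (grade 2, CTCAE convention; configurable). Nadir
  ties break to the earliest day.
* **K-S validation.** Default p-values use the classic asymptotic
  kstest2-style series with the Stephens small-sample correction (scipy's
  exact method is available by option). `validate_cohort` treats the
  multi-day comparison as one familywise decision at level α (Šidák-adjusted
  per-day levels): a valid cohort then passes *all* days with probability
  ≥ 1−α, which is the decision the workflow actually needs; per-day raw
  tests remain available (`familywise=False`). Because clinical ANC carries
  measurement error and model output does not, the cohort comparison can
  smear virtual snapshots with the declared measurement-noise model
  (`measurement_sigma`), making the null comparison like-with-like.
* **Sensitivity analysis.** Latin-hypercube sampling with PRCC scores.
  PRCC measures the *monotonicity* of each input–output relation after
  conditioning on the other inputs, so in a deterministic model every
  consistently monotone parameter scores near ±1 regardless of effect size:
  with the homeostatic cascade tying Vmax to K_M, `K_M,fraction` has a small
  but strictly monotone effect on the nadir and consequently a high PRCC,
  ranking above γ. The robust, seed-stable conclusion — verified in the test
  suite — is that the reservoir ratio dominates. Rankings should be read
  together with the raw score magnitudes and effect sizes.

## Synthetic data

No clinical trial data ship with the package; `neutrosim.synthetic`
generates clinical-format studies with known ground truth. Defaults encode
the study conditions the workflow targets: baselines uniform on 2–8 ×10⁹
cells/L (the clinically observed span), lognormal marrow traits around the
lymphoma-cohort medians (ratio 2.5, K_M fraction 0.1, γ 0.01; log-sd
0.2–0.3, a moderate between-patient spread chosen once as realistic for
fitted-parameter samples), sparse sampling at days 1, 8, 15, 22, 28,
multiplicative lognormal measurement noise with σ = 0.15, and a G-CSF
rescue fixture (trigger 5e8 cells/L, per-day probability 0.3) whose only
purpose is to exercise the censoring path. The generator runs on the same
solver settings as the fitting loop so closed-loop recovery studies measure
statistical identifiability rather than discretization mismatch.

What passing synthetic-data tests do show: the estimation machinery is
unbiased and precise under the model's own data-generating process, the
vpop/validation loop is self-consistent, and the endpoint machinery scores
trajectories correctly. What they cannot show: that the model structure is
right for real patients, that real fitted-parameter distributions look like
the synthetic ones, or that real measurement error is lognormal with
σ = 0.15.

## Problem sizes used in the shipped checks

Cohort-trend checks use 200 virtual patients over 10 scenarios; closed-loop
validation uses 20 replicate studies of 16 clinical-format patients against
100-patient virtual cohorts; noisy parameter recovery uses 20 replicate
fits. These sizes give stable qualitative statistics while keeping the full
suite to a few minutes; the library itself runs 1000-patient, 42-scenario
screens with the same code path.

## Known limitations

* Single cycle only; no intra-patient parameter drift, no G-CSF rebound.
* PK parameter sets are calibrated stand-ins, not transcriptions of the
  (unpublished) source values; absolute incidence percentages therefore
  depend on that calibration even though the schedule/dose orderings are
  robust to it.
* Exact published incidence tables are not reproducible without the
  original fitted patient-parameter distributions; the package reproduces
  them as qualitative trends.
* γ is only locally identifiable from sparse single-schedule profiles; its
  noise-free recovery relies on the restart policy and degrades quickly
  with measurement noise (the reservoir ratio stays well identified).
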