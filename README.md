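# il7r-pkpd

Model-based analysis of an anti-IL-7Rα monoclonal antibody in early clinical
development: target-mediated drug disposition (TMDD) pharmacokinetics with two
receptor targets, indirect-response dose-response models for CD4+ T-cell
subsets, population simulation, diagnostics, and estimation — exercised end to
end on synthetic trials that emulate a multiple-ascending-dose (MAD) study in
adults with type 1 diabetes.

## The problem

An IgG1 antibody blocks the interleukin-7 receptor alpha chain (IL-7Rα), which
exists both as a soluble protein (sIL7Rα) and as a membrane receptor on
T cells (cIL7Rα). Blocking IL-7 signalling depletes effector-memory T cells
(T_EM) more than regulatory T cells (T_reg), so the T_reg:T_EM ratio — a
tolerance biomarker in type 1 diabetes — can be *raised* by the right dose and
lowered again by too much drug. The package answers the study's central
quantitative questions: what drives the nonlinear PK, how much receptor is
occupied under each regimen, and which dose maximizes the T_reg:T_EM ratio.

## Models

**Quasi-equilibrium TMDD** (amounts in nmol; five states: central antibody
A₁, peripheral antibody A₂, soluble receptor A₃, cellular receptor A₄, SC
depot A₅):

    dA₁/dt = kₐA₅ + Q(A₂/Vₚ − FAB/V_c) − (CL_A·FAB + CL_C1·CPX₁ + CL_C2·CPX₂)/V_c
    dA₂/dt = Q(FAB/V_c − A₂/Vₚ)
    dA₃/dt = k_syn1 − (CL_SR·FSR + CL_C1·CPX₁)/V_c
    dA₄/dt = k_syn2 − (CL_CR·FCR + CL_C2·CPX₂)/V_c
    dA₅/dt = −kₐA₅

with the complex amounts CPX₁ (mAb:sIL7Rα) and CPX₂ (mAb:cIL7Rα) given at
every instant by coupled quadratic mass-action relations (binding assumed at
equilibrium), and FAB/FSR/FCR the free species by mass balance. Free receptor
occupancy is reported as Free RO % = 100·FCR(t)/(BL_CR·V_c).

**Indirect-response dose-response** for R ∈ {T_EM, T_reg} counts:

    R(t) = R₀ { e^(−k_out·t) + (1 − E_max·D/(ED₅₀+D)) (1 − e^(−k_out·t)) }

with dose D in mg/kg per 2 weeks, steady state R₀(1 − E_max·D/(ED₅₀+D)), and
k_in = R₀·k_out.

**Statistical layer**: log-normal inter-individual variability
P_i = P̂·exp(η_i), additive/proportional residual error
C = Ĉ(1+ε_p) + ε_a, LLOQ censoring flags, prediction-corrected VPCs, a
Laplace-type marginal-likelihood population fit of the dose-response models,
per-subject penalized TMDD fits, and a stratified nonparametric bootstrap.

## Worked example

```python
import numpy as np
from il7r_pkpd import (DoseEvent, argmax_dose, default_dr_pair,
                       default_tmdd, observe_free_ro, simulate_profile)

pair = default_dr_pair()
print(f"ratio-maximizing dose: {argmax_dose(pair):.2f} mg/kg q2w")

p = default_tmdd()
times = np.arange(0.0, 28.01, 0.25)
traj = simulate_profile(p, [DoseEvent(0.0, 70.0)], 70.0, times)  # 1 mg/kg, 70 kg
ro = observe_free_ro(traj)
print(f"Free RO at day 14: {ro[np.argmin(abs(times - 14.0))]:.1f}%")
```

prints

```
ratio-maximizing dose: 3.02 mg/kg q2w
Free RO at day 14: 70.8%
```

i.e. the steady-state T_reg:T_EM ratio peaks at ~3 mg/kg every two weeks (the
dose at which cellular-receptor occupancy is already near-maximal), and after
a single 1 mg/kg dose about 71% of the cellular receptor is free again two
weeks later — occupancy at this dose is lost between days 8 and 14 as the
free antibody drops below the receptor pool and target-mediated elimination
takes over.

The numbered drivers under `analysis/` walk the full workflow: the
dose-response curve (01), typical-subject occupancy profiles (02), virtual
study generation (03), parameter recovery across seeded trials (04),
bootstrap uncertainty bands (05), and prediction-corrected VPCs (06). Each
writes tables under `results/`. The `il7r-pkpd` console script exposes the
same steps as subcommands (`generate`, `simulate`, `fit-dr`, `bootstrap`,
`vpc`, `dr-curve`).

## Layout

- `src/il7r_pkpd/` — library: `binding` (QE solver + bracketing oracle),
  `tmdd` (ODE system, dosing, observables, unit bridges), `doseresponse`,
  `population` (IIV, residual error, trial simulation, pcVPC), `estimation`
  (population DR fit, per-subject TMDD fit, bootstrap), `datasets`
  (generator + NONMEM-style CSV dialect), `params` (published estimates),
  `cli`.
- `analysis/` — numbered narrative drivers.
- `tests/` — pytest suite, including end-to-end recovery checks.
- `docs/methods.md` — modelling assumptions, parameter provenance, numerical
  choices, and limitations.
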