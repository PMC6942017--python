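# Methods

## Scope and data

No clinical data ship with this package. Every analysis runs on synthetic
trials produced by `il7r_pkpd.datasets.generate_study`, which emulates the
design of the phase 1b multiple-ascending-dose study the models were
estimated from: three q2w cohorts (1, 3, 8 mg/kg SC on days 1, 15, 29, 43,
57, 71), one q1w cohort (6 mg/kg SC on days 1–78), pooled placebo subjects,
and the protocol's PK/biomarker sampling days. Default arm sizes follow the
study's analysis populations: 8/8/8/5 active subjects for the T-lymphocyte
streams plus 7 placebo (36 total), with a 5/8/8/5 subset contributing the
PK, soluble-receptor, and receptor-occupancy streams (the study excluded
three active subjects from that analysis).

## TMDD model

Two-compartment disposition with first-order SC absorption, linear
target-independent clearance, and quasi-equilibrium (QE) binding of the
antibody to two targets: soluble IL-7Rα and cellular IL-7Rα on T cells, each
synthesized at a constant rate and cleared as free receptor or as
drug–receptor complex. All state is carried in amounts (nmol). The published
symbol list calls the complex variables "concentrations", but the KD·V_c
terms of the QE expressions only balance dimensionally for amounts, and the
Discussion's input-rate arithmetic confirms that reading; the amount
interpretation is used throughout.

At each right-hand-side evaluation the coupled quadratic QE equations are
solved by damped Gauss–Seidel fixed-point iteration from CPX₁ = CPX₂ = 0
(relative tolerance 1e-12, 200 sweep budget, quadratics evaluated in the
cancellation-free citardauq form). A genuinely independent solver — a
bracketed Brent search on the scalar free-antibody mass balance, whose left
side is strictly increasing so the root is unique — serves both as the
fallback if the iteration stalls and as the cross-check oracle in the test
suite (agreement ≤ 1e-8 relative over six decades of random inputs).

Receptor synthesis rates are not free parameters: k_syn = CL·BL for each
target, which forces the drug-free system to sit exactly at its baseline
steady state and makes the initial conditions self-consistent. With the
published tie CL_C2 = CL_CR, total cellular receptor is constant, so free
receptor occupancy relative to baseline equals occupancy relative to the
instantaneous total; both normalizations are available.

Integration uses LSODA with rtol 1e-8 and atol 1e-10 nmol, restarted at
every dose event (SC doses enter the depot as F·dose). An output time that
coincides with a dose is reported pre-dose, matching trial sampling
convention.

### Parameters and units

Typical values are the published population estimates: CL_A 0.999 L/day,
V_c 1.10 L, V_p 5.28 L, Q 1.1 L/day (fixed), F 0.5 (fixed), k_a 0.211/day,
CL_SR 2.24 L/day, CL_C1 0.196 L/day, K_D1 0.779 nM, BL_SR 0.45 nM, CL_CR
10.4 L/day, CL_C2 = CL_CR, K_D2 0.450 nM, BL_CR 1.37 nM. One source table
note prints Q in L/h; the estimate table's L/day is used, consistent with
every other rate in the model.

Two constants the source does not state are fixed as package defaults: the
antibody molecular weight (150 kDa, the IgG1 convention) and the reference
body weight for typical-subject simulations (70 kg). The soluble-receptor
molecular weight is back-derived from the published baseline pair
(0.45 nM ↔ ~14 ng/mL), giving 31.1 kDa; with it, ng/mL = nM × MW(kDa)
exactly. Assay limits are kept as constants (PK LLOQ 75 ng/mL, ULOQ
1500 ng/mL; sIL7Rα 0.7/241 ng/mL).

### What the TMDD simulation reproduces — and what it does not

At the typical parameters the simulation reproduces the reported day-14
Free RO after a single 1 mg/kg dose (~71% simulated vs ~68% reported) and
the reported dominance of the target-mediated elimination pathway at 1 mg/kg
(free antibody falls below the cellular-receptor pool ~10 days after the
last dose). It does **not** reproduce the reported "≥98% occupancy
maintained" at 3 mg/kg q2w: with 70 kg/150 kDa the minimum occupancy over
all six intervals is ~93.5% (first-interval trough; ~96% at steady state).
An independent re-implementation of the same equations in R/deSolve gives
identical trajectories to four decimals, so this is a property of the
printed parameter set under these weight/MW assumptions, not a solver
artifact; 6 mg/kg q2w does maintain ≥98% in the same simulation. The
acceptance script reports the honestly computed value.

## Dose-response model

T_EM and T_reg absolute counts follow an inhibition-of-input indirect
response model driven by the fortnightly dose (not exposure): zero-order
input k_in = R₀·k_out, first-order loss k_out, and an Emax reduction of the
input. The published relation is printed with its symbols transposed
(R₀/k_out = k_in); the dimensionally correct product form is used, which
also reproduces the published input rates (4.2 and 1.4 cells/µL/day). The
6 mg/kg q1w cohort maps to 12 mg/kg/2wk — same cumulative fortnightly dose —
an assumption, flagged here, implied by the ED₅₀ unit.

Typical values: T_EM R₀ 63.1 cells/µL, k_out 0.0665/day, E_max 0.715, ED₅₀
0.353 mg/kg/2wk; T_reg R₀ 46.2, k_out 0.0308, E_max 0.700, ED₅₀ 7.06. The
closed form is verified against numerical integration of the underlying ODE
(≤1e-6 relative). The ratio-maximizing dose is found by a 0.01-step grid
scan over 0–16 mg/kg/2wk refined by bounded golden-section search (xatol
1e-4); a flat ratio curve returns the lower bound with a warning.

## Statistical model and trial simulation

Inter-individual variability is log-normal, P_i = P̂·exp(η_i), with the
published CVs: CL_A 42.5%, V_c 7.3%, k_a 31.3%, BL_SR 35.1%, and R₀/E_max
per cell population (41/21% T_EM, 33/27% T_reg); ω² = ln(1+CV²). Ω is
diagonal by default — a full PK block was estimated in the source but its
correlations were never printed, and inventing them seemed worse than
omitting them; a correlation matrix is accepted via `IIVSpec`. Individual
E_max draws can exceed 1 under a log-normal; they are capped at 0.999, the
structural model's validity bound.

Residual error follows C = Ĉ(1+ε_p)+ε_a with the published magnitudes
interpreted as SDs: PK proportional 0.434, sIL7Rα proportional 0.150,
Free RO additive 18.2 percentage points (applied on the Free-RO scale — the
source does not say which scale; flagged), T_EM 0.11, T_reg 0.061. Negative
simulated values are clamped to zero and flagged. PK values below LLOQ are
flagged BLQ and excluded from fitting (M1-style); no likelihood-based BLQ
handling. Note that a normal proportional error of SD 0.434 occasionally
produces near-zero observations even at high concentrations — a property of
the published error form, retained deliberately.

Body weights are drawn uniform on [50, 100] kg, inside the protocol's
40–120 kg eligibility window without modelling BMI. Placebo subjects
contribute T-cell streams only, simulated as (individual) baseline plus
residual noise — no placebo drift term, since none was reported. An optional
mode (`arm_baseline_imbalance`) rescales each arm's baseline T-cell counts
to the study's observed between-arm imbalance; it is off by default so all
arms share one generative baseline.

Datasets are NONMEM-style long CSVs (ID, ARM, TIME, EVID, CMT, AMT, DOSE,
WT, DV, MDV, BLQ); the reader validates stream labels and reports the first
offending line. A truth sidecar (JSON) records every subject's generative
parameters for recovery testing. The same seed reproduces the same bytes.

### pcVPC

Prediction correction multiplies each observation by
median(PRED in bin)/PRED, with PRED computed at the typical parameters
(weight-dependent for the PK-type streams). Bins are nominal sampling days —
the schedule is sparse and fixed, so nominal-time bins are exact. Observed
10/50/90th percentiles are overlaid on percentile bands across replicate
simulations; the band quantiles default to 10–90% and the self-consistency
test uses the conventional 95% band, because an 80% band has exactly 80%
expected per-bin coverage and the bins of one trial are correlated through
its subjects, making the narrower band uninformative as a pass/fail check.

## Estimation

**Population dose-response fit** (`fit_dr_population`): a Laplace-type
approximate marginal likelihood with log-normal random effects on R₀ and
E_max and proportional residual error. Per subject, the random-effect mode
is found by vectorized Gauss–Newton with analytic derivatives (backtracking
line search, Ω-preconditioned steepest-descent fallback, always cold-started
so the objective is a deterministic function of the structural parameters);
the marginal contribution uses the Gauss–Newton information,
log det(I + Ω·JᵀJ), the stable form of log|Ω| + log|H|. Structural
parameters are optimized on transformed scales (log; logit for E_max) with
bounds, by multi-start L-BFGS-B (3 jittered starts, finite-difference
gradients) followed by a Powell polish; convergence tolerance 1e-10 on the
objective. SD-scale floors of 1e-4 on σ and ω keep the objective finite on
noise-free data (where both collapse to the floor and the structural
parameters are recovered to ≤0.1%). Exact FOCE-I replication of the original
software is out of scope; parameter recovery at the study's design is the
operative standard: across 20 seeded trials the median E_max(T_EM) lands
within a few percent of the generative 0.715 and the median ED₅₀ near 0.353
(individual-trial ED₅₀ estimates scatter widely — its published RSE was
~64%). Starting values are data-derived (day-1 mean for R₀, terminal
suppression in the highest-dose arm for E_max, a quarter of the median
positive dose for ED₅₀, two-week turnover half-life), never the generative
truth.

**Per-subject TMDD fit** (`fit_subject_tmdd`): penalized least squares on
log residuals for the PK and soluble-receptor streams (plus optional
additive Free-RO residuals), with log-normal shrinkage toward the typical
values weighted by the published ω² for the four parameters carrying IIV
(CL_A, V_c, k_a, BL_SR); everything else stays at typicals. Population
TMDD estimation (all subjects jointly, full Ω) is deliberately not
implemented — the published Table II values serve as generative truth.
Subjects with fewer than 4 quantifiable PK observations are refused.

**Bootstrap** (`bootstrap_dr`): subjects are resampled with replacement
within each arm (stratification preserves the dose design; the source does
not state its scheme), and each replicate is refit from the base estimates
with a single start. T_EM and T_reg models are fit independently by default
(the source evaluated independent and combined variants); refitting both on
the same resample yields joint bands for the ratio. Non-converging
replicates are dropped and counted. Bands are 5th/95th percentiles of the
steady-state curves and their ratio across replicates.

## Problem sizes used by the shipped analyses

The numbered drivers and the acceptance script use desk-scale sizes chosen
to keep a full run in minutes: 20 seeded trials for recovery, 60 bootstrap
replicates for the shipped bands table (the script default is 100; the
study used 1000), 40–50 VPC replicates, and reduced replicate counts in the
estimator-consistency and coverage tests. All are parameters, not limits of
the implementation.

## Known limitations

- Dose, not exposure, drives the dose-response models (as in the source);
  no mechanistic coupling from the TMDD model to the T-cell turnover.
- No covariates, no immunogenicity effects on PK, no dropout, no lymphatic
  uptake modelling, no IV route.
- The unstated antibody MW and reference weight make absolute occupancy
  predictions at a given mg/kg dose assumption-dependent (see the 3 mg/kg
  discussion above).
- Synthetic trials inherit every modelling assumption above, so green tests
  demonstrate internal consistency and estimator behaviour under the assumed
  data-generating process — not the adequacy of these models for any real
  dataset.
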