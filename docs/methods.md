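# Methods

## Scope and design

`pbtkmix` is a generalized multi-chemical toxicokinetic engine: one
chemical-independent whole-body physiology, onto which structurally different
chemical-specific models are mapped and integrated *jointly*. The package
separates four concerns:

1. **Physiology** (`physiology`) — tissue volumes and blood flows with a hard
   conservation invariant: perfused flows sum to the cardiac output to 1e-9
   relative. Tissues a chemical model does not resolve can be lumped into
   rapidly/slowly perfused groups whose flow is exactly the cardiac output
   minus the explicit flows, so lumping never breaks the budget.
2. **Kinetics** (`kinetics`) — assembly of the coupled mass balances into one
   state vector and a constant linear coefficient matrix plus compiled
   saturable terms, integrated by a stiff implicit solver.
3. **Chemical structure** (`chemical_models`) — builders that contain
   *structure only*; every numeric parameter lives in a packaged YAML file
   with a provenance string.
4. **Interactions** (`interactions`) — cross-chemical effects layered on top
   without touching mass balances (they modify rates, never ledgers).

## Units and state

All internal amounts are molar (μmol) and all times are hours. The molar
basis is load-bearing: a first-order metabolic edge A→B then conserves matter
exactly (1 μmol of A consumed forms 1 μmol of B), which is what makes the
formation-rate-equals-negative-loss convention of the Γ matrix mass
consistent. Mass-based dose units (μg/day, μg/kg/day, mg, ppm) are converted
at the boundary using each chemical's molar mass; mercury amounts are
expressed as Hg and arsenic amounts as As, the conventions their
dose/biomarker literatures use.

The state vector is a bijection onto named (chemical, compartment,
subcompartment) pools, followed by per-chemical ledger states (cumulative
administered; cumulative excreted by route; cumulative molar flux along every
metabolic edge) and interaction effect states. Ledgers are integrated *with*
the system, so the conservation audit

    administered + transformed-in + initial = in-body + excreted + transformed-away

is exact up to solver error; every simulation checks it at 1e-6 relative and
fails loudly otherwise.

## Tissue schemes

* *Perfusion-limited*: `dC/dt = (Q (C_in − C/P) + S)/V`, venous outlet at
  `C/P`.
* *Diffusion-limited*: extracellular and cellular spaces with permeation flux
  `H (C_E − C_C/P)`; outlet at `C_E`. The driving-force convention
  (equilibrium at `C_C = P·C_E`) is one of several used in the field; it is
  the one implemented, and the perfusion-limited model is recovered in the
  H→∞ limit with an effective partition `(V_E + P·V_C)/(V_E + V_C)` — a
  property the test suite checks (monotone convergence, <1% of peak at
  H = 100·Q).
* *Storage*: pools (bone shells, GI lumen, red cells, fetus) with no direct
  perfusion; they exchange only through explicit transport processes and are
  excluded from the cardiac-output sum.

Blood is a single well-mixed central pool (arterial = venous). Chemicals that
need blood sub-structure (lead's red-cell binding) add chemical-specific
storage pools. A chemical absent from a tissue's parameter map is transparent
to that tissue (outlet = inlet).

Gas exchange is continuous-ventilation equilibrium at the lung:
uptake `= Q_alv (C_air − C_blood/P_blood:air)` with `C_air = ppm/24.45`
μmol/L (ideal gas, 25 °C, 1 atm). The exhaled stream is a ledgered excretion
route, so inhalation scenarios audit exactly like oral ones.

## Metabolism

Per tissue, the net first-order rate-constant matrix Γ (diagonal = total loss
constant; off-diagonal (B,A) = −k for each tracked pathway A→B; untracked
products contribute only the diagonal) drives linear metabolism as `Γ·y`.
Saturable reactions use the mixture Michaelis–Menten form with competitive
inhibition in the denominator and an effective Vmax

    Vmax_eff = Vmax · Π 1/(1 + C_nc/K_nc) · Π (1 + f_ind) · Π max(0, 1 − E)

The noncompetitive and induction functional forms are this package's choice
(the generalized-kinetics literature states only that "similar" terms apply);
the clamp at zero keeps a strong interaction effect from producing a negative
velocity.

## Numerical choices

* Stiff integration with BDF, analytic Jacobian (the linear matrix plus
  closed-form saturable-term partials), rtol 1e-8, atol 1e-12 μmol.
* Dose boluses and intake-scaling switches are solver restart points; boluses
  are exact state jumps, never impulse approximations, so events are never
  stepped over and the administered ledger is exact.
* Negative-state guard: amounts in `[−(10·rtol·max|A| + 1e-9), 0)` are
  treated as solver noise and clipped to zero; anything more negative raises.
  The floor is relative because chronic-exposure runs hold 1e4–1e6 μmol and a
  fixed 1e-9 μmol floor would misclassify ordinary integrator noise as a
  modelling bug.
* The report grid is decoupled from solver steps; reported times are the
  requested grid plus event boundaries.
* Time-dependent volumes (the growing fetal pool) are handled inside the
  derivative, not by re-assembly; everything else is a constant matrix.

## Chemical models and parameter provenance

The builders reproduce the *structures* of the standard single-chemical
models: the cadmium first-order biokinetic network (blood/liver/kidney/other,
sex-dependent GI absorption, slow renal elimination), the six-arsenical
methylation/reduction network (no demethylation; the two AS3MT methylation
steps noncompetitively inhibited by liver MMAIII and AsIII respectively;
urinary excretion the only elimination), the lead bone model (red-cell
binding, trabecular pool, mature cortical bone as eight equal-thickness
concentric cylindrical shells exchanging by radial diffusion with blood
contact at the innermost shell), chromium as fast blood reduction of Cr(VI)
to Cr(III) on the lead skeleton, methylmercury with brain diffusion
limitation, urine/hair/feces(/milk) excretion, distributed demethylation and
an optional fetal subsystem, and benzene/toluene inhalation PBTK with
mutually competitively inhibited hepatic oxidation.

The original parameter compilations are not redistributable, so the packaged
YAML values are representative defaults of the cited model families,
calibrated against published *behavioural* anchors rather than transcribed
tables: human urinary arsenic speciation (~25% inorganic / ~18% MMA / ~57%
DMA at low dose), a methylmercury whole-body half-life of ~60 days with
fecal excretion dominant, cadmium kidney burden still rising after 30 years
of constant intake, Cr(VI) undetectable in blood within hours, and — the one
numeric anchor — ~95% of the chronic adult lead body burden in bone, which
fixes the bone uptake clearances, the bone:blood partition and the shell
conductance scale jointly. Every parameter carries a provenance string naming
its packaged file and source note, and a scenario's full provenance can be
dumped via `simio.provenance_report`.

Cortical-shell geometry: equal-thickness annuli of a cylinder with inner
radius half the outer; shell volumes follow `r_i² − r_{i-1}²` and interface
conductances scale with interface radius over shell thickness from a single
conductance parameter. Uniform shell concentrations are a null state of the
resulting discrete radial operator.

## The mixture case study

A 30-year-old adult: 15/40/70/100 μg/day of cadmium, methylmercury, lead and
inorganic arsenic (dosed as AsIII) plus 20 ppm toluene and 10 ppm benzene for
500 days, then all metal intakes ×1.4 with the organics held constant.
Cadmium is initialised from a birth-to-age-30 pre-run at 0.2 μg/kg/day.
Because the true magnitudes of metal→metabolism interactions are unknown, the
modulation weights are deliberately synthetic: an equal-contribution rule
gives each metal group (the six arsenicals count as one group) the same share
of a chosen total baseline effect (default 0.25), and variants sweep a common
multiplier. The lag time constant defaults to 24 h, realised as a first-order
filter state rather than a delay term. Variant outputs are therefore
qualitative by construction — the base case is invariant to the metal step,
any positive-weight variant shows benzene rising after day 500 — and no
quantitative interaction claim should be read from them.

## What the synthetic fixtures do and do not establish

`fixtures.generate_linear_fixture` draws random stable compartmental (Metzler,
column-dominant) systems with constant inputs and solves them in closed form
via the matrix exponential; the same system is then expressed through the
public model surface and integrated by the engine. Agreement (rtol 1e-6 over
20 seeded fixtures) establishes that assembly, transport wiring, infusion
handling and stiff integration are correct for *linear* dynamics of arbitrary
topology. It does not validate saturable kinetics (covered by closed-form
rate-law identities and directional tests), nor any parameter value, nor
agreement with human biomarker data — observational evaluation data live in
figures of the source literature and are out of scope here.

## Known limitations

* No portal (gut→liver first-pass) chaining: absorbed oral dose enters blood
  or liver directly per model configuration.
* The continuous-ventilation lung has no dead-space or breath-by-breath
  resolution; fine for the multi-day scenarios targeted.
* Virtual-individual sampling perturbs volumes, flows and cardiac output
  lognormally and renormalises flows; it does not model covariance between
  organ sizes beyond the common body-mass scaling.
* Childhood growth is reduced to optional piecewise body-mass/bone-turnover
  hooks; a full growth model is out of scope.
* Parameter values are representative, not transcriptions; quantitative
  per-chemical predictions should be re-parameterised against the user's
  preferred compilation (the YAML override mechanism exists for exactly
  this).
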