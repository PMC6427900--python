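# Methods

`angiopd` implements a spherically symmetric free-boundary PDE model of a
vascularized tumor under combination therapy with an anti-VEGF antibody (B)
and an anti-PD-1 checkpoint inhibitor (A), together with the machinery needed
to ask a scheduling question: given fixed per-drug dose budgets, is it better
to give the two drugs simultaneously or sequentially?

## Model

Fifteen fields live on the ball 0 ≤ r ≤ R(t): six cell densities (dendritic
cells D, Th1 cells T1, CD8+ T cells T8, Tregs Tr, endothelial cells E, cancer
cells C), five molecular concentrations (IL-12, IL-2, TGF-β, oxygen W, VEGF
G), the PD-1 loads carried by the T-cell compartments (P1 on Th1+Treg, P8 on
CD8), and the two drugs. All units are g/cm³ and days.

The structural assumption is incompressibility: the six cell densities sum to
a constant θ = 0.4064 g/cm³ everywhere and always. Net local cell production
S(r) therefore drives a radial bulk velocity through θ ∇·u = S, and the tumor
boundary moves with the cells, dR/dt = u(R). Cells are advected by u (plus a
small dispersion); molecules only diffuse, with coefficients 10⁴–10⁶-fold
larger.

Kinetics follow Michaelis–Menten saturation and competitive-inhibition
factors 1/(1 + X/K):

* DCs are activated by tumor (via the necrosis → HMGB-1 route, reduced to a
  direct C-dependence because both intermediates are fast), inhibited by VEGF.
* T1/T8 are activated by IL-12 (inhibited by Tregs, VEGF, and the PD-1–PD-L1
  complex) and proliferate under IL-2 (inhibited by the complex).
* Tregs are induced by TGF-β and VEGF; endothelial cells proliferate above a
  VEGF threshold, are chemoattracted up VEGF gradients, and source oxygen.
* Cancer cells grow at an oxygen-limited logistic rate and are killed by T
  cells (η₁ T1 + η₈ T8).
* VEGF production by tumor cells is bimodal in oxygen: rising below the
  hypoxia threshold W*, falling above it, constant beyond the normal level.

The checkpoint is algebraic: PD-L1 is slaved to the cell fields,
L = ρ_L(T1 + T8 + ε_T Tr + ε_C C), the complex is in fast equilibrium,
and T-cell activation carries the factor 1/(1 + P·L/K'_TQ) with
P = P1 + P8 and K'_TQ = ½ K_P K_L. The PD-1 loads P1, P8 are transported
fields whose sources are the exact algebraic images of the T-cell equations
(for P8 including the VEGF-dependence (1 + ε_G G) and its cross-terms in
u·∇G, ∇²G and ∇T8·∇G), minus depletion by anti-PD-1, μ_PA P A, modulated by
the anti-VEGF perfusion factor: 1/(1 + B/K_PB) when anti-VEGF restricts
perfusion, 1 + B/(K_B + B) when it enhances it.

Boundary conditions: Robin influx for T1/T8 (IL-12-gated), Tregs
(TGF-β-gated), endothelial cells (VEGF-gated), and oxygen (relaxing to the
blood level); no-flux for everything else; symmetry at r = 0.

### The two "normal oxygen" constants

The sources use two distinct constants that the original presentation of this
model family denotes with the same symbol: the rate-law threshold
`W_0 = 4.65e-4` (where the cancer growth law saturates and the VEGF law
plateaus) and the blood oxygen level `W_blood = 1.69e-4` that the boundary
condition relaxes W towards. Only this split makes the parameter-derivation
arithmetic (η₈ = 60.375 requires W̄/W_0 = 1.69/4.65) consistent with the
half-saturation closure (steady W = K_W = 1.69e-4). Using 4.65e-4 at the
boundary floods a 0.01 cm tumor with oxygen within hours, ignites the full
growth rate, and the induced dilution collapses the endothelial and T-cell
compartments — qualitatively wrong behavior. Both constants are separate
`ParameterSet` fields.

## Parameter derivations

All constants live in `params.ParameterSet` (mouse defaults; a clinical
variant changes λ_DC, λ_E, λ_CW and K_PB). `derive_secondary_parameters`
re-runs every steady-state closure — built on the half-saturation rule
K_X = X₀ — and reports each derived value against the tabulated one as a
`ClosureRecord` (exportable as a CSV audit). Tabulated values stay canonical
for simulation because three rates (λ_DC, λ_E, λ_CW) were deliberately
adjusted upward relative to their raw balances to compensate for source
depletion; the audit shows both numbers. Two bookkeeping notes: the
anti-VEGF/VEGF depletion pair follows the derivation (μ_BG = 9 d_B/K_G =
2.19e7 for the antibody, μ_GB = 6 μ_BG for VEGF); and the published CD8 PD-1
initial value is used in its algebraically consistent form
ρ_P T8 (1 + ε_G G) = 5.43e-10.

## Numerics

Space: a moving radial mesh whose nodes ride on u (arbitrary
Lagrangian–Eulerian). Advected fields then keep only the compression term
−(∇·u)X; diffusing fields get a mesh-sweep correction +u ∂X/∂r. Diffusion is
discretized in conservative finite-volume form (face fluxes r² δ ∂X/∂r over
node control volumes), which conserves a no-flux field's discrete mass to
round-off and is second-order on smooth meshes. The velocity is the exact
moment integral u = (θr²)⁻¹ ∫ s²S ds of the piecewise-linear reaction sum
(plus the analytically integrated chemotaxis flux), and the divergence
entering the cell equations is taken from its defining identity ∇·u = S/θ, so
the constant-density state is an exact fixed point of the discrete interior
scheme; the residual drift (boundary rows) is tracked and stays ~1e-5.

Time: backward Euler with Picard closure. Each sweep re-evaluates sources,
velocity, and mesh from the provisional state and solves one tridiagonal
system per field; each field's own linear sinks (death, degradation, drug
depletion) sit on the diagonal, so stiff decay (TGF-β at 499/day) does not
restrict the step. Three safeguards matter in drug-induced regression, where
the checkpoint factor couples P to the T-cell sources with |∂src/∂P| ≫ 1/τ:
negative lagged sources are folded into the diagonal (Patankar linearization,
preserving positivity), the PD-1 sources carry a diagonal Newton term (both
leave the converged fixed point unchanged), and the update is adaptively
under-relaxed when the iteration stalls. Convergence is judged per field
against fixed characteristic scales (θ for cells, K_X for molecules,
γ/d for drugs) so a fully depleted field cannot stall the iteration at
round-off level; tolerance 1e-8, at most 200 sweeps, with step halving and
conservative remeshing (uniform re-interpolation when the interval ratio
exceeds 10) as fallbacks. Near the regression separatrix the coupled
T-cell/PD-1 fixed-point map can retain a mode with gain close to one at any
τ; an exhausted iteration whose residual is nonetheless below 1e-5 (well
under the truncation level) is accepted and counted in the run diagnostics.
Fields are solved in physical units: the per-field systems are linear, so
this is algebraically identical to scaling each field by a constant, and the
per-field relative norms supply the scaling.

Default resolution is N = 64 nodes, τ = 0.05 day. The acceptance suite
verifies spatial order ≥ 2 and temporal order ≥ 1 against an analytic Neumann
eigenmode, agreement to 1e-3 with a stiff ODE integration of the well-mixed
reduction over 10 days, and that halving h and τ moves the headline endpoint
(time to 95% volume reduction) by < 2%.

## Experiments

Clinical schedules run in 9-week cycles with 3-week continuous windows —
S1: both drugs in weeks 1–3; S2: anti-PD-1 then anti-VEGF; S3: anti-VEGF then
anti-PD-1 — repeated until the endpoint T_crit (first time the volume falls
to 5% of its value at treatment start, linearly interpolated, reported in
weeks) or the horizon. Dosing indicators are evaluated at step midpoints and
switch times are snapped onto the time grid. Dosing starts at day 0 from the
standard initial state (R = 0.01 cm, uniform fields summing to θ), for mouse
and clinical runs alike: that is the one initial state the model defines, and
the untreated tumor has no steady radius to wait for (it settles into slow
exponential rim growth). `run_schedule_experiment(pretreat_days=...)` exposes
the alternative protocol in which the tumor grows untreated first. Runs whose
volume escapes 100-fold above the starting value are terminated early and
reported as not reaching the endpoint.

Mouse regimens dose continuously from day 0 (10- or 30-day courses) and are
read out at day 30; the per-cell CD8 PD-1 load is operationalized as
⟨P8⟩/(ρ_P ⟨T8⟩), which equals 1 + ε_G G for the algebraically consistent
state.

## Sensitivity analysis

Ten constants (λ_DC, λ_T8I12, λ_TrG, λ_E, λ_GW, η₈, K_DG, K'_TQ, K_TG, K_PB)
are sampled by Latin hypercube over [½×, 2×] their baselines (the checkpoint
constant through its implemented composite K'_TQ); each draw is scored by the
day-30 tumor volume of a mouse-calibration run. PRCC rank-transforms
parameters and outcome, partials out the other parameters by linear
regression on ranks, and correlates the residuals; p-values use the
t-transform with n − k − 2 degrees of freedom, ties broken by average ranks.
The pipeline default runs untreated (and then K_PB is a structural null: it
only enters the anti-PD-1 depletion term); the acceptance configuration doses
the combination so every parameter has a live causal channel. Sensitivity
runs use a scaled-down resolution (N = 24, τ = 0.2) whose PRCC signs match
the finer default.

A structural point the sensitivity results expose: each inhibition
half-saturation enters as 1/(1 + X/K), so a *larger* K weakens the
inhibition, strengthens the immune compartment and shrinks the tumor — K'_TQ
and K_TG therefore carry negative PRCC in this implementation, and K_DG is
near-null because its factor only spans 0.83–0.94 over the sampled range.
Verbal summaries that treat these K's as "inhibition strengths" predict the
opposite signs.

## Synthetic scenarios

`make_fixture` builds self-consistent scaled-down scenarios (`fast_mouse`:
N = 50, 10-day horizon; `fast_human`: a short S2-like course; `stress`:
±10% parameter jitter under a seed) for tests and CI. They emulate the model
under the canonical parameter tables — not any external data — so passing
tests demonstrate internal consistency of the implementation, reproduction of
the derivable constants, and the solver's convergence properties; they cannot
validate the biology against measurements.

## Known limitations

* The scheduling endpoints are sensitive to the (unpublished) operating point
  of the clinical runs: from the day-0 state, S2 reaches the 95% endpoint in
  6.4 weeks at the first published dose pair, while S1/S3 do not reach it
  within 60 weeks; a 7-day pre-growth protocol reproduces the published S2
  endpoints to a few percent but leaves S1/S3 unreached. At these doses the
  anti-PD-1 depletion rate (μ_PA γ_A/d_A ≈ 0.015/day) cannot strip a PD-1
  pool that the checkpoint feedback replenishes between cycles, so an
  established tumor never tips in this realization.
* Radial symmetry only; no pharmacokinetics beyond uniform source terms; no
  toxicity; the necrosis/HMGB-1 intermediates are analytically eliminated.
* Immune densities can transiently exceed physiological ranges during strong
  regression (the incompressibility constraint funnels displaced volume into
  the immune compartments, and T-cell proliferation saturates only through
  IL-2).
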