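# Methods

## The hybrid growth/division model

Each registered model is a deterministic ODE system for intensive
cell-cycle activities, coupled to exponentially growing cell volume
(`dV/dt = μV`, μ in 1/min; volume is never altered by perturbation
protocols unless μ itself is the target). Volume feeds back through
volume-scaled synthesis terms — the Cln3-like size sensors — and the
dynamics set the timing of two events:

* **budding**: a G1-cyclin-like observable crosses its threshold upward;
  all subsequent growth is bookkept to the bud;
* **division**: a mitotic observable crosses its threshold downward; the
  daughter receives the bud volume (`V_dau = V_div − V_bud`) and inherits
  the intensive state unchanged.

Only the daughter lineage is followed; mother branches are discarded.
Thresholds and Hill exponents are structural constants of each model, not
parameters. The daughter fraction `f` and the period `T_div` are emergent:
nothing in the models fixes them directly, and at every steady cycle we
find `f < 0.5` with `T_div` above the mass doubling time, as it must be for
asymmetric division.

### The three bundled models

The registry holds three in-package renditions of the classic modelling
tiers, written for this package (their equations are given in the module
docstrings):

* `pfeuty` — 2 variables, 8 parameters. A relaxation oscillator: the G1/S
  activator X is self-activating (the Start positive feedback) and driven
  by `s_x2·V`; the mitotic activity Y is switched on by X, represses X
  synthesis and accelerates X turnover. Rate constants scale uniformly
  with μ, so the cycle keeps its shape in units of the doubling time.
* `chen` — 9 variables, 63 parameters. SBF/Cln2 Start switch, Clb5/Clb2
  cyclin waves antagonised by Sic1 and Cdh1, Mcm1 mitotic positive
  feedback, Cdc20→Cdc14 exit module. Transcription-factor and adaptor
  activities use saturating (Goldbeter–Koshland) interconversion; the
  M-phase program (Mcm1) represses SBF until exit completes, which is what
  keeps Start from re-firing in large pre-division mothers.
* `barik` — 61 species, 70 parameters, pure mass-action. mRNAs and
  proteins are explicit; switches arise from multisite phosphorylation
  (Sic1 with 8 phospho-states, free and bound to either cyclin class;
  Net1 with 5, free and in the RENT complex with Cdc14) and stoichiometric
  sequestration (Whi5:SBF, Sic1:cyclin). Cdc14 is a conserved moiety,
  only exchanged between the free pool and RENT. This model carries the
  named glucose-channel parameters `k_s_n3`, `k_s_mbS`, `k_d_t1`, `k_d_nt`.

Basal growth rate is ln 2/100 min⁻¹ (100-minute doubling) in all three.
Volume units are calibrated so steady daughters are ≈36 fL — the scale of
the chemostat data behind the empirical glucose response — via the
volume-scaled synthesis rates; this is an exact unit change that leaves
all times, fractions and concentrations untouched.

At basal parameters the steady cycles are: minimal model
`T_div = 161.0`, `T_G1 = 103.7`, `f = 0.328`; mid-size `139.3 / 70.1 /
0.381`; detailed `160.6 / 103.2 / 0.328` (minutes).

## Numerical choices

Integration uses LSODA with `rtol = 1e−8`, `atol = 1e−10`; halving the
tolerances moves the steady `T_div` by well under 1e−6 relative. Each
generation is integrated in two stages (birth→budding, budding→division)
with terminal, direction-filtered events, split at every protocol
parameter switch; the first minute of each stage is integrated event-free
to guard against re-triggering on numerical chatter. A generation longer
than five doubling times counts as arrest ("oscillation lost").
Steady cycles are declared converged when `(T_div, V_div)` move less than
1e−8 relative between generations (default cap 200 generations); perturbed
models are converged by continuation from the basal cycle-start state.

Sensitivities use central differences in ln k with step δ = 0.01; each
half-step fully re-converges the steady cycle. Halving δ moves the
coefficients by < 0.5% (the difference is O(δ²)). Dynamic sensitivities
default to 6 generations on a 50-point perturbation-time grid per cycle;
Z and Z^phase are centred differences with one-sided ends. Phase shifts
sum period changes over 12 generations — the per-generation increments
decay geometrically, putting the truncation error far below the
finite-difference resolution. The nonmonotonicity tolerance is 1e−3 of a
curve family's maximum amplitude, so integrator ripple is never counted
as a sign change.

Sign convention: **Δφ > 0 means division is delayed**
(Δφ = Σᵢ (T_div,i − T_div,0)). A transiently enlarged daughter fraction
therefore produces a *negative* shift: the daughter is ahead of its growth
schedule, and the fraction-product formula reads
Δφ = −(1/μ) ln Π (f₀+Δfᵢ)/f₀. This identity is exact for any lineage that
returns to its original steady cycle, whatever the model — the package
tests it both on closed-form synthetic streams (to 1e−10) and against
direct ODE simulation (to better than 2%).

For 1:1 mode locking against a pulse train with period `T_f = T_0 −
detuning`, the locked pulse phase solves `Δφ(t*) = −detuning`; under the
delay-positive convention the stable branch of the circle map
`φ_{n+1} = φ_n − detuning − Δφ(φ_n)` is where `0 < Δφ′(t*) < 2`, and the
crossing with positive slope is returned. Δφ(t) is measured by direct
simulation of the finite pulse at each grid phase (60 phases by default),
because the pulse has finite duration; the step-based linear route
(Δφ ≈ (Δk/k)(S^phase(t₁) − S^phase(t₂))) is available as a cross-check.
The prediction neglects multi-cycle relaxation (it assumes the shift is
realised before the next pulse), which is the main source of the few-minute
discrepancy against forced simulation.

Nonmonotonicity of responses down generations is judged on the sequence
*including the pre-perturbation baseline* (0, S₁, …, S₆, C) by default: a
generation-1 overshoot that then reverses toward the limit is the
canonical transient of these models and would be invisible to a
generations-only sequence. The generations-only variant is available via
`include_baseline=False`; on the minimal model it scores 0.27 against 0.59
with the baseline.

The attainable cone is built from channel vectors
`sign · Σ_k (C_k^{T_G1}, C_k^{V_dau})`; membership is decided by
nonnegative least squares (residual below 1e−9 relative counts as an exact
witness), and weight families reaching a fixed endpoint are solved from
the two steady-state equations with chosen channels fixed. All-zero
channel vectors are dropped as degenerate generators with a warning.

## The synthetic lineage generator

`cyclesens.fixtures.generate_lineage` emits birth/budding/division event
streams in closed form: exponential growth, exact per-generation
identities, and a per-generation donated-fraction schedule `f₀ + Δfᵢ`
realised through sizer mechanics (budding volume fixed, division moved).
Its cumulative division-time shift equals the fraction-product formula
*exactly*, which makes it the ground truth for the phase-shift estimators.
Optional noise is a multiplicative log-normal jitter on each generation's
*recorded* volumes (one draw per generation, timings exact, nothing
propagated), i.e. measurement noise for estimator-recovery tests. What the
generator does not emulate: cell-to-cell variability, mother lineages,
correlated timing noise — so passing tests on it validate bookkeeping and
estimators, not biological stochasticity.

## Problem sizes used in the shipped runs

The test suite and the reproduction script run, by design, at: 12-point
perturbation grids for convergence checks, the default 50-point grid for
the nonmonotonicity summary (minimal model, all 8 parameters), 30
prediction phases and 60 forced cycles for mode locking, and 50 noisy
generations for synthetic recovery. The mid-size model's nonmonotonicity
sweep (63 parameters × 50 phases × 2 signs × 6 generations of a stiff
9-ODE system) is not part of the default runs; the machinery accepts it
unchanged for anyone willing to wait.

## Known limitations

* The three models are this package's own renditions of the classic
  budding-yeast modelling tiers, matched to the published variable and
  parameter counts and qualitative behaviours — not parameter-identical
  ports. Quantities that depend on the original parameterisations differ;
  two measured examples are documented honestly by failing tests:
  the transient-nonmonotonicity fraction reaches 0.59 rather than ≥0.8
  (our renditions have near-deadbeat size homeostasis, so half the
  parameters' step responses settle monotonically), and the empirical
  glucose direction (0.27 fL of daughter volume per minute of G1) falls
  just outside the detailed model's attainable cone, whose
  daughter-enlarging boundary — the Net1 channel, qualitatively correct as
  the only channel that can enlarge daughters — provides 0.14 fL/min.
* Mode locking is demonstrated with a pulse the minimal model responds to
  (+50% of `d_y` for 20 min); very short, weak pulses of the
  Cln3-analogue are erased by its Start sizer and predict (and produce)
  no locking.
* Finite differences on the hybrid system are the contract; there is no
  adjoint/variational sensitivity path, no bifurcation analysis, and no
  stochastic simulation.
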