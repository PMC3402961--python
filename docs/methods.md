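# Methods

## Model form and assumptions

A kinetic metabolic model is the ODE system `dX/dt = A·R(X,P) + B(X,P)`
over the dynamic metabolite concentrations `X` (mM, time in seconds).
Rate laws are declarative arithmetic expressions over metabolite ids and
named parameters (safe-parsed, compiled once); external species
(boundary substrates, co-metabolites) are held at fixed concentrations and
are not ODE states. The `B` term carries per-metabolite expressions for
transport/dilution not represented as reactions; the bundled models leave
it empty and represent uptake and drains as (lumped) reactions instead.
Deterministic, well-mixed kinetics is assumed throughout — no stochastic
effects, delays, or events.

An in-silico knockout zeroes the reaction's declared maximal-rate
parameter(s) (`vmax_params`). This keeps the state dimension fixed, so
wild-type and knockout trajectories live on the same grid and can be
compared column-wise. Knockouts refuse lumped transport/biosynthesis
steps and reactions whose maximal-rate parameter is shared with another
rate law (a shared parameter would silently delete two reactions).

## Simulation

Integration uses the BDF (Gear-family) implicit multistep method
(`scipy.integrate.solve_ivp`), rtol 1e-8 / atol 1e-10, sampled on a
uniform grid anchored at t = 0 (default horizon 2000 s, 400 intervals —
roughly forty times the slowest relaxation time of the bundled model, so
converging systems are flat well before the horizon). Concentrations are
clipped to zero below −1e-6 mM before rate evaluation (MM-type rate laws
make exact zero absorbing, so trajectories cannot escape far below zero).
A state crossing the validity ceiling of 1e6 mM terminates the run as
`blew_up` with the crossing time; solver breakdown (e.g. the step-size
collapse at a finite-time singularity) is reported as `solver_failed`,
never raised. Downstream consumers treat both as divergence.

## State fluctuation

For entity `k` (metabolite concentration, or reaction flux in the
enzyme-centric view) the amplitude is

    f_k = ||X^e_k − X^0_k||_2 / ||X^0_k||_2

with the L2 norms evaluated as integral (trapezoid) norms on the shared
time grid — this makes `f_k` invariant under grid refinement, whereas raw
sample norms drift by O(grid fraction of the transient). A zero-norm
wild-type column (metabolite absent in the wild type) falls back to the
unnormalized difference norm and is flagged instead of dividing by zero.
When either trajectory ends early, amplitudes are computed on the common
valid window and the profile is flagged `truncated`. Note that when both
systems converge, `f_k` tends to `|Δ∞_k| / |X∞_k|` as the horizon grows:
entities that return to their baseline see their amplitude diluted by the
converged tail — amplitudes are therefore always reported with the horizon
that produced them.

Distances come from the intact (pre-knockout) topology: metabolites
participating in the deleted reaction (substrates, products and — by
default — inhibitors/activators, since effectors enter the rate laws the
same way) are at distance 1; metabolites sharing a reaction with a
distance-k metabolite are at k+1 (breadth-first on the bipartite graph).
The enzyme-centric view connects reaction A to B when a product of A is a
substrate of B; distances there ignore edge direction by default because
influence in an ODE propagates upstream too (both choices are toggleable).
Unreachable entities carry an explicit `None`, never a large sentinel, and
contribute nothing to the impact measure

    M_n(d, f) = Σ_k f_k / d_k^n ,  n ∈ {1, 2} by default.

The distance-discounting reading of `M_n` is the default; the
distance-amplifying alternative `Σ f_k · d_k^n` sits behind
`mode="weight"`. With the discounting reading `M_{n+1} ≤ M_n` always
(all d ≥ 1), which the tests assert.

## Dynamical stability

Equilibria are located by trust-region reflective least squares on
`rhs(x) = 0` (non-negativity bounds), seeded at the endpoint of a long
simulation plus 10 seeded log-uniform random restarts inside the
ordinary-range box. An equilibrium counts as found when the residual norm
is below 1e-6 mM/s and the state is finite and below the ceiling.
"No equilibrium" requires *both* that every start fails *and* that the
long trajectory is divergent (blown up, or still drifting more than
1e-4 mM/s at the horizon); solver failure with a settled bounded
trajectory yields `indeterminate` instead.

Stability follows the Jacobian spectrum at the equilibrium (central finite
differences, per-coordinate relative step 1e-6): all real parts negative →
asymptotically stable; any positive → unstable; a conjugate pair within
the relative band |Re λ| < 1e-6·max(1, |λ|) of the imaginary axis →
center candidate (likely limit-cycle bifurcation). The spectrum maps to
the reduced normal form (planar center block + N_s contracting + N_u
expanding coordinates); σ defaults to +1, and β is treated as a
qualitative sign parameter estimated from the radial drift of probe
trajectories rather than computed by center-manifold reduction — the
reduced system is used for qualitative orbit description only. Unstable
limit cycles are probed directly: trajectories launched at chosen radii on
a 2-D plane around the equilibrium are classified converged / cycling /
diverged, and the cycle radius is bisected on the sign of a short-horizon
radial drift (the probe horizon is kept short because an unstable cycle
amplifies integration error exponentially).

Knockout categories: with `r = ‖X_d − X_eq‖ / ‖X_eq‖`, a found
equilibrium is `near_stable` when stable and r < 0.5; `extreme_deviation`
when it leaves the ordinary-range box (componentwise 100× the reference)
or r > 1; `relocated_with_stability_change` when its stability differs
from the (stable) reference; `relocated_stable` otherwise. With several
distinct equilibria the most severe category is reported. The 0.5/1.0/100×
cuts are this package's operational definitions of "near", "extreme" and
"ordinary range": in a scaled-down model, legitimate flux compensation
after an uncritical knockout already moves pathway pools severalfold, so a
much tighter near-cut would misread compensation as qualitative change.
They were fixed from design-time flux-balance analysis of the bundled
model and are exposed in `StabilityThresholds`.

## MOMA and flux-sums

The adjustment problem — minimize `‖x − X0‖²` over steady states of the
knocked-out system — is solved as a box-bounded global minimization of
`‖x − X0‖² + λ·‖rhs(x)‖²` by differential evolution (≈100 individuals,
200 generations, seeded; the naive post-knockout simulation endpoint and
X0 itself are injected into the initial population, so the result is
never worse than either — asserted as the elitism invariant). The
stationarity weight λ = 1e6 (mM⁻² s²-scaled) is set high enough that no
distance advantage available inside the box can outweigh a visible
stationarity violation: the steady-state condition is a hard constraint
of the problem and the penalty is only a numerical device. For residual
systems with *no* steady state the optimum lands on the bounded
near-stationary states (asymptotic jam states) the dynamics actually
approach, which is exactly the regime the flux-sum validation should
evaluate. The decision box is the validity-scale box (1e4× the reference
state componentwise), not the 100× ordinary-range box, because the
adjusted state of a catastrophic knockout lies outside the ordinary range
by definition. Identical seed and configuration give bit-identical
results.

Flux-sums count state-dependent production: reaction i contributes to
`Φ_k` at state x when its signed instantaneous production `A_ki·R_i(x)` is
positive. The flux-sum table reports Φ before (reference equilibrium) and
after (MOMA state) a knockout, reduction fractions, and flags compensating
increases. The essentiality bound used in validation: a critical deletion
reduces every annotated-essential metabolite's flux-sum by more than 50 %,
an uncritical one none.

## Criticality verdicts

`critical` = qualitative stability change (`no_equilibrium`,
`extreme_deviation`, `relocated_with_stability_change`) **and** M(1) at or
above the impact threshold; `uncritical` = `near_stable` **and** M(1)
below it; anything else `indeterminate`. The threshold self-calibrates per
sweep: knockouts whose residual system keeps a nearby stable equilibrium
are the sweep's own reference for small impact, and the cut sits a
factor-two margin above their largest M(1). This supervised rule was
chosen over unsupervised cuts (median, largest-gap) because the critical
class can be the majority, which silently breaks distribution-based
splits. Without any near-stable knockout (a linear chain, say) an
absolute default of 10 applies — M(1) sums relative trajectory deviations,
so order-1 values mean the system barely moved while order-10⁺ values mean
aggregate deviations of many baseline magnitudes. An explicit override is
available everywhere, and raising the threshold can never turn an
uncritical verdict critical (asserted).

## The bundled synthetic model

`make_central_carbon()` is a *synthetic*, scaled-down central-carbon-style
network — the topology of E. coli glycolysis + pentose phosphate pathway
(18 dynamic metabolites, 19 enzymes, 8 lumped transport/biosynthesis
steps), with designed irreversible Michaelis–Menten/Hill kinetics, not
measured parameters. Design principles:

- The tabulated reference state is an **exact** flux-balanced equilibrium
  by construction (every Vmax is back-computed from a designed
  concentration/flux table), numerically asymptotically stable.
- Uptake is pep-coupled (phosphotransferase-style, bi-substrate MM with
  Kpep below the pep level, so uptake shuts down when lower glycolysis
  collapses) plus a small pep-independent leak (0.05 mM/s) that keeps
  blocked linear segments accumulating instead of freezing — deletions of
  backbone enzymes therefore leave genuinely rootless residual systems.
- PGI and the transketolase/transaldolase routes form alternative paths
  to fructose-6-phosphate, so PGI deletion is survivable with local flux
  compensation through the pentose phosphate pathway.
- Jam propagation uses two mechanisms of the real system: product
  inhibition along the oxidative PPP (6-phosphogluconate inhibits PGI and
  G6PDH; ribulose-5-phosphate inhibits PGDH; sedoheptulose-7-phosphate
  inhibits transketolase-a; erythrose-4-phosphate inhibits transaldolase —
  standing in for the reversibility of the real kinetics), and
  sugar-phosphate stress inhibition of uptake (accumulated
  pg6/xyl5p/rib5p/sed7p/e4p throttle the PTS, emulating the bacterial
  sugar-phosphate stress response). Inhibition constants (2–15 mM) sit
  well above baseline pools so they only engage in genuine jams; all Vmax
  values are rescaled exactly so the reference equilibrium is unchanged.
- The epimerase/isomerase split (1.5 : 1) exceeds transketolase's 1 : 1
  consumption, so deleting transketolase-b leaves excess
  xylulose-5-phosphate with no sink — the structural reason that knockout
  is catastrophic.
- Eight biosynthetic-precursor metabolites (g6p, f6p, gap, pg3, pep, pyr,
  e4p, rib5p) carry a synthetic "essential" annotation used by the
  flux-sum validation.

What the generator does **not** emulate: cofactor pools (ATP/NAD(P)H) and
their time profiles, reversible rate laws, allosteric regulation beyond
the inhibitions above, carbon stoichiometry across lumped steps (drains
remove mass), and measured parameter values. Passing tests therefore
demonstrate that the pipeline's machinery draws the intended conclusions
on a network *engineered to have* the reference behaviors (backbone
deletions catastrophic, PGI/PK/PGM-style deletions benign with
compensation); they do not validate predictions on any real organism's
measured kinetics.

Other fixtures: linear chains (closed-form steady state `v0/k_i`,
triangular Jacobian), a two-branch compensation motif (each branch alone
can carry the inflow), and the planar normal-form oscillator with
contracting/expanding extra dimensions (unstable cycle radius √(−β) for
σ=+1, β<0) — the oracle for the stability module. Fixture generation is
byte-stable under a fixed spec/seed.

## Problem sizes and tolerances used in the shipped checks

The test suite and `scripts/acceptance.py` run the bundled 18-dimensional
model at the defaults above; property suites use 20–100 random fixture
instances (chains up to n=4, probe horizons 2–30 s). GA runs use ~100
individuals × 200 generations; flux-sum validation repeats over three GA
seeds and requires all-seed agreement on the 50 % bound. These sizes are
the package's reference study conditions; everything is configurable.

## Known limitations

- Equilibrium nonexistence is established operationally (multi-start
  failure plus trajectory divergence), not analytically; systems whose
  residual drifts vanish asymptotically (jams growing like √t) may be
  reported as far-relocated equilibria rather than `no_equilibrium` —
  both count as qualitative changes, so verdicts are unaffected.
- β of the normal-form signature is qualitative (probe-based); no
  center-manifold coefficients are computed.
- Finite-time singularities surface as `solver_failed` (step-size
  collapse below the ceiling crossing); treated as divergence downstream.
- The MOMA search is heuristic global optimization: with multiple
  feasible equilibria it returns the best found, which the seeded
  multi-candidate initialization makes reproducible but not provably
  globally optimal.
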