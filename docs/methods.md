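# Methods

This note documents the models, estimators and numerical choices behind
`pumpsel`, and what the package's passing tests do and do not establish
about all-atom systems.

## The reduced binding-site model

The site is a single mobile cation inside a half-harmonic spherical wall
(default radius 3.5 Å, stiffness 20 kcal/mol/Å²), coordinated by N
flexible "arms" (default 4–8, anchors on a shell of radius 4 Å placed
octahedrally, or on a golden spiral for N > 6).  Each arm is a rigid rod
of length 2.2 Å pivoting about its fixed anchor on a tilted cone
(half-angle 55°, axis tilted 25° off the inward radial direction), so
its single torsion χ genuinely modulates the tip–ion distance.  An arm
carries a dipole (+q at 40 % of the arm, −q at the tip; q = 0.45 e,
carbonyl-like) and, if flagged acidic and deprotonated, an extra −1 e at
the tip.  The tip is the only Lennard-Jones site (ε = 0.12 kcal/mol,
R_min/2 = 1.70 Å, oxygen-like).

Energy terms: Coulomb with 332.0716 kcal·Å/(mol·e²) and no dielectric
screening; LJ in ε/r_min convention with geometric/arithmetic
combination and explicit pair-specific overrides (the representation
needed for pair-corrected ion–oxygen interactions); an intrinsic
multi-well torsion cosine series per arm (default 3-fold barrier of
1.5 kcal/mol plus a 1-fold term of 0.8 — multiple rotamers separated by
barriers of several k_BT, which is what makes boosting worthwhile);
the confinement wall; and the optional ion translational restraint
u_trans = ½[k_r(r−r0)²+k_θ(θ−θ0)²+k_ψ(ψ−ψ0)²] defined by distance,
angle and dihedral against three fixed anchor points (defaults
k_r = 10 kcal/mol/Å², k_θ = k_ψ = 200 kcal/mol/rad²; equilibrium values
taken from the relaxed ion position).  Angles are degrees externally,
radians internally; angular differences are wrapped to (−π, π] before
squaring.

Ion species differ **only** in nonbonded parameters (published
fixed-charge values: Na⁺ ε = 0.0469, R_min/2 = 1.41075 Å; K⁺
ε = 0.0870, R_min/2 = 1.76375 Å; both +1 e), so Na⁺↔K⁺ alchemy is a
pure LJ transformation.  A D→N-style mutation neutralises the
dissociable charge and adds +0.2 Å to the tip radius (bulkier but
neutral amide surrogate).  Protonation changes charges only; LJ terms
are bit-identical before/after, which the tests assert.

The bulk phase is a separate droplet: the ion plus 8 rigid solvent
dipoles (q = 0.60 e, 0.9 Å arm, water-oxygen-like LJ) inside a soft
spherical boundary of radius 5.5 Å — the minimal stand-in for an
ion-in-water sphere with an implicit outer boundary.

The spherical wall replaces an implicit-boundary treatment of the outer
region; its contract (finite sampling volume, fixed outer shell) is
preserved, its electrostatics are not.  With no dielectric screening,
absolute energies are vacuum-scale: toy ΔG legs are an order of
magnitude larger than condensed-phase values.  Every conclusion the
package draws is therefore about *differences and trends* (ΔΔG signs
and orderings, pKa shift directions), not absolute magnitudes.

## Sampling

Metropolis Monte Carlo replaces dynamics: every downstream estimator
consumes only equilibrium averages.  The move set mixes a Gaussian ion
displacement with single-torsion rotations (uniform in ±Δ), selected
uniformly; move sizes are tuned toward 30–50 % acceptance in eight
150-step rounds and then frozen before equilibration and production, so
identical (model, seed, settings) give bit-identical series.
Production chains record every `thin`-th step.  Umbrella sampling along
one torsion uses 72 windows at 5° spacing with a 100 kcal/mol/rad² bias
by default; each window's chain starts at its centre.  Time-based
budgets of the production-scale protocol map onto step counts here; the
shipped profiles are `tiny` (seconds, provenance re-runs), `fast`
(minutes, the default study conditions) and `paper_analog` (the
production window counts — 16 λ site / 11 bulk / 24+10 deprotonation —
with longer chains).

## Estimators

**Umbrella WHAM** bins the period (2° default), forms the biased
histograms and iterates the self-consistent equations in log space to a
max |Δf| of 1e−8 kcal/mol (cap 1e5), anchoring the PMF at its minimum.
Empty bins across the period raise an error (a window gap cannot be
bridged by reweighting).

**Multistate WHAM** (the histogram-free form, equivalent to iterated
Bennett) consumes a frames × states cross-energy matrix.  "Solved
self-consistently" is implemented as: L-BFGS on the convex mixture
objective, a Newton polish with the analytic Hessian
diag(Σ w) − WᵀW and f₀ pinned (plain fixed-point iteration contracts
arbitrarily slowly when states barely overlap), then self-consistent
sweeps that certify the fixed point — convergence is accepted at
|Δf| ≤ 1e−8 kcal/mol or stationarity of the objective (gradient
≤ 1e−9·N).  The result is deterministic given the matrix.

**Errors** follow the block convention: contiguous 10-block partition,
estimator per block, *sample standard deviation* (ddof = 1) across
blocks — not the SEM — so error bars compare like for like with the
reference tables.

**Overlap diagnostic**: worst-case effective sample size of
adjacent-state importance weights (a state's frames reweighted into its
neighbour); below 50 frames a RuntimeWarning is raised.  Self-ESS is
deliberately not used — a state's own frames always look fine.

## Alchemical legs

*Ion swap* uses the three-point scheme: sample the start ion, the
parameter-midpoint hybrid (all LJ parameters and pair overrides
linearly interpolated; charge unchanged), and the target ion;
cross-evaluate every frame under all three parameter sets; read the two
adjacent free-energy differences off the converged multistate WHAM and
sum them.  λ = 0/1 reproduce the pure species exactly (asserted to
machine precision), and the three-state result closes against a direct
two-state estimate within block errors.

*Restraint decoupling* couples u_trans as λ²·u_trans (quadratic by
default): with stiff angular constants the restraint free energy is
dominated by the region where the restraint first takes hold, and the
quadratic map concentrates windows there; cross-energies are exact
linear combinations of the two endpoint evaluations.  The scenario
runner computes the Na and K legs with **common random numbers** (same
window seeds), so per-leg sampling bias largely cancels in the Na−K
difference that enters ΔΔG.

*Deprotonation* grows the dissociable tip charge linearly in λ (charges
only, no topology change — the pKa cycle needs only the site-vs-bulk
difference, which this isolates).  The default bulk reference for the
pKa cycle is the same geometry with every other ligand uncharged: the
cycle then measures exactly the electrostatic effect of the charged
binding-site environment on the titratable group.  With vacuum
electrostatics the toy shift is numerically huge (≈ +130 pK units in
the default scenario); only its sign and monotonicity in the
neighbour charge are meaningful, and that is what the tests assert.

## Boosting and replica exchange

The boosting potential U_BP(χ) = Σₙ kₙ{1+cos[n(χ−χ0ₙ)]} is fitted to a
PMF by expanding each term as aₙcos(nχ)+bₙsin(nχ) — linear least
squares with a free additive constant (which absorbs the "+1" offsets
and the PMF anchor), hence convex and deterministic — and converting
back via kₙ = √(aₙ²+bₙ²), χ0ₙ = atan2(bₙ,aₙ)/n, making fitted kₙ ≥ 0 by
phase choice.  N is chosen in 3…6 by lowest RMS residual on the grid,
ties to the smaller N.  Packaged reference rows keep their printed
(sometimes negative) kₙ and are evaluated literally.  Applied with
strength s, the torsion feels intrinsic − s·U_BP; s = 1 on a matching
intrinsic potential flattens it to machine precision.

The replica grid couples n_λ λ-windows × n_b boost strengths, both
evenly spaced on [0, 1] (the simplest defensible choice where only the
endpoints are prescribed).  Exchanges are allowed between adjacent
boost levels within a λ window and between adjacent λ windows at zero
boost — n_λ(n_b−1) + (n_λ−1) edges; at production scale (16, 8) that is
128 replicas and 127 edges.  One sweep runs a short Metropolis segment
per replica and then attempts alternating halves of the edge list with
the standard swap criterion min(1, e^{−βΔ}),
Δ = [U_a(x_b)+U_b(x_a)] − [U_a(x_a)+U_b(x_b)].  Only zero-boost
replicas contribute frames to estimation; the boosted rows exist to
shuttle decorrelated rotamers down the ladder, and the tests check that
a boosted run and plain independent-window sampling agree on ΔG within
errors.

## Thermodynamic post-processing

F_t = r0² sinθ0 (2π k_BT)^{3/2} / (k_r k_θ k_ψ)^{1/2} is the Gaussian
rigid-rotor approximation of the u_trans configurational integral in
(r, θ, ψ); the quadrature oracle — not the formula — is the contract,
and agreement is asserted to ≤ 0.5 % over force constants spanning two
decades.  C° is fixed at 1 molecule/1661 Å³ (1 M).  Conversions use
k_B = 0.0019872041 kcal/mol/K and T = 303.15 K by default
(RT = 0.60242 kcal/mol), so ΔΔG = 3.7 kcal/mol ↔ K_D ratio ≈ 465; the
reference tables print ratios computed from unrounded ΔΔG values, so
comparisons carry a few percent of rounding slack.  ΔpKa uses the
printed constant 2.303 for ln 10.

## What the synthetic models do and do not show

The toy site reproduces the *mechanistic* structure of the production
calculation: flexible multi-rotamer coordination, protonation-dependent
field strength, size-based ion discrimination, restraint bookkeeping,
and every estimator on the path from trajectories to ΔΔG, K_D ratios
and pKa shifts.  Passing tests therefore validate the estimators
(against closed forms and independent oracles) and the qualitative
physics (deprotonation drives Na⁺ selectivity; charged environments
retain protons).  They do not validate force-field accuracy, dielectric
screening, explicit water structure, multi-ion occupancy, or the
magnitudes of condensed-phase free energies — the toy ΔG legs are
vacuum-scale by construction.

## Degenerate inputs and tie-breaks

Identical alchemical states converge to Δf = 0 exactly; zero restraint
force constants give ΔG_trans = 0; a boost of strength 0 returns the
model object unchanged; n_blocks equal to the frame count degenerates
to per-frame estimates; single-replica topologies have no edges; fit
ties prefer fewer cosine terms; the restraint geometry is undefined
(and raises) for an ion coincident with the first anchor point.

## Known limitations

Vacuum electrostatics (above); one torsion per ligand rather than full
side-chain rotamer trees; the droplet's eight dipoles underestimate
solvation shells; H-REMD exchange rates on the toy models are low at
production ladder spacing because the boost gaps are large relative to
the small system's fluctuations — the estimators never consume boosted
frames, so this costs efficiency, not correctness.
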