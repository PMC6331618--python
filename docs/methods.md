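# Methods

This note records the models, estimators and numerical choices implemented
in `cgwater`, the defaults and their rationale, and what the desk-scale
tests do and do not demonstrate.

## Units and constants

Internal units are nm, kJ/mol, u, e, ps, K; pressure is kJ/mol/nm³
(16.6054 bar). Observables convert at I/O boundaries to g/cm³
(density), mN/m (surface tension), 10⁻⁶/bar (compressibility) and mPa·s
(viscosity). The Coulomb prefactor is 138.935458 kJ·mol⁻¹·nm·e⁻²; water's
molar mass is 18.0153 g/mol.

## The CG model family

Seven structures (`1S`, `2S`, `3S`, `3S*`, `2SF`, `3SF`, `3SF*`) at
mappings M = 1–12. Total entity mass is M × 18.0153 u; in multi-site
structures the central site carries twice the mass of each outer site.
Charges are structural multiples of the parameter q, so neutrality holds
for any q. Exactly one site per entity carries the Lennard-Jones
interaction (the negative site in `2S`/`3S`; the chargeless central site in
`3S*`). Electrostatics are uniformly screened by ε_r = 2.5.

Interactions: `U_LJ = 4ε[(σ/r)¹² − (σ/r)⁶]`, screened Coulomb
`U_e = q_i q_j / (4π ε_r ε₀ r)`, harmonic bond `k_b (r − r0)²` and harmonic
angle `k_a (θ − θ0)²`. In periodic systems the LJ term is cut at 1.2 nm
with an energy shift, and electrostatics use a reaction field with
ε_RF → ∞ (shifted to zero at the cutoff); the summation method is a
package choice — a uniform screening constant is already assumed, and the
reaction field is cheap and consistent with it. Isolated (non-periodic)
configurations use untruncated LJ and bare screened Coulomb. Nonbonded
pairs within one entity are excluded, the standard convention for bonded
clusters. Site overlaps are either capped (pair distances clamped at
0.05 nm, giving large finite energies) or raised as errors, per a flag.

Geometry conventions: the bend angle θ is measured at the central site;
r0 is the central-to-outer distance in all multi-site structures; in the
flexible three-site models the two bonds stay rigidly constrained and only
the angle fluctuates, in `2SF` the bond itself is harmonic.

## Priors

Uniform boxes over all parameters plus the error scale σ_n:
σ ∈ [0.25, 0.80] nm, ε ∈ [0.1, 6.0] kJ/mol, q ∈ [0.1, 1.2] e,
r0 ∈ [0.05, 0.35] nm, θ0 ∈ [60°, 180°], k_b ∈ [10³, 10⁵] kJ/mol/nm²,
k_a ∈ [10, 10³] kJ/mol/rad², σ_n ∈ [0.01, 1]. These are package defaults —
wide enough to contain the physically plausible liquid-state region for
every mapping — and are overridable per model via config.

## The MD forward engine

Velocity-Verlet integration; rigid bonds and rigid triangles enforced by an
iterative Lagrange-multiplier solver (SHAKE on positions, RATTLE on
velocities; tolerance 10⁻¹⁰ relative on squared distances, max 100
iterations — holding distances far tighter than the 10⁻⁸ contract).
Constraint forces contribute to the virial through the accumulated
multipliers. NVT adds an Ornstein-Uhlenbeck velocity refresh (friction
2 ps⁻¹) after each Verlet step, re-projected onto the constraint manifold;
this is first-order splitting, whose temperature bias is O(dt²) — measured
≲0.5% for single-site fluids at 4 fs and ~3% for rigid dimers at the 8 fs
ceiling, so production-quality runs should stay below the ceiling. NPT adds
isotropic Monte-Carlo volume moves (ln V proposals, entity centers of mass
rescaled, acceptance with the (N+1) ln(V'/V) Jacobian term). Recommended
maximal timesteps: rigid 8 fs growing to 20 fs with the mapping,
flexible 2 fs (set by the stiffest harmonic terms); `run_md` rejects
timesteps far above the ceiling.

Estimators (equilibration fraction 0.2, 10-block standard errors):

* ρ = ⟨m_tot/V⟩ from the NPT volume series.
* κ = (⟨V²⟩ − ⟨V⟩²)/(k_B T ⟨V⟩).
* ε from total-dipole fluctuations,
  ε = 1 + 4π f ⟨ΔM²⟩ / (3 ε_r V k_B T), the conducting-boundary
  fluctuation formula with the interaction screening ε_r dividing the
  dipolar coupling — consistent with the screened reaction-field
  Hamiltonian, and exactly 1 when all charges vanish. ε is undefined for
  chargeless structures and omitted from their QoI vector.
* γ = (L_z/2)⟨P_zz − (P_xx + P_yy)/2⟩ on an elongated slab box.
* η by Green–Kubo: (V/k_B T)∫⟨P_αβ(0)P_αβ(t)⟩dt averaged over the three
  off-diagonal components, each integrated to the first zero crossing of
  the mean autocorrelation (the running integral has plateaued there;
  a never-decaying ACF is flagged). An Einstein-relation estimator on the
  same series serves as an independent cross-check.

One forward evaluation orchestrates NPT bulk → NVT bulk (at the NPT mean
density) → NVT slab, with all sub-seeds derived from the evaluation seed:
identical calls are bit-identical. Because the MD observables are
stochastic, likelihood evaluations use a fixed evaluation seed (common
random numbers), which makes the likelihood a well-defined deterministic
function of the parameters at the cost of freezing one noise realization —
an approximation that vanishes as run budgets grow.

Default desk-scale budgets (125 entities, thousands of steps) are far below
production fidelity (5 nm boxes, ~10 ns); trajectories and forward results
carry a fidelity flag saying so. Production-scale budgets are encoded in
the study pipeline behind an explicit `cluster` switch. MD-backed evidence
sweeps at desk scale are qualitative only; the quantitative acceptance
suite runs on the analytic surrogate.

## Evidence estimation

Transitional ensemble MCMC: particles start from the prior; the tempering
exponent β grows adaptively so the stage weights' coefficient of variation
stays at 1; each stage resamples and applies Metropolis sweeps with a
Gaussian proposal scaled (0.2²) from the weighted sample covariance. The
sum of stage log-mean-weights estimates ln p(d|M). Defaults: 1000
particles, 5 Metropolis sweeps per stage, 3 independent replicates whose
spread gives the reported standard error (floored at 0.01). These defaults
were calibrated against closed-form conjugate marginals and an
importance-sampling gold standard on surrogate posteriors; harder (higher
dimensional, strongly curved) posteriors benefit from 10 sweeps and larger
ensembles, which is what the acceptance checks use.

Decomposition: expected fit = posterior mean of the per-sample
log-likelihoods. The information gain KL(posterior‖prior) is estimated with
a nearest-neighbor (Kozachenko–Leonenko) entropy estimator on whitened
samples. A Gaussian kernel density with Scott's-rule bandwidth was tried
first and rejected: its entropy bias on exactly-Gaussian 6-dimensional
targets at feasible ensemble sizes (≈ −0.2 nats) already exceeds the
closure budget of 0.15 that the decomposition is held to. Duplicate
(unmoved) particles are dropped before the neighbor search; non-uniformly
weighted ensembles are resampled first.

MAP: the ensemble argmax of the unnormalized log-posterior (ties break to
the lowest sample index), optionally polished by Nelder-Mead inside the
prior bounds.

## Hierarchical layer

Conditionally on ψ = (location, scale per dimension), each condition's φ_i
follows independent per-dimension Gaussians truncated to the prior box.
Hyper-priors: locations uniform over the box; scales log-uniform between
width/200 and width. σ_n is treated per condition, tied only through its
own hyper-component. Sampling is two-stage: classical per-condition
posteriors under the flat base prior, then hyper-level transitional MCMC on

    p(d_i | ψ) = Z_i · E_{φ~p(φ|d_i)}[ p(φ|ψ) / p_base(φ) ]

evaluated by importance reweighting of the stage-1 ensembles. The
hierarchical evidence is Σ_i ln Z_i + ln Z_hyper. Per-condition posteriors
informed by all data reweight each ensemble by the hyper-posterior-averaged
prior ratio; the predictive (data-informed) prior for a new condition is
the finite mixture of truncated normals over hyper-posterior draws. The
functional form of the conditional prior is a package choice — a standard
two-level Gaussian construction; with a single condition and a point-mass
hyper-prior the machinery reduces to a classical posterior under p(φ|ψ*),
which the tests verify.

## Selection

p(M_i|d) is a max-subtracted softmax of log-evidence + log model prior
(equal priors by default), stable across log-evidence spans of ±10⁶.
Utility u = log10(speedup); 𝒰 = p(M_i|d)·u. Speedups are user-supplied
(a `CostTable` with a provenance note): wall-clock is hardware-dependent
and deliberately outside the package's claims. Rankings are computed only
within a fixed QoI set and annotate it — chargeless and charged models see
different data (no dielectric constant) and their evidences are not
comparable. Ties order lexicographically by label. The published
log-evidences of the six mapping-4 models ship as input constants for the
selection arithmetic; the package never asserts them as its own output.

## Synthetic data

The surrogate observable map is
`F_k(φ, T) = F0_k(T) · exp(c_k(T)·u + q_k·u²)` in scaled coordinates
u = (φ_c − φ0)/half-width, with φ0 the prior-box center, F0 the
experimental values (linearly interpolated in T) and fixed coefficient
tables shipped in the source (signs follow CG-fluid physics: bigger beads
→ lower density, deeper wells → higher γ and η, more charge → higher ε).
It is smooth, strictly positive, full-rank at φ0, exactly F0 at φ0, and
optionally carries multiplicative lognormal jitter to mimic MD noise.

Pseudo-experiments draw `d_i = F_i(1 + σ_n ξ)`: the generative noise scale
is proportional to the model observable (making the scale proportional to
the datum itself would be self-referential at generation time), while the
likelihood keeps its diag(d²) covariance exactly. Benchmark suites emit
datasets shaped like the experimental table (same labels, units and
temperatures), with ground truth recorded in a provenance dict from which
`regenerate` rebuilds the suite bit-identically. The default suite noise
is σ_n = 0.05, within the plausible posterior range for the printed data
scatter; ground truths sit 0.3 half-widths off the prior center so
recovery is nontrivial; hyper-truth suites draw per-condition truths with
SD = 0.1 half-width.

What the surrogate does *not* emulate: real MD estimator autocorrelation,
rare-event sensitivity of γ and η, finite-size effects, or any physical
response of actual water. Passing the desk-scale suite demonstrates that
the inference machinery is correct, not that a given CG water model is
accurate.

## Problem sizes in the bundled checks

The test and acceptance runs use 48–125 entities, 10⁴-step NVE checks,
1.2·10⁴-step transport runs, ensembles of 800–4000 particles with 2–5
replicates, and 20-repetition recovery/parsimony studies. These sizes were
chosen so each statistical criterion has comfortable Monte-Carlo margin
(3σ bands, binomial tolerances) while the whole suite stays desk-scale.

## Known limitations

* The thermostat's O(dt²) bias reaches ~3% for rigid dimers at the 8 fs
  ceiling; use smaller steps when quantitative temperatures matter.
* The constraint-virial convention (SHAKE multipliers only) is approximate;
  it does not affect the chargeless bulk checks, the volume-fluctuation
  compressibility, or any acceptance quantity, but rigid-model pressure
  tensors should not be over-interpreted.
* Evidence estimates for strongly curved 6+-dimensional posteriors carry
  residual transitional-MCMC bias of order 0.1–0.3 nats at default budgets.
* No Ewald/PME electrostatics, no triclinic boxes, no tabulated potentials;
  the atomistic baseline enters only through the user-supplied cost table.
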