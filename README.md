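# cgwater

Bayesian comparison and selection of coarse-grained (CG) water models.

Effective CG water models replace groups of `M` water molecules by one, two
or three interaction sites, trading molecular detail for large savings in
simulation cost. Which resolution, which site structure, and which degrees
of freedom (charges, bond/angle flexibility) are worth keeping is usually
decided by intuition. This package mechanizes that decision: it treats each
candidate model `M_i` as a Bayesian hypothesis, calibrates its potential
parameters against experimental thermodynamic observables, and scores it by
its **model evidence** `p(d | M_i)` and by an accuracy/efficiency
**expected utility**. It is aimed at force-field developers and simulators
who want a defensible, data-driven ranking of reduced water models.

## The statistical model

For experimental data `d = {d_i}` at conditions `x` (temperature) and a
forward observable map `F(x; φ_c)` (molecular dynamics, or an analytic
surrogate for testing), each datum is modeled with an error proportional to
its own magnitude:

    y_i = F_i(x; φ_c) + σ_n d_i ε,     ε ~ N(0, 1)

so the likelihood is `p(d|φ) = N(d | F(x, φ_c), σ_n² diag(d²))` with
parameter vector `φ = (φ_c, σ_n)` and uniform priors. The evidence
`p(d|M) = ∫ p(d|φ, M) p(φ|M) dφ` is estimated by transitional (tempered)
ensemble MCMC and decomposes as

    ln p(d|M) = E[ln p(d|φ, M)] − KL( p(φ|d, M) ‖ p(φ|M) )

— an expected data fit minus an information-gain (Ockham) penalty, so
over-flexible models are penalized automatically. Models are compared by
`p(M_i|d) ∝ p(d|M_i) p(M_i)` and by the expected utility
`𝒰(M_i; d) = p(M_i|d) · log10(speedup_i)`, with speedups supplied by the
user. A hierarchical layer ties per-temperature parameter vectors `φ_i`
together through hyper-parameters `ψ = (location, scale)`, yielding a
cross-temperature (transferability) evidence and a data-informed prior for
new conditions.

## The model family

Structures `1S` (one chargeless LJ bead), `2S` (±q pair at distance r0),
`3S` (central −q, outer +q/2 each), `3S*` (chargeless central LJ site,
outer ±q), plus flexible variants `2SF` (harmonic bond) and `3SF`/`3SF*`
(harmonic angle), at mappings `M` = 1–12 water molecules per CG entity.
Electrostatics are screened by a global dielectric constant (2.5). The
bundled MD engine (velocity Verlet, SHAKE/RATTLE rigid constraints,
Langevin thermostat, Monte-Carlo barostat, reaction-field electrostatics)
estimates the five target observables: density ρ, dielectric constant ε,
surface tension γ, isothermal compressibility κ and shear viscosity η
(Green–Kubo, with an Einstein-relation cross-check). The experimental
values at 283/298/323 K ship as a CSV fixture.

## Worked example

Calibrate the rigid `3S*` model at mapping 4 against the experimental
observables at 298 K, using the analytic surrogate backend:

```python
from cgwater.model_zoo import build_model, default_priors
from cgwater.synthetic import SurrogateForward, load_experimental_qoi
from cgwater.inference import (make_log_likelihood, sample_posterior,
                               evidence_decomposition, map_estimate)

spec = build_model("3S*", 4)
prior = default_priors(spec)
forward = SurrogateForward(spec, prior)
data = next(d for d in load_experimental_qoi() if d.temperature == 298.0)

ens = sample_posterior(prior, make_log_likelihood(forward, data), seed=1,
                       sampler_cfg={"n_samples": 1000, "n_runs": 3})
rep = evidence_decomposition(ens, prior)
phi_map = map_estimate(ens, prior)
```

which prints (seed 1):

```
model 3S*,4: ln p(d|M) = -11.73 +- 0.21
  expected fit    = -6.10
  information gain= 5.70  (Ockham penalty)
  MAP sigma = 0.524 nm, epsilon = 3.42 kJ/mol, sigma_n = 0.013
```

`ln p(d|M)` is the log-evidence with its replicate standard error; the
information gain is the KL distance the data pulled the posterior away from
the prior — the parsimony penalty subtracted from the expected fit. The MAP
row gives the best-fit LJ diameter and well depth and the inferred relative
error scale.

Ranking models from log-evidences and a user-supplied cost table works from
the shell:

```sh
cgwater rank --evidences evidences.json --costs costs.json \
             --criterion expected_utility
```

Other subcommands (`simulate`, `observe`, `infer`, `evidence`, `hier`,
`synth`, `study`) expose the engine, single-model calibration, the
hierarchical temperature study, synthetic benchmark generation and full
config-driven studies; `cgwater study --preset surrogate-full` runs the
whole desk-scale model sweep. MD-backed studies at production budgets are
gated behind `--cluster`.

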