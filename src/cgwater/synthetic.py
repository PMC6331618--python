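"""Synthetic data for exercising the inference pipeline without MD.

Provides

* an analytic surrogate observable function with known ground truth (a
  smooth, strictly positive response map standing in for the MD forward
  model),
* pseudo-experiment generation under the proportional-error generative
  model ``y_i = F_i(x; phi_c) + noise`` with noise SD proportional to the
  observable,
* multi-condition benchmark suites (common truth across temperatures, or
  per-condition truths drawn from a hyper-distribution), and
* the packaged experimental QoI table (density, dielectric constant,
  surface tension, isothermal compressibility, shear viscosity at
  283/298/323 K).

The surrogate makes no claim of physical fidelity to water; it exists so
that every inference component can be validated against closed forms at
desk scale.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .inference import QOI_LABELS, QOI_UNITS, QoIDataset, read_qoi_csv
from .model_zoo import CGModelSpec, build_model, default_priors
from .priors import TruncatedNormalPrior, UniformBoxPrior

__all__ = [
    "SurrogateForward",
    "SyntheticStudy",
    "surrogate_forward",
    "generate_pseudo_experiment",
    "make_benchmark_suite",
    "regenerate",
    "load_experimental_qoi",
    "REFERENCE_MODEL_PROPERTIES",
]

# Experimental QoI at the three study temperatures (also shipped as CSV).
_EXPERIMENTAL_QOI = {
    "rho": {283.0: 0.999, 298.0: 0.997, 323.0: 0.988},
    "epsilon": {283.0: 84.0, 298.0: 78.4, 323.0: 69.9},
    "gamma": {283.0: 74.2, 298.0: 72.0, 323.0: 67.9},
    "kappa": {283.0: 47.89, 298.0: 45.24, 323.0: 44.17},
    "eta": {283.0: 1.307, 298.0: 0.891, 323.0: 0.547},
}

# Published properties of reference CG water models at 298 K, kept only as
# comparison constants (None where no value is defined/reported).
REFERENCE_MODEL_PROPERTIES = {
    "MARTINI": {"rho": 0.99, "epsilon": None, "gamma": 35.0, "kappa": 60.0},
    "MARTINI-pol": {"rho": 1.043, "epsilon": 75.6, "gamma": 30.5},
    "BMW": {"rho": 1.047, "epsilon": 74.0, "gamma": 77.0, "kappa": 33.0},
    "GROMOS-CG": {"rho": 0.995, "epsilon": 73.7, "gamma": 51.2},
}

# Canonical column per parameter symbol (both force constants share one).
_PARAM_COL = {
    "sigma": 0,
    "epsilon": 1,
    "q": 2,
    "r0": 3,
    "theta0": 4,
    "k_b": 5,
    "k_a": 5,
}

# Fixed response coefficients: rows follow QOI_LABELS, columns _PARAM_COL.
# Signs encode the qualitative physics of a CG fluid: larger beads lower the
# density, deeper LJ wells raise surface tension and viscosity and lower the
# compressibility, charge raises the dielectric response.
_BASE_C = np.array(
    [
        [-0.35, 0.15, 0.05, -0.10, 0.04, 0.02],   # rho
        [-0.10, 0.05, 0.60, 0.25, -0.15, 0.03],   # epsilon (dielectric)
        [0.20, 0.45, 0.15, -0.05, 0.10, -0.04],   # gamma
        [0.30, -0.40, -0.10, 0.08, -0.06, 0.05],  # kappa
        [0.15, 0.50, 0.20, 0.12, 0.08, 0.06],     # eta
    ]
)

# Mild curvature; kept small so responses stay monotone over the unit cube.
_BASE_Q = np.array(
    [
        [0.04, -0.03, 0.02, 0.03, -0.02, 0.01],
        [-0.03, 0.02, 0.05, -0.02, 0.03, -0.01],
        [0.03, 0.05, -0.02, 0.02, 0.01, 0.02],
        [-0.02, 0.04, 0.03, -0.03, 0.02, -0.02],
        [0.02, 0.05, 0.02, 0.04, -0.03, 0.01],
    ]
)


def _f0(label: str, temperature: float) -> float:
    """Reference observable at a condition, linearly interpolated in T."""
    table = _EXPERIMENTAL_QOI[label]
    temps = np.array(sorted(table))
    vals = np.array([table[t] for t in temps])
    return float(np.interp(temperature, temps, vals))


class SurrogateForward:
    """Closed-form stand-in for the MD observable function F(x; phi_c).

    The response in scaled coordinates ``u = (phi_c - phi0) / halfwidth``
    (phi0 the prior-box center) is

        F_k(phi, T) = F0_k(T) * exp( c_k(T) . u  +  q_k . u^2 )

    with fixed coefficient tables and a temperature modulation
    ``c_k(T) = c_k * (1 + 0.15 (T - 298)/40)``.  By construction
    F(phi0, T) = F0(T) exactly and all outputs are strictly positive.
    Optional multiplicative lognormal jitter mimics MD estimator noise.
    """

    def __init__(
        self,
        spec: Optional[CGModelSpec] = None,
        prior: Optional[UniformBoxPrior] = None,
        names: Optional[Sequence[str]] = None,
        labels: Optional[Sequence[str]] = None,
        jitter: float = 0.0,
    ):
        if spec is not None:
            names = names or spec.parameter_names
            if labels is None:
                labels = (
                    QOI_LABELS
                    if spec.is_charged
                    else tuple(l for l in QOI_LABELS if l != "epsilon")
                )
            if prior is None:
                prior = default_priors(spec)
        if names is None or prior is None:
            raise ValueError("need a model spec or explicit names + prior")
        self.names = tuple(names)
        self.labels = tuple(labels or QOI_LABELS)
        self.jitter = float(jitter)
        # strip sigma_n if the prior includes it
        keep = [i for i, n in enumerate(prior.names) if n != "sigma_n"]
        lo = prior.lower[keep]
        hi = prior.upper[keep]
        kept_names = tuple(prior.names[i] for i in keep)
        if kept_names != self.names:
            raise ValueError("prior parameter names do not match the model")
        self.phi0 = 0.5 * (lo + hi)
        self.halfwidth = 0.5 * (hi - lo)
        cols = [_PARAM_COL[n] for n in self.names]
        rows = [QOI_LABELS.index(l) for l in self.labels]
        self._C = _BASE_C[np.ix_(rows, cols)]
        self._Q = _BASE_Q[np.ix_(rows, cols)]

    @property
    def n_params(self) -> int:
        return len(self.names)

    def f0(self, temperature: float) -> np.ndarray:
        return np.array([_f0(l, temperature) for l in self.labels])

    def __call__(self, phi_c, temperature: float, rng=None) -> np.ndarray:
        phi = np.asarray(phi_c, dtype=float)
        single = phi.ndim == 1
        phi2 = phi[None, :] if single else phi
        u = (phi2 - self.phi0) / self.halfwidth
        tfac = 1.0 + 0.15 * (temperature - 298.0) / 40.0
        expo = u @ (tfac * self._C).T + (u**2) @ (tfac * self._Q).T
        F = self.f0(temperature)[None, :] * np.exp(expo)
        if self.jitter > 0:
            if rng is None:
                raise ValueError("jitter > 0 requires an rng")
            F = F * np.exp(self.jitter * rng.standard_normal(F.shape))
        return F[0] if single else F

    def observable_vector(self, phi_c, temperature: float, rng=None):
        from .engine.observables import ObservableVector

        vals = self(phi_c, temperature, rng=rng)
        return ObservableVector(
            values=dict(zip(self.labels, vals)),
            temperature=temperature,
        )

    def jacobian_fd(self, phi_c, temperature: float, h: float = 1e-6):
        """Finite-difference Jacobian dF/dphi at a point (for rank checks)."""
        phi = np.asarray(phi_c, dtype=float)
        J = np.empty((len(self.labels), len(phi)))
        for j in range(len(phi)):
            e = np.zeros_like(phi)
            e[j] = h * max(1.0, abs(phi[j]))
            J[:, j] = (self(phi + e, temperature) - self(phi - e, temperature)) / (
                2 * e[j]
            )
        return J


def surrogate_forward(phi_c, temperature: float, spec=None, **kw) -> np.ndarray:
    """Functional convenience wrapper around :class:`SurrogateForward`."""
    sur = SurrogateForward(spec=spec or build_model("3S*", 4), **kw)
    return sur(phi_c, temperature)


def generate_pseudo_experiment(
    forward,
    phi_star,
    sigma_n: float,
    temperature: float,
    seed: int,
    labels: Optional[Sequence[str]] = None,
) -> QoIDataset:
    """Draw one pseudo-experimental dataset from the generative model.

    Each datum is ``d_i = F_i (1 + sigma_n xi)`` with standard-normal xi:
    the generative noise scale is proportional to the model observable
    (the likelihood keeps its proportionality to the datum itself).
    """
    if sigma_n < 0:
        raise ValueError("sigma_n must be nonnegative")
    labels = tuple(labels or getattr(forward, "labels", QOI_LABELS))
    rng = np.random.default_rng(seed)
    F = np.asarray(forward(np.asarray(phi_star, dtype=float), temperature))
    d = F * (1.0 + sigma_n * rng.standard_normal(len(F)))
    return QoIDataset(labels=labels, values=d, temperature=temperature)


@dataclass
class SyntheticStudy:
    """A generated benchmark: datasets plus full ground-truth provenance."""

    kind: str
    spec: CGModelSpec
    prior: UniformBoxPrior
    surrogate: SurrogateForward
    true_params: np.ndarray        # (n_conditions, n_params)
    sigma_n: float
    datasets: list
    seed: int
    hyper_loc: Optional[np.ndarray] = None
    hyper_scale: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_conditions(self) -> int:
        return len(self.datasets)

    @property
    def temperatures(self):
        return [ds.temperature for ds in self.datasets]


_DEFAULT_TEMPS = (283.0, 298.0, 323.0)


def make_benchmark_suite(
    kind: str,
    n_conditions: int = 3,
    seed: int = 0,
    structure: str = "3S*",
    mapping: int = 4,
    sigma_n: float = 0.05,
    hyper_rel_scale: float = 0.10,
) -> SyntheticStudy:
    """Generate a seeded multi-condition benchmark.

    kinds: ``single_condition`` (one temperature), ``common_truth`` (one
    phi* shared by all temperatures), ``hyper_truth`` (per-condition phi*_i
    drawn from a Gaussian with SD ``hyper_rel_scale`` x prior half-width,
    truncated to the prior box).  Datasets carry the same QoI labels/units
    and temperatures as the experimental table.
    """
    if kind not in ("single_condition", "common_truth", "hyper_truth"):
        raise ValueError(f"unknown suite kind {kind!r}")
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    if kind == "single_condition":
        n_conditions = 1

    spec = build_model(structure, mapping)
    prior = default_priors(spec)
    sur = SurrogateForward(spec, prior)
    temps = [
        _DEFAULT_TEMPS[i % 3] + 25.0 * (i // 3) for i in range(n_conditions)
    ]

    # ground truth offset from the prior center so recovery is nontrivial
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(sur.n_params)])
    phi_star = sur.phi0 + 0.3 * sur.halfwidth * signs

    ss = np.random.SeedSequence(seed)
    hyper_seed, *data_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_conditions + 1)
    ]

    hyper_loc = hyper_scale = None
    if kind == "hyper_truth":
        hyper_loc = phi_star.copy()
        hyper_scale = hyper_rel_scale * sur.halfwidth
        hyper = TruncatedNormalPrior(
            sur.names, hyper_loc, hyper_scale,
            sur.phi0 - sur.halfwidth, sur.phi0 + sur.halfwidth,
        )
        truths = hyper.sample(n_conditions, np.random.default_rng(hyper_seed))
    else:
        truths = np.tile(phi_star, (n_conditions, 1))

    datasets = [
        generate_pseudo_experiment(sur, truths[i], sigma_n, temps[i], data_seeds[i])
        for i in range(n_conditions)
    ]
    provenance = {
        "kind": kind,
        "n_conditions": n_conditions,
        "seed": seed,
        "structure": structure,
        "mapping": mapping,
        "sigma_n": sigma_n,
        "hyper_rel_scale": hyper_rel_scale,
    }
    return SyntheticStudy(
        kind=kind,
        spec=spec,
        prior=prior,
        surrogate=sur,
        true_params=truths,
        sigma_n=sigma_n,
        datasets=datasets,
        seed=seed,
        hyper_loc=hyper_loc,
        hyper_scale=hyper_scale,
        provenance=provenance,
    )


def regenerate(provenance: dict) -> SyntheticStudy:
    """Rebuild a study bit-identically from its provenance record."""
    return make_benchmark_suite(**provenance)


def load_experimental_qoi() -> list:
    """The packaged experimental QoI datasets (one per temperature)."""
    path = importlib.resources.files("cgwater.data").joinpath(
        "experimental_qoi.csv"
    )
    with importlib.resources.as_file(path) as p:
        return read_qoi_csv(p)
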