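"""Hierarchical Bayesian calibration across conditions (temperatures).

Data measured at several conditions d = {d_1, ..., d_Nd} are modeled with
per-condition parameter vectors phi_i tied together by hyper-parameters
psi = (loc, scale): conditionally on psi, each phi_i follows independent
per-dimension Gaussians truncated to the base prior box.  The hyper-prior
is uniform on each location over the box and log-uniform on each scale.

Sampling is two-staged: classical per-condition posteriors are drawn first
under the flat base prior; the hyper-level likelihood

    p(d_i | psi) = Z_i * E_{phi ~ p(phi|d_i)}[ p(phi|psi) / p_base(phi) ]

is then evaluated by importance reweighting of those ensembles, and psi is
sampled with the same transitional-MCMC evidence estimator.  The total
hierarchical log-evidence is sum_i ln Z_i + ln Z_hyper.  Per-condition
posteriors informed by all data, p(phi_i | d_vec), are obtained by
reweighting each condition's ensemble by the hyper-posterior-averaged
prior ratio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .inference import (
    PosteriorEnsemble,
    make_log_likelihood,
    sample_posterior,
)
from .priors import TruncatedNormalPrior, UniformBoxPrior

__all__ = [
    "HyperParameters",
    "PointHyperPrior",
    "HierarchicalResult",
    "make_hyper_prior",
    "fit_hierarchical",
    "predictive_prior",
    "PredictivePrior",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class HyperParameters:
    """psi = (loc, scale) over the parameter dimensions."""

    loc: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.loc = np.atleast_1d(np.asarray(self.loc, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        if np.any(self.scale <= 0):
            raise ValueError("hyper scales must be positive")


@dataclass
class PointHyperPrior:
    """Degenerate hyper-prior: psi fixed at a single value."""

    psi: HyperParameters


@dataclass
class HierarchicalResult:
    """Output of :func:`fit_hierarchical`."""

    per_condition: list                 # PosteriorEnsemble, informed by all data
    per_condition_independent: list     # PosteriorEnsemble, single-condition
    hyper_samples: Optional[np.ndarray]  # (n, 2*dim): loc then log-scale
    hyper_names: tuple
    log_evidence: float                 # hierarchical ln p(d_vec | M)
    log_evidence_se: float
    condition_log_evidences: list
    base_prior: UniformBoxPrior = None
    seed: Optional[int] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_conditions(self) -> int:
        return len(self.per_condition)

    def hyper_posterior(self) -> Optional[dict]:
        """Mean/SD summaries of the hyper-posterior (locs and scales)."""
        if self.hyper_samples is None:
            return None
        d = self.hyper_samples.shape[1] // 2
        locs = self.hyper_samples[:, :d]
        scales = np.exp(self.hyper_samples[:, d:])
        return {
            "loc_mean": locs.mean(axis=0),
            "loc_sd": locs.std(axis=0, ddof=1),
            "scale_mean": scales.mean(axis=0),
            "scale_sd": scales.std(axis=0, ddof=1),
        }


def make_hyper_prior(
    base_prior: UniformBoxPrior,
    scale_lo_frac: float = 1.0 / 200.0,
    scale_hi_frac: float = 1.0,
) -> UniformBoxPrior:
    """Uniform hyper-prior over (loc, ln scale) per dimension.

    Locations range over the base box; log-scales uniformly between
    ln(width * scale_lo_frac) and ln(width * scale_hi_frac).
    """
    widths = base_prior.upper - base_prior.lower
    names = tuple(f"loc_{n}" for n in base_prior.names) + tuple(
        f"log_scale_{n}" for n in base_prior.names
    )
    lower = np.concatenate([base_prior.lower, np.log(widths * scale_lo_frac)])
    upper = np.concatenate([base_prior.upper, np.log(widths * scale_hi_frac)])
    return UniformBoxPrior(names, lower, upper)


def _trunc_norm_log_pdf(X, loc, scale, lo, hi):
    """log p(X | psi) for per-dim truncated normals.

    X: (S, d); loc/scale: (m, d); returns (m, S).
    """
    z = (X[None, :, :] - loc[:, None, :]) / scale[:, None, :]
    a = (lo[None, :] - loc) / scale      # (m, d)
    b = (hi[None, :] - loc) / scale
    log_z = np.log(np.maximum(ndtr(b) - ndtr(a), 1e-300))  # (m, d)
    lp = (
        -0.5 * z**2
        - 0.5 * _LOG_2PI
        - np.log(scale)[:, None, :]
        - log_z[:, None, :]
    ).sum(axis=2)
    return lp


def _hyper_log_likelihood(cond_samples, base_prior, chunk=64):
    """Batched hyper-level log-likelihood ln prod_i E_i[p(phi|psi)/p_base]."""
    lo, hi = base_prior.lower, base_prior.upper
    log_vol = float(np.sum(np.log(hi - lo)))
    d = len(lo)

    def fn(Psi: np.ndarray) -> np.ndarray:
        Psi = np.atleast_2d(Psi)
        m = len(Psi)
        out = np.zeros(m)
        for start in range(0, m, chunk):
            P = Psi[start : start + chunk]
            loc, log_s = P[:, :d], P[:, d:]
            scale = np.exp(log_s)
            tot = np.zeros(len(P))
            for X in cond_samples:
                lp = _trunc_norm_log_pdf(X, loc, scale, lo, hi)  # (mc, S)
                mx = lp.max(axis=1)
                mean_ratio = (
                    mx
                    + np.log(np.mean(np.exp(lp - mx[:, None]), axis=1))
                    + log_vol
                )
                tot += mean_ratio
            out[start : start + chunk] = tot
        return out

    return fn


def _condition_weights(X, base_prior, psi_locs, psi_log_scales, max_draws=300,
                       rng=None):
    """Posterior-averaged prior-ratio weights for one condition's samples."""
    lo, hi = base_prior.lower, base_prior.upper
    log_vol = float(np.sum(np.log(hi - lo)))
    n = len(psi_locs)
    if n > max_draws:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(n, size=max_draws, replace=False)
        psi_locs = psi_locs[idx]
        psi_log_scales = psi_log_scales[idx]
    lp = _trunc_norm_log_pdf(
        X, psi_locs, np.exp(psi_log_scales), lo, hi
    )  # (T, S)
    lr = lp + log_vol
    mx = lr.max(axis=0)
    w = np.mean(np.exp(lr - mx[None, :]), axis=0) * np.exp(mx - mx.max())
    return w / w.sum()


def fit_hierarchical(
    datasets: Sequence,
    forward: Callable,
    base_prior: UniformBoxPrior,
    hyper_prior=None,
    sampler_cfg: Optional[dict] = None,
    hyper_sampler_cfg: Optional[dict] = None,
    seed: int = 0,
    condition_seeds: Optional[Sequence[int]] = None,
    sigma_n: Optional[float] = None,
) -> HierarchicalResult:
    """Two-stage hierarchical fit across conditions.

    ``datasets`` is one QoIDataset per condition; ``forward`` the batched
    observable function shared by all conditions.  ``hyper_prior`` defaults
    to :func:`make_hyper_prior` over all parameter dimensions (including
    sigma_n, so the error scale is tied across conditions only through its
    own hyper-component); pass a :class:`PointHyperPrior` to condition on a
    fixed psi.
    """
    datasets = list(datasets)
    n_cond = len(datasets)
    if n_cond < 1:
        raise ValueError("need at least one condition")
    labels0 = set(datasets[0].labels)
    if any(set(ds.labels) != labels0 for ds in datasets):
        raise ValueError("QoI labels must agree across conditions")

    if condition_seeds is None:
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(n_cond + 1)
        condition_seeds = [
            int(c.generate_state(1)[0] % (2**31)) for c in children[:-1]
        ]
        hyper_seed = int(children[-1].generate_state(1)[0] % (2**31))
    else:
        condition_seeds = [int(s) for s in condition_seeds]
        hyper_seed = int(
            np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
        )

    # Stage 1: classical per-condition posteriors under the base prior
    independent = []
    for ds, s in zip(datasets, condition_seeds):
        ll = make_log_likelihood(forward, ds, sigma_n=sigma_n)
        independent.append(
            sample_posterior(
                base_prior, ll, sampler_cfg=sampler_cfg, seed=s,
                names=base_prior.names,
            )
        )
    cond_samples = [e.samples for e in independent]
    cond_log_z = [e.log_evidence for e in independent]
    cond_se2 = sum(e.log_evidence_se**2 for e in independent)

    # Stage 2: hyper-level
    if isinstance(hyper_prior, PointHyperPrior):
        psi = hyper_prior.psi
        locs = psi.loc[None, :]
        lscales = np.log(psi.scale)[None, :]
        hyper_ll = _hyper_log_likelihood(cond_samples, base_prior)
        point = np.concatenate([psi.loc, np.log(psi.scale)])[None, :]
        log_z_hyper = float(hyper_ll(point)[0])
        hyper_samples = None
        hyper_names = ()
        se_hyper = 0.0
        diag = {"hyper": "point"}
    else:
        if hyper_prior is None:
            hyper_prior = make_hyper_prior(base_prior)
        hyper_ll = _hyper_log_likelihood(cond_samples, base_prior)
        hcfg = dict(n_samples=500, n_runs=2)
        if hyper_sampler_cfg:
            hcfg.update(hyper_sampler_cfg)
        hyper_ens = sample_posterior(
            hyper_prior, hyper_ll, sampler_cfg=hcfg, seed=hyper_seed,
            names=hyper_prior.names,
        )
        hyper_samples = hyper_ens.samples
        hyper_names = hyper_prior.names
        log_z_hyper = hyper_ens.log_evidence
        se_hyper = hyper_ens.log_evidence_se
        d = len(base_prior.lower)
        locs = hyper_samples[:, :d]
        lscales = hyper_samples[:, d:]
        diag = {"hyper_diagnostics": hyper_ens.diagnostics}

    log_evidence = float(sum(cond_log_z) + log_z_hyper)
    se = math.sqrt(cond_se2 + se_hyper**2)

    # Per-condition posteriors informed by all data (reweighted multiplies
    # existing ensemble weights, so pass the ratio)
    informed = [
        ens.reweighted(
            _condition_weights(
                ens.samples, base_prior, locs, lscales,
                rng=np.random.default_rng(condition_seeds[i] + 1),
            )
            / ens.weights
        )
        for i, ens in enumerate(independent)
    ]

    return HierarchicalResult(
        per_condition=informed,
        per_condition_independent=independent,
        hyper_samples=hyper_samples,
        hyper_names=hyper_names,
        log_evidence=log_evidence,
        log_evidence_se=se,
        condition_log_evidences=cond_log_z,
        base_prior=base_prior,
        seed=seed,
        diagnostics=diag,
    )


@dataclass
class PredictivePrior:
    """The data-informed prior p(phi) = int p(phi|psi) p(psi|d_vec) dpsi,
    represented as a finite mixture over hyper-posterior draws."""

    components: list                    # TruncatedNormalPrior mixture terms
    names: tuple = ()

    @property
    def dim(self) -> int:
        return self.components[0].dim

    @property
    def bounds(self):
        return self.components[0].bounds

    def log_pdf(self, x):
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        lps = np.stack([c.log_pdf(x2) for c in self.components])  # (T, n)
        mx = lps.max(axis=0)
        safe = np.where(np.isfinite(mx), mx, 0.0)
        out = safe + np.log(np.mean(np.exp(lps - safe[None, :]), axis=0))
        out = np.where(np.isfinite(mx), out, -np.inf)
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    def pdf(self, x):
        return np.exp(self.log_pdf(x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ks = rng.integers(0, len(self.components), size=n)
        out = np.empty((n, self.dim))
        for k in np.unique(ks):
            m = ks == k
            out[m] = self.components[k].sample(int(m.sum()), rng)
        return out


def predictive_prior(
    result: HierarchicalResult, max_components: int = 300, seed: int = 0
) -> PredictivePrior:
    """Data-informed prior for a new, unobserved condition."""
    lo, hi = result.base_prior.lower, result.base_prior.upper
    names = result.base_prior.names
    if result.hyper_samples is None:
        raise ValueError("point hyper-prior: predictive prior is p(phi|psi*)")
    H = result.hyper_samples
    if len(H) > max_components:
        rng = np.random.default_rng(seed)
        H = H[rng.choice(len(H), size=max_components, replace=False)]
    d = H.shape[1] // 2
    comps = [
        TruncatedNormalPrior(names, h[:d], np.exp(h[d:]), lo, hi) for h in H
    ]
    return PredictivePrior(components=comps, names=names)
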