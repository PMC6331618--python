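"""Shared closed-form Bayesian oracles for the test suite."""

import numpy as np
from scipy import stats

from cgwater.inference import QoIDataset
from cgwater.priors import GaussianPrior


def conjugate_problem(dim, seed, n_data=None):
    """Linear-Gaussian forward with a Gaussian prior and fixed error scale.

    Data are generated from the model itself; the marginal likelihood,
    posterior mean/covariance, and the prior-to-posterior KL divergence all
    have closed forms, providing independent oracles for the evidence
    sampler and the decomposition.
    """
    rng = np.random.default_rng(seed)
    n_data = n_data or dim + 3
    A = rng.standard_normal((n_data, dim)) * 0.8
    b = rng.standard_normal(n_data)
    m0, S0 = np.zeros(dim), np.eye(dim) * 0.5
    phi_true = stats.multivariate_normal(m0, S0).rvs(random_state=rng)
    sn = 0.1
    mean = A @ np.atleast_1d(phi_true) + b
    d = mean + sn * np.abs(mean) * rng.standard_normal(n_data)
    d[np.abs(d) < 0.2] += 0.5          # keep data away from zero
    Sig = sn**2 * np.diag(d**2)
    log_z = stats.multivariate_normal(A @ m0 + b, A @ S0 @ A.T + Sig).logpdf(d)
    S_post = np.linalg.inv(np.linalg.inv(S0) + A.T @ np.linalg.inv(Sig) @ A)
    m_post = S_post @ (A.T @ np.linalg.inv(Sig) @ (d - b))
    dm = m0 - m_post
    kl = 0.5 * (
        np.trace(np.linalg.inv(S0) @ S_post)
        + dm @ np.linalg.inv(S0) @ dm
        - dim
        + np.log(np.linalg.det(S0) / np.linalg.det(S_post))
    )
    ds = QoIDataset(
        labels=[f"q{i}" for i in range(n_data)], values=d, temperature=298.0
    )
    prior = GaussianPrior(tuple(f"p{i}" for i in range(dim)), m0, S0)
    fwd = lambda phi, x: phi @ A.T + b  # noqa: E731
    return dict(
        prior=prior, forward=fwd, dataset=ds, sigma_n=sn,
        log_z=log_z, m_post=m_post, S_post=S_post, m0=m0, S0=S0, kl=kl,
    )
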