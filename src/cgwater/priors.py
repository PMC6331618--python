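"""Prior distributions over parameter vectors.

All priors operate on batches: ``log_pdf`` accepts an array of shape
``(n, dim)`` (or ``(dim,)``) and returns ``(n,)`` (or a scalar); ``sample``
returns ``(n, dim)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


def _atleast_2d(x):
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    return (x[None, :] if scalar else x), scalar


@dataclass
class UniformBoxPrior:
    """Independent uniform prior over an axis-aligned box."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower >= self.upper):
            raise ValueError("prior bounds must satisfy lower < upper")
        self._log_vol = float(np.sum(np.log(self.upper - self.lower)))

    @property
    def dim(self) -> int:
        return len(self.lower)

    @property
    def bounds(self):
        return self.lower, self.upper

    def log_pdf(self, x):
        x2, scalar = _atleast_2d(x)
        inside = np.all((x2 >= self.lower) & (x2 <= self.upper), axis=1)
        out = np.where(inside, -self._log_vol, -np.inf)
        return float(out[0]) if scalar else out

    def pdf(self, x):
        return np.exp(self.log_pdf(x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def restrict(self, name: str, lo: float, hi: float) -> "UniformBoxPrior":
        """Return a copy with one parameter's bounds replaced."""
        i = self.names.index(name)
        lower, upper = self.lower.copy(), self.upper.copy()
        lower[i], upper[i] = lo, hi
        return UniformBoxPrior(self.names, lower, upper)


@dataclass
class GaussianPrior:
    """Multivariate normal prior (used e.g. for conjugate cross-checks)."""

    names: tuple
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        self._mvn = stats.multivariate_normal(self.mean, self.cov)
        self._chol = np.linalg.cholesky(self.cov)

    @property
    def dim(self) -> int:
        return len(self.mean)

    @property
    def bounds(self):
        return None

    def log_pdf(self, x):
        x2, scalar = _atleast_2d(x)
        out = np.atleast_1d(self._mvn.logpdf(x2))
        return float(out[0]) if scalar else out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.dim))
        return self.mean + z @ self._chol.T


@dataclass
class TruncatedNormalPrior:
    """Independent per-dimension normals truncated to a box.

    This is the conditional prior p(phi | psi) of the hierarchical layer:
    psi = (loc, scale) per dimension, support clipped to the base box.
    """

    names: tuple
    loc: np.ndarray
    scale: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.loc = np.asarray(self.loc, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")
        self._a = (self.lower - self.loc) / self.scale
        self._b = (self.upper - self.loc) / self.scale
        # log normalizer per dim, Phi(b) - Phi(a)
        self._log_z = np.log(
            stats.norm.cdf(self._b) - stats.norm.cdf(self._a)
        )

    @property
    def dim(self) -> int:
        return len(self.loc)

    @property
    def bounds(self):
        return self.lower, self.upper

    def log_pdf(self, x):
        x2, scalar = _atleast_2d(x)
        z = (x2 - self.loc) / self.scale
        lp = (
            stats.norm.logpdf(z)
            - np.log(self.scale)
            - self._log_z
        ).sum(axis=1)
        inside = np.all((x2 >= self.lower) & (x2 <= self.upper), axis=1)
        lp = np.where(inside, lp, -np.inf)
        return float(lp[0]) if scalar else lp

    def pdf(self, x):
        return np.exp(self.log_pdf(x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # inverse-CDF sampling per dimension
        u = rng.uniform(size=(n, self.dim))
        ca = stats.norm.cdf(self._a)
        cb = stats.norm.cdf(self._b)
        z = stats.norm.ppf(ca + u * (cb - ca))
        return self.loc + z * self.scale
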