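"""Estimators for the five quantities of interest.

From an NPT bulk trajectory: density rho (g/cm^3), isothermal
compressibility kappa (1e-6/bar, from volume fluctuations) and the
dielectric constant (from total-dipole fluctuations, consistent with the
reaction-field electrostatics with uniform screening eps_r: the fluctuation
term is divided by eps_r, and a chargeless system has eps = 1).  From a
slab NVT trajectory: surface tension gamma (mN/m, pressure-tensor
anisotropy).  From a bulk NVT trajectory: shear viscosity eta (mPa*s,
Green-Kubo integral of the off-diagonal pressure autocorrelation, with an
Einstein-relation cross-estimator).

Statistical errors come from block averaging (default 10 blocks) or, for
the viscosity, from the spread of the three independent tensor components.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .. import units
from ..model_zoo import CGModelSpec
from .core import Trajectory

__all__ = [
    "ObservableVector",
    "estimate_static_qoi",
    "estimate_surface_tension",
    "estimate_viscosity",
    "estimate_viscosity_einstein",
]


@dataclass
class ObservableVector:
    """QoI values at one condition, in their conventional units."""

    values: dict                      # label -> value
    temperature: float = float("nan")
    errors: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite observable {k!r}")
        if "rho" in self.values and self.values["rho"] <= 0:
            raise ValueError("density must be positive")

    @property
    def labels(self) -> tuple:
        return tuple(self.values)

    def as_array(self, labels=None) -> np.ndarray:
        labels = labels or self.labels
        return np.array([self.values[l] for l in labels], dtype=float)

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "values": dict(self.values),
            "errors": dict(self.errors),
            "units": {l: units_of(l) for l in self.values},
            "metadata": dict(self.metadata),
        }


_QOI_UNITS = {
    "rho": "g/cm3",
    "epsilon": "dimensionless",
    "gamma": "mN/m",
    "kappa": "1e-6/bar",
    "eta": "mPa s",
}


def units_of(label: str) -> str:
    return _QOI_UNITS.get(label, "")


def _equilibrated(traj: Trajectory, equilibration: float):
    n0 = int(equilibration * traj.n_frames)
    if traj.n_frames - n0 < 2:
        raise ValueError("trajectory too short after equilibration discard")
    return slice(n0, None)


def _block_error(x: np.ndarray, n_blocks: int) -> float:
    if len(x) < 2 * n_blocks:
        raise ValueError(
            f"trajectory too short for {n_blocks}-block averaging"
        )
    usable = (len(x) // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / math.sqrt(n_blocks))


def estimate_static_qoi(
    traj: Trajectory,
    spec: CGModelSpec,
    equilibration: float = 0.2,
    n_blocks: int = 10,
) -> ObservableVector:
    """rho, kappa and (for charged models) the dielectric constant from an
    NPT trajectory."""
    if traj.ensemble != "NPT":
        raise ValueError("static QoI require an NPT trajectory")
    sl = _equilibrated(traj, equilibration)
    V = traj.volume[sl]
    kbt = units.KB * traj.temperature
    m_tot = traj.n_entities * spec.total_mass

    rho_series = m_tot / V * units.DENSITY_G_CM3
    rho = float(rho_series.mean())
    rho_err = _block_error(rho_series, n_blocks)

    v_mean = V.mean()
    kappa_int = float(V.var(ddof=0) / (kbt * v_mean))  # 1/(kJ/mol/nm^3)
    kappa = kappa_int / units.PRESSURE_BAR * 1e6       # 1e-6/bar
    # block estimate of the fluctuation statistic
    usable = (len(V) // n_blocks) * n_blocks
    vb = V[:usable].reshape(n_blocks, -1)
    kb_blocks = vb.var(axis=1, ddof=0) / (kbt * vb.mean(axis=1))
    kappa_err = float(
        kb_blocks.std(ddof=1) / math.sqrt(n_blocks)
    ) / units.PRESSURE_BAR * 1e6

    values = {"rho": rho, "kappa": kappa}
    errors = {"rho": rho_err, "kappa": kappa_err}

    if spec.is_charged:
        M = traj.dipole[sl]
        dM2 = float(np.sum(M.var(axis=0, ddof=0)))  # <M^2> - <M>^2, (e nm)^2
        pref = 4.0 * math.pi * units.F_COULOMB / (
            3.0 * spec.global_dielectric * kbt
        )
        eps = 1.0 + pref * dM2 / v_mean
        m2 = np.sum((M - M.mean(axis=0)) ** 2, axis=1)
        eps_err = pref * _block_error(m2, n_blocks) / v_mean
        values["epsilon"] = float(eps)
        errors["epsilon"] = float(eps_err)

    return ObservableVector(
        values=values,
        temperature=traj.temperature,
        errors=errors,
        metadata={"estimator": "npt-fluctuations", "seed": traj.seed},
    )


def estimate_surface_tension(
    traj: Trajectory,
    spec: CGModelSpec,
    equilibration: float = 0.2,
    n_blocks: int = 10,
) -> float:
    """gamma (mN/m) from the pressure anisotropy of a slab trajectory.

    gamma = (L_z / 2) < P_zz - (P_xx + P_yy)/2 >.  Returns the value; the
    block-averaged standard error is available via
    :func:`surface_tension_with_error`.
    """
    val, _ = surface_tension_with_error(traj, spec, equilibration, n_blocks)
    return val


def surface_tension_with_error(
    traj: Trajectory,
    spec: CGModelSpec,
    equilibration: float = 0.2,
    n_blocks: int = 10,
):
    if not traj.metadata.get("slab", False):
        warnings.warn(
            "surface-tension estimate on a non-slab (homogeneous) "
            "trajectory; expect a result near zero",
            stacklevel=2,
        )
    sl = _equilibrated(traj, equilibration)
    P = traj.pressure_tensor[sl]
    lz = traj.box_series[sl, 2]
    series = 0.5 * lz * (P[:, 2, 2] - 0.5 * (P[:, 0, 0] + P[:, 1, 1]))
    gamma = float(series.mean()) * units.SURFACE_TENSION_MN_M
    err = _block_error(series, n_blocks) * units.SURFACE_TENSION_MN_M
    return gamma, err


def _acf_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    nf = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nf)
    acf = np.fft.irfft(f * np.conj(f), nf)[:max_lag]
    return acf / (n - np.arange(max_lag))


def estimate_viscosity(
    traj: Trajectory,
    spec: CGModelSpec,
    equilibration: float = 0.2,
    max_lag_frac: float = 0.2,
):
    """Green-Kubo shear viscosity (mPa*s) with plateau detection.

    eta = (V / k_B T) integral dt <P_ab(0) P_ab(t)> for ab in {xy, xz, yz};
    each component's autocorrelation is integrated up to the first zero
    crossing of the component-averaged ACF (the running integral has
    plateaued there).  Returns (eta, standard error, flagged) where
    ``flagged`` marks a non-decaying autocorrelation.
    """
    sl = _equilibrated(traj, equilibration)
    P = traj.pressure_tensor[sl]
    comps = np.stack([P[:, 0, 1], P[:, 0, 2], P[:, 1, 2]])
    dt_s = traj.dt * traj.sample_every
    n = comps.shape[1]
    max_lag = max(2, int(max_lag_frac * n))
    acfs = np.stack([_acf_fft(c - c.mean(), max_lag) for c in comps])
    mean_acf = acfs.mean(axis=0)
    below = np.nonzero(mean_acf <= 0)[0]
    flagged = len(below) == 0
    cut = int(below[0]) if len(below) else max_lag
    V = float(traj.volume[sl].mean())
    kbt = units.KB * traj.temperature
    pref = V / kbt * dt_s * units.VISCOSITY_MPAS
    # trapezoidal integral of each component ACF up to the plateau point
    etas = np.array(
        [
            pref * (np.sum(a[:cut]) - 0.5 * a[0] - (0.5 * a[cut - 1] if cut > 1 else 0.0))
            for a in acfs
        ]
    )
    eta = float(etas.mean())
    err = float(etas.std(ddof=1) / math.sqrt(len(etas))) if len(etas) > 1 else 0.0
    return eta, err, flagged


def estimate_viscosity_einstein(
    traj: Trajectory,
    spec: CGModelSpec,
    equilibration: float = 0.2,
    fit_window=(0.05, 0.25),
):
    """Einstein-relation viscosity from the same trajectory.

    eta = (V / 2 k_B T) d/dt < ( integral_0^t P_ab dt' )^2 >, slope fitted
    over ``fit_window`` (fractions of the available lag range), averaged
    over the three off-diagonal components.  Serves as an independent
    cross-estimator for the Green-Kubo route.
    """
    sl = _equilibrated(traj, equilibration)
    P = traj.pressure_tensor[sl]
    comps = np.stack([P[:, 0, 1], P[:, 0, 2], P[:, 1, 2]])
    dt_s = traj.dt * traj.sample_every
    n = comps.shape[1]
    max_lag = max(4, int(0.25 * n))
    V = float(traj.volume[sl].mean())
    kbt = units.KB * traj.temperature

    lags = np.arange(1, max_lag)
    etas = []
    for c in comps:
        a = _acf_fft(c - c.mean(), max_lag)
        # <A(t)^2> from the ACF: dt^2 * sum_{i,j<t} acf(|i-j|)
        msd = np.empty(len(lags))
        for ii, L in enumerate(lags):
            w = (L - np.arange(L)).astype(float)
            w[0] = L
            msd[ii] = dt_s**2 * (2.0 * np.sum(w[1:] * a[1:L]) + L * a[0])
        t = lags * dt_s
        i0 = max(1, int(fit_window[0] * len(lags)))
        i1 = max(i0 + 2, int(fit_window[1] * len(lags)))
        slope = np.polyfit(t[i0:i1], msd[i0:i1], 1)[0]
        etas.append(V / (2.0 * kbt) * slope * units.VISCOSITY_MPAS)
    etas = np.array(etas)
    eta = float(etas.mean())
    err = float(etas.std(ddof=1) / math.sqrt(len(etas)))
    return eta, err
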