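"""The coarse-grained water model family.

Seven model structures are supported.  Each coarse-grained (CG) entity
represents ``M`` water molecules (the mapping) and carries one, two or three
interaction sites:

``1S``
    a single chargeless Lennard-Jones bead; parameters (sigma, epsilon).
``2S``
    two oppositely charged sites (+q / -q) at a constrained distance r0; the
    negative site also carries the LJ interaction; (sigma, epsilon, q, r0).
``3S``
    a "big water molecule": central site with charge -q (and LJ), two outer
    sites with +q/2 each, rigid bonds r0 and rigid angle theta0;
    (sigma, epsilon, q, r0, theta0).
``3S*``
    central site chargeless (and LJ), outer sites carry +q and -q; same
    geometry and parameters as 3S.
``2SF``
    flexible 2S: harmonic bond k_b (r - r0)^2 instead of the constraint;
    (sigma, epsilon, q, r0, k_b).
``3SF`` / ``3SF*``
    flexible three-site models: bonds stay rigid, the angle is governed by a
    harmonic term k_a (theta - theta0)^2; (sigma, epsilon, q, r0, theta0, k_a).

Electrostatics are uniformly screened by a global dielectric constant
(default 2.5).  The mapping fixes the total mass of the entity
(M x 18.0153 u); in multi-site structures the central site carries twice the
mass of each outer site.

Internal units: nm, kJ/mol, u, e, ps, K (see :mod:`cgwater.units`); angles are
radians internally, degrees at config-file boundaries.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import units
from .priors import UniformBoxPrior

__all__ = [
    "SiteSpec",
    "CGModelSpec",
    "Configuration",
    "ForceField",
    "OverlapError",
    "STRUCTURE_LABELS",
    "build_model",
    "site_masses",
    "potential_energy",
    "forces",
    "default_priors",
    "DEFAULT_PRIOR_BOUNDS",
    "spec_to_json",
    "spec_from_json",
    "spec_from_yaml",
]

STRUCTURE_LABELS = ("1S", "2S", "3S", "3S*", "2SF", "3SF", "3SF*")

_ALIASES = {"3S*F": "3SF*", "3SF*": "3SF*", "3S*": "3S*"}

# Uniform prior bounds in internal units.  The error scale sigma_n is
# dimensionless.  Overridable per model via config.
DEFAULT_PRIOR_BOUNDS = {
    "sigma": (0.25, 0.80),          # nm
    "epsilon": (0.1, 6.0),          # kJ/mol
    "q": (0.1, 1.2),                # e
    "r0": (0.05, 0.35),             # nm
    "theta0": (60 * units.DEG, 180 * units.DEG),  # rad
    "k_b": (1.0e3, 1.0e5),          # kJ/mol/nm^2
    "k_a": (10.0, 1.0e3),           # kJ/mol/rad^2
    "sigma_n": (0.01, 1.0),
}


class OverlapError(ValueError):
    """Raised when two interacting sites (nearly) coincide and the overlap
    policy is 'error'."""


@dataclass(frozen=True)
class SiteSpec:
    """One interaction site of a CG entity.

    ``q_coeff`` is the linear coefficient of the charge in the model
    parameter q (site charge = q_coeff * q), so total charge neutrality is
    structural, independent of the value of q.
    """

    name: str
    mass: float           # u
    q_coeff: float        # dimensionless, charge = q_coeff * q [e]
    has_lj: bool


@dataclass
class CGModelSpec:
    """Full definition of one member of the CG water model family."""

    structure_label: str
    mapping_M: int
    sites: tuple
    rigid_constraints: tuple   # ((i, j, kind),) with kind in {"r0", "outer"}
    flexible_terms: tuple      # ("bond", i, j) or ("angle", c, i, k)
    parameter_names: tuple
    global_dielectric: float = 2.5

    def __post_init__(self):
        if not (1 <= len(self.sites) <= 3):
            raise ValueError("a CG entity has 1-3 sites")
        if abs(sum(s.q_coeff for s in self.sites)) > 1e-12:
            raise ValueError("total site charge must be exactly zero")
        if any(s.mass <= 0 for s in self.sites):
            raise ValueError("site masses must be positive")
        if sum(s.has_lj for s in self.sites) != 1:
            raise ValueError("exactly one site per entity carries LJ")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def lj_site(self) -> int:
        return next(i for i, s in enumerate(self.sites) if s.has_lj)

    @property
    def is_charged(self) -> bool:
        return any(s.q_coeff != 0 for s in self.sites)

    @property
    def is_flexible(self) -> bool:
        return len(self.flexible_terms) > 0

    @property
    def label(self) -> str:
        return f"{self.structure_label},{self.mapping_M}"

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.sites)

    def params(self, phi_c) -> dict:
        phi_c = np.asarray(phi_c, dtype=float)
        if phi_c.shape != (self.n_parameters,):
            raise ValueError(
                f"{self.label} expects {self.n_parameters} parameters "
                f"{self.parameter_names}, got shape {phi_c.shape}"
            )
        return dict(zip(self.parameter_names, phi_c))

    def charges(self, q: float) -> np.ndarray:
        return np.array([s.q_coeff * q for s in self.sites])

    def constraint_lengths(self, p: dict) -> list:
        """Resolve symbolic constraints to (i, j, distance) triples."""
        out = []
        for i, j, kind in self.rigid_constraints:
            if kind == "r0":
                d = p["r0"]
            elif kind == "outer":
                d = 2.0 * p["r0"] * math.sin(0.5 * p["theta0"])
            else:  # pragma: no cover
                raise ValueError(f"unknown constraint kind {kind!r}")
            out.append((i, j, d))
        return out

    def reference_geometry(self, p: dict) -> np.ndarray:
        """Site coordinates of one entity in its body frame, (n_sites, 3)."""
        n = self.n_sites
        if n == 1:
            return np.zeros((1, 3))
        r0 = p["r0"]
        if n == 2:
            return np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
        th = p["theta0"]
        # central site at origin, outer sites in the xy plane
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [r0, 0.0, 0.0],
                [r0 * math.cos(th), r0 * math.sin(th), 0.0],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "structure_label": self.structure_label,
            "mapping_M": self.mapping_M,
            "sites": [
                {
                    "name": s.name,
                    "mass": s.mass,
                    "q_coeff": s.q_coeff,
                    "has_lj": s.has_lj,
                }
                for s in self.sites
            ],
            "rigid_constraints": [list(c) for c in self.rigid_constraints],
            "flexible_terms": [list(t) for t in self.flexible_terms],
            "parameter_names": list(self.parameter_names),
            "global_dielectric": self.global_dielectric,
        }


@dataclass
class Configuration:
    """A set of site positions, grouped by entity, with an optional periodic
    box (orthorhombic, edge lengths in nm)."""

    positions: np.ndarray          # (n_sites_total, 3), entity-major
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive edge lengths")


def site_masses(structure_label: str, mapping_M: int) -> list:
    """Site masses (u) for a structure/mapping.

    The total mass is M times the molar mass of water; in 2- and 3-site
    structures the central (first) site carries twice the mass of each of
    the others.
    """
    label = _canonical(structure_label)
    if mapping_M < 1:
        raise ValueError("mapping M must be a positive integer")
    total = mapping_M * units.M_WATER
    n = 1 if label == "1S" else (2 if label in ("2S", "2SF") else 3)
    if n == 1:
        return [total]
    if n == 2:
        return [2 * total / 3, total / 3]
    return [total / 2, total / 4, total / 4]


def _canonical(structure_label: str) -> str:
    label = _ALIASES.get(structure_label, structure_label)
    if label not in STRUCTURE_LABELS:
        raise ValueError(
            f"unknown structure label {structure_label!r}; "
            f"expected one of {STRUCTURE_LABELS}"
        )
    return label


def build_model(
    structure_label: str,
    mapping_M: int,
    global_dielectric: float = 2.5,
) -> CGModelSpec:
    """Construct a fully populated :class:`CGModelSpec`.

    The 1S structure is meaningful down to M = 1; charged structures are
    accepted for mappings up to 12.
    """
    label = _canonical(structure_label)
    if not isinstance(mapping_M, (int, np.integer)) or mapping_M < 1:
        raise ValueError("mapping M must be a positive integer")
    if mapping_M > 12:
        raise ValueError("mappings above 12 are not part of the family")
    masses = site_masses(label, mapping_M)

    if label == "1S":
        sites = (SiteSpec("CG", masses[0], 0.0, True),)
        constraints = ()
        flexible = ()
        names = ("sigma", "epsilon")
    elif label == "2S":
        sites = (
            SiteSpec("N", masses[0], -1.0, True),   # negative, LJ-bearing
            SiteSpec("P", masses[1], +1.0, False),
        )
        constraints = ((0, 1, "r0"),)
        flexible = ()
        names = ("sigma", "epsilon", "q", "r0")
    elif label == "2SF":
        sites = (
            SiteSpec("N", masses[0], -1.0, True),
            SiteSpec("P", masses[1], +1.0, False),
        )
        constraints = ()
        flexible = (("bond", 0, 1),)
        names = ("sigma", "epsilon", "q", "r0", "k_b")
    elif label in ("3S", "3SF"):
        sites = (
            SiteSpec("C", masses[0], -1.0, True),   # central, negative, LJ
            SiteSpec("O1", masses[1], +0.5, False),
            SiteSpec("O2", masses[2], +0.5, False),
        )
        if label == "3S":
            constraints = ((0, 1, "r0"), (0, 2, "r0"), (1, 2, "outer"))
            flexible = ()
            names = ("sigma", "epsilon", "q", "r0", "theta0")
        else:
            constraints = ((0, 1, "r0"), (0, 2, "r0"))
            flexible = (("angle", 0, 1, 2),)
            names = ("sigma", "epsilon", "q", "r0", "theta0", "k_a")
    else:  # 3S* / 3SF*: central chargeless LJ site, outer +-q
        sites = (
            SiteSpec("C", masses[0], 0.0, True),
            SiteSpec("O1", masses[1], +1.0, False),
            SiteSpec("O2", masses[2], -1.0, False),
        )
        if label == "3S*":
            constraints = ((0, 1, "r0"), (0, 2, "r0"), (1, 2, "outer"))
            flexible = ()
            names = ("sigma", "epsilon", "q", "r0", "theta0")
        else:
            constraints = ((0, 1, "r0"), (0, 2, "r0"))
            flexible = (("angle", 0, 1, 2),)
            names = ("sigma", "epsilon", "q", "r0", "theta0", "k_a")

    return CGModelSpec(
        structure_label=label,
        mapping_M=int(mapping_M),
        sites=sites,
        rigid_constraints=constraints,
        flexible_terms=flexible,
        parameter_names=names,
        global_dielectric=global_dielectric,
    )


def default_priors(
    spec: CGModelSpec,
    overrides: Optional[dict] = None,
    include_sigma_n: bool = True,
) -> UniformBoxPrior:
    """Uniform box prior over the model parameters (plus sigma_n).

    Bounds come from :data:`DEFAULT_PRIOR_BOUNDS`; ``overrides`` maps
    parameter name -> (lo, hi).
    """
    bounds = dict(DEFAULT_PRIOR_BOUNDS)
    if overrides:
        bounds.update(overrides)
    names = list(spec.parameter_names) + (["sigma_n"] if include_sigma_n else [])
    lower = [bounds[n][0] for n in names]
    upper = [bounds[n][1] for n in names]
    return UniformBoxPrior(tuple(names), lower, upper)


# ---------------------------------------------------------------------------
# Potential energy, forces and virial
# ---------------------------------------------------------------------------


class ForceField:
    """Evaluates energy, forces and the virial tensor for N entities of one
    model.

    Periodic systems use minimum-image distances, a 1.2 nm cutoff with LJ
    energy shift and reaction-field electrostatics (eps_RF = infinity) with
    the global screening constant inside the cutoff.  Non-periodic
    configurations use untruncated LJ and bare screened Coulomb — this is
    the convention for isolated clusters and dimer checks.

    ``overlap`` policy: 'cap' clamps pair distances below ``cap_radius``
    (finite, very large energies); 'error' raises :class:`OverlapError`.
    """

    def __init__(
        self,
        spec: CGModelSpec,
        phi_c,
        n_entities: int,
        rcut: float = 1.2,
        overlap: str = "cap",
        cap_radius: float = 0.05,
    ):
        self.spec = spec
        self.p = spec.params(phi_c)
        self.n_entities = int(n_entities)
        self.rcut = float(rcut)
        self.overlap = overlap
        self.cap_radius = float(cap_radius)
        ns = spec.n_sites
        self.n_sites_total = self.n_entities * ns

        ent = np.repeat(np.arange(self.n_entities), ns)
        self.entity_of = ent

        # LJ pair list: one LJ site per entity
        lj_flat = np.arange(self.n_entities) * ns + spec.lj_site
        ii, jj = np.triu_indices(self.n_entities, k=1)
        self.lj_i = lj_flat[ii]
        self.lj_j = lj_flat[jj]

        # Coulomb pair list: all charged-site pairs across entities
        q = self.p.get("q", 0.0)
        charges = spec.charges(q) if spec.is_charged else np.zeros(ns)
        self.site_charges = np.tile(charges, self.n_entities)
        ch_local = np.nonzero(charges != 0.0)[0]
        if len(ch_local) and q != 0.0:
            ch_flat = (
                np.arange(self.n_entities)[:, None] * ns + ch_local[None, :]
            ).ravel()
            a, b = np.triu_indices(len(ch_flat), k=1)
            ci, cj = ch_flat[a], ch_flat[b]
            keep = ent[ci] != ent[cj]
            self.coul_i = ci[keep]
            self.coul_j = cj[keep]
            self.qq = self.site_charges[self.coul_i] * self.site_charges[self.coul_j]
        else:
            self.coul_i = self.coul_j = np.empty(0, dtype=int)
            self.qq = np.empty(0)

        self.masses = np.tile([s.mass for s in spec.sites], self.n_entities)

    # -- helpers ----------------------------------------------------------

    def _pair_vectors(self, pos, i, j, box):
        dr = pos[i] - pos[j]
        if box is not None:
            dr -= box * np.rint(dr / box)
        r2 = np.einsum("ij,ij->i", dr, dr)
        if self.overlap == "error":
            if np.any(r2 < self.cap_radius**2):
                raise OverlapError("overlapping interaction sites")
        else:
            r2 = np.maximum(r2, self.cap_radius**2)
        return dr, r2

    def evaluate(self, positions, box=None, want_forces=True):
        """Return (energy, forces, virial).

        ``positions``: (n_sites_total, 3).  Virial W_ab = sum f_a r_b over
        interactions (pairwise plus intra-entity terms in relative
        coordinates); the pressure tensor is (K2 + W)/V with K2 the doubled
        kinetic tensor.
        """
        pos = np.asarray(positions, dtype=float)
        E = 0.0
        F = np.zeros_like(pos)
        W = np.zeros((3, 3))
        p = self.p
        periodic = box is not None

        # Lennard-Jones
        if len(self.lj_i):
            dr, r2 = self._pair_vectors(pos, self.lj_i, self.lj_j, box)
            sig2, eps = p["sigma"] ** 2, p["epsilon"]
            if periodic:
                mask = r2 < self.rcut**2
                dr, r2 = dr[mask], r2[mask]
                src6 = (sig2 / self.rcut**2) ** 3
                e_shift = 4 * eps * (src6 * src6 - src6)
            else:
                e_shift = 0.0
            if len(r2):
                sr6 = (sig2 / r2) ** 3
                E += float(np.sum(4 * eps * (sr6 * sr6 - sr6) - e_shift))
                if want_forces:
                    fs = (24 * eps * (2 * sr6 * sr6 - sr6) / r2)[:, None]
                    fv = fs * dr
                    np.add.at(F, self.lj_i[mask] if periodic else self.lj_i, fv)
                    np.add.at(F, self.lj_j[mask] if periodic else self.lj_j, -fv)
                    W += fv.T @ dr

        # Electrostatics
        if len(self.coul_i):
            dr, r2 = self._pair_vectors(pos, self.coul_i, self.coul_j, box)
            pref = units.F_COULOMB / self.spec.global_dielectric
            if periodic:
                mask = r2 < self.rcut**2
                dr, r2 = dr[mask], r2[mask]
                qq = self.qq[mask]
                r = np.sqrt(r2)
                rc = self.rcut
                # reaction field with eps_RF -> infinity, shifted to 0 at rc
                E += float(
                    np.sum(pref * qq * (1 / r + r2 / (2 * rc**3) - 3 / (2 * rc)))
                )
                if want_forces:
                    fs = (pref * qq * (1 / (r2 * r) - 1 / rc**3))[:, None]
                    fv = fs * dr
                    np.add.at(F, self.coul_i[mask], fv)
                    np.add.at(F, self.coul_j[mask], -fv)
                    W += fv.T @ dr
            else:
                r = np.sqrt(r2)
                E += float(np.sum(pref * self.qq / r))
                if want_forces:
                    fs = (pref * self.qq / (r2 * r))[:, None]
                    fv = fs * dr
                    np.add.at(F, self.coul_i, fv)
                    np.add.at(F, self.coul_j, -fv)
                    W += fv.T @ dr

        # Intra-entity flexible terms (entities are stored whole/unwrapped,
        # so no minimum image is applied inside an entity)
        ns = self.spec.n_sites
        ent_pos = pos.reshape(self.n_entities, ns, 3)
        for term in self.spec.flexible_terms:
            if term[0] == "bond":
                _, a, b = term
                kb, r0 = p["k_b"], p["r0"]
                d = ent_pos[:, a] - ent_pos[:, b]
                r = np.linalg.norm(d, axis=1)
                E += float(np.sum(kb * (r - r0) ** 2))
                if want_forces:
                    fs = (-2 * kb * (r - r0) / np.maximum(r, 1e-12))[:, None]
                    fv = fs * d
                    Fe = F.reshape(self.n_entities, ns, 3)
                    Fe[:, a] += fv
                    Fe[:, b] -= fv
                    W += fv.T @ d
            elif term[0] == "angle":
                _, c, a, b = term
                ka, th0 = p["k_a"], p["theta0"]
                u = ent_pos[:, a] - ent_pos[:, c]
                v = ent_pos[:, b] - ent_pos[:, c]
                nu = np.linalg.norm(u, axis=1)
                nv = np.linalg.norm(v, axis=1)
                costh = np.clip(
                    np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0
                )
                th = np.arccos(costh)
                E += float(np.sum(ka * (th - th0) ** 2))
                if want_forces:
                    sinth = np.maximum(np.sqrt(1 - costh**2), 1e-8)
                    dEdth = 2 * ka * (th - th0)
                    uh = u / nu[:, None]
                    vh = v / nv[:, None]
                    dth_da = (costh[:, None] * uh - vh) / (nu * sinth)[:, None]
                    dth_db = (costh[:, None] * vh - uh) / (nv * sinth)[:, None]
                    fa = -dEdth[:, None] * dth_da
                    fb = -dEdth[:, None] * dth_db
                    Fe = F.reshape(self.n_entities, ns, 3)
                    Fe[:, a] += fa
                    Fe[:, b] += fb
                    Fe[:, c] -= fa + fb
                    W += fa.T @ u + fb.T @ v

        return E, F, W


def _ff_for_config(spec, phi_c, config, **kw) -> ForceField:
    n_tot = len(config.positions)
    if n_tot % spec.n_sites:
        raise ValueError(
            f"{n_tot} positions is not a multiple of {spec.n_sites} sites"
        )
    return ForceField(spec, phi_c, n_tot // spec.n_sites, **kw)


def potential_energy(
    spec: CGModelSpec, phi_c, config: Configuration, **kw
) -> float:
    """Total potential energy (kJ/mol) of a configuration.

    Keyword arguments are forwarded to :class:`ForceField` (``rcut``,
    ``overlap``, ``cap_radius``).
    """
    if len(config.positions) == 0:
        raise ValueError("empty configuration")
    ff = _ff_for_config(spec, phi_c, config, **kw)
    E, _, _ = ff.evaluate(config.positions, config.box, want_forces=False)
    return E


def forces(spec: CGModelSpec, phi_c, config: Configuration, **kw):
    """(energy, forces) of a configuration; forces in kJ/mol/nm."""
    ff = _ff_for_config(spec, phi_c, config, **kw)
    E, F, _ = ff.evaluate(config.positions, config.box)
    return E, F


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def spec_to_json(spec: CGModelSpec) -> str:
    """JSON export of a built spec, for provenance records."""
    return json.dumps(spec.to_dict(), indent=2, sort_keys=True)


def spec_from_json(text: str) -> CGModelSpec:
    d = json.loads(text)
    return CGModelSpec(
        structure_label=d["structure_label"],
        mapping_M=d["mapping_M"],
        sites=tuple(SiteSpec(**s) for s in d["sites"]),
        rigid_constraints=tuple(tuple(c) for c in d["rigid_constraints"]),
        flexible_terms=tuple(tuple(t) for t in d["flexible_terms"]),
        parameter_names=tuple(d["parameter_names"]),
        global_dielectric=d["global_dielectric"],
    )


def spec_from_yaml(text: str):
    """Build (spec, prior) from a YAML model definition.

    Schema::

        structure: 3S*
        mapping: 4
        global_dielectric: 2.5      # optional
        priors:                      # optional overrides, internal units
          sigma: [0.3, 0.6]
    """
    import yaml

    cfg = yaml.safe_load(text)
    spec = build_model(
        cfg["structure"],
        int(cfg["mapping"]),
        global_dielectric=float(cfg.get("global_dielectric", 2.5)),
    )
    overrides = {
        k: tuple(v) for k, v in (cfg.get("priors") or {}).items()
    }
    prior = default_priors(spec, overrides=overrides)
    return spec, prior
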