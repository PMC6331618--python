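"""Velocity-Verlet MD with rigid constraints, Langevin thermostat and a
Monte-Carlo barostat.

The engine propagates N identical CG entities (1-3 sites each) in an
orthorhombic periodic box.  Integration is velocity Verlet; rigid bonds and
rigid triangles are enforced with an iterative Lagrange-multiplier solver
(SHAKE for positions, RATTLE for velocities).  NVT adds an
Ornstein-Uhlenbeck velocity refresh after each Verlet step (friction gamma,
default 2/ps), followed by re-projection onto the constraint manifold.  NPT
adds isotropic Monte-Carlo volume moves that rescale entity centers of
mass, leaving internal geometry intact.

Desk-scale fidelity note: default system sizes (125-512 entities) and run
lengths are far below production studies of CG water; trajectories carry a
``fidelity`` flag in their metadata saying so.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .. import units
from ..model_zoo import CGModelSpec, ForceField

__all__ = ["Trajectory", "Simulation", "run_md", "default_max_dt"]


def default_max_dt(spec: CGModelSpec) -> float:
    """Recommended maximal timestep (ps) per model structure and mapping.

    Rigid structures tolerate 8-20 fs, growing with the mapping (softer
    interactions); flexible structures are limited by the stiff harmonic
    terms to ~2 fs.
    """
    if spec.is_flexible:
        return 0.002
    dt = 0.008 + 0.003 * max(0, spec.mapping_M - 3)
    return min(dt, 0.020)


@dataclass
class Trajectory:
    """Scalar time series plus final state of one MD run."""

    spec_label: str
    ensemble: str
    temperature: float
    dt: float
    seed: int
    n_entities: int
    sample_every: int
    times: np.ndarray
    potential: np.ndarray
    kinetic: np.ndarray
    volume: np.ndarray
    pressure_tensor: np.ndarray       # (n_frames, 3, 3), kJ/mol/nm^3
    dipole: np.ndarray                # (n_frames, 3), e*nm
    box_series: np.ndarray            # (n_frames, 3)
    final_positions: np.ndarray
    final_velocities: np.ndarray
    final_box: np.ndarray
    pressure: Optional[float] = None  # target, bar (NPT)
    metadata: dict = field(default_factory=dict)
    frames: Optional[list] = None     # stored positions (optional)

    def __post_init__(self):
        if len(self.times) < 1:
            raise ValueError("a trajectory holds at least one frame")
        if np.any(self.volume <= 0):
            raise ValueError("volumes must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    @property
    def instantaneous_temperature(self) -> np.ndarray:
        g = self.metadata["dof"]
        return 2.0 * self.kinetic / (g * units.KB)

    def to_xyz(self) -> str:
        """Extended-XYZ dump of the stored frames (or the final state)."""
        frames = self.frames or [self.final_positions]
        out = []
        for k, pos in enumerate(frames):
            out.append(str(len(pos)))
            bx = self.final_box
            out.append(
                f'Lattice="{bx[0]} 0 0 0 {bx[1]} 0 0 0 {bx[2]}" '
                f"Properties=species:S:1:pos:R:3 frame={k}"
            )
            for p in pos:
                out.append(f"CG {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
        return "\n".join(out) + "\n"


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


class Simulation:
    """Mutable MD state for one model at one state point."""

    SHAKE_TOL = 1e-10
    SHAKE_MAX_ITER = 100

    def __init__(
        self,
        spec: CGModelSpec,
        phi_c,
        n_entities: int,
        temperature: float,
        box=None,
        density: float = 0.95,
        slab: bool = False,
        seed: int = 0,
        rcut: float = 1.2,
        friction: float = 2.0,
        overlap: str = "cap",
        initial_state=None,
    ):
        if n_entities < 2:
            raise ValueError("need at least two entities")
        self.spec = spec
        self.p = spec.params(phi_c)
        self.n_ent = int(n_entities)
        self.ns = spec.n_sites
        self.T = float(temperature)
        self.friction = float(friction)
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.ff = ForceField(spec, phi_c, self.n_ent, rcut=rcut, overlap=overlap)
        self.masses = self.ff.masses
        self.constraints = spec.constraint_lengths(self.p)
        self.n_constraints = len(self.constraints) * self.n_ent
        self.slab = bool(slab)

        if initial_state is not None:
            pos, vel, bx = initial_state
            self.pos = np.array(pos, dtype=float)
            self.vel = np.array(vel, dtype=float)
            self.box = np.array(bx, dtype=float)
        else:
            self.box = self._initial_box(box, density, slab)
            self.pos = self._initial_positions()
            self.vel = self._initial_velocities()
        self.E, self.F, self.W = self.ff.evaluate(self.pos, self.box)
        self._w_constraint = np.zeros((3, 3))

    # -- setup ------------------------------------------------------------

    def _initial_box(self, box, density, slab):
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.ndim == 0:
                box = np.repeat(float(box), 3)
            return box.copy()
        m_tot = self.n_ent * self.spec.total_mass
        V = m_tot * units.DENSITY_G_CM3 / density
        L = V ** (1.0 / 3.0)
        if slab:
            return np.array([L, L, 3.0 * L])
        return np.array([L, L, L])

    def _initial_positions(self):
        n_side = math.ceil(self.n_ent ** (1.0 / 3.0))
        # entities fill a cubic sub-lattice of the (possibly elongated) box
        lx, ly, lz = self.box
        lat_z = min(lz, lx)  # slab: liquid film occupies the central cube
        idx = np.arange(n_side)
        grid = np.stack(
            np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1
        ).reshape(-1, 3)[: self.n_ent]
        frac = (grid + 0.5) / n_side
        centers = frac * np.array([lx, ly, lat_z])
        if self.slab:
            centers[:, 2] += 0.5 * (lz - lat_z)
        ref = self.spec.reference_geometry(self.p)
        m = np.array([s.mass for s in self.spec.sites])
        ref = ref - (m[:, None] * ref).sum(axis=0) / m.sum()
        R = _random_rotations(self.n_ent, self.rng)
        sites = centers[:, None, :] + np.einsum("nij,sj->nsi", R, ref)
        return sites.reshape(-1, 3)

    def _initial_velocities(self):
        sd = np.sqrt(units.KB * self.T / self.masses)
        v = self.rng.standard_normal((len(self.masses), 3)) * sd[:, None]
        p_tot = (self.masses[:, None] * v).sum(axis=0)
        v -= p_tot / self.masses.sum()
        if self.constraints:
            v = self._rattle(self.pos, v)
        return v

    # -- constraints ------------------------------------------------------

    def _shake(self, pos_new, pos_ref, dt):
        """Iteratively restore rigid distances; returns corrected positions.

        Accumulates the Lagrange multipliers into the constraint virial
        (constraint force on site a is -2 g r_ref / dt^2).
        """
        ns = self.ns
        P = pos_new.reshape(self.n_ent, ns, 3)
        Pr = pos_ref.reshape(self.n_ent, ns, 3)
        m = np.array([s.mass for s in self.spec.sites])
        g_acc = [np.zeros(self.n_ent) for _ in self.constraints]
        for _ in range(self.SHAKE_MAX_ITER):
            max_dev = 0.0
            for k, (a, b, d) in enumerate(self.constraints):
                r = P[:, a] - P[:, b]
                r2 = np.einsum("ij,ij->i", r, r)
                diff = r2 - d * d
                dev = np.max(np.abs(diff)) / (d * d)
                max_dev = max(max_dev, dev)
                if dev <= self.SHAKE_TOL:
                    continue
                rr = Pr[:, a] - Pr[:, b]
                denom = 2.0 * (1.0 / m[a] + 1.0 / m[b]) * np.einsum(
                    "ij,ij->i", r, rr
                )
                g = diff / denom
                P[:, a] -= (g / m[a])[:, None] * rr
                P[:, b] += (g / m[b])[:, None] * rr
                g_acc[k] += g
            if max_dev <= self.SHAKE_TOL:
                break
        else:
            raise RuntimeError(
                "constraint solver did not converge within "
                f"{self.SHAKE_MAX_ITER} iterations (max deviation {max_dev:.2e})"
            )
        w = np.zeros((3, 3))
        for k, (a, b, d) in enumerate(self.constraints):
            rr = Pr[:, a] - Pr[:, b]
            w -= (2.0 / dt**2) * np.einsum("n,ni,nj->ij", g_acc[k], rr, rr)
        self._w_constraint = w
        return P.reshape(-1, 3)

    def _rattle(self, pos, vel):
        """Project velocities onto the constraint manifold."""
        ns = self.ns
        P = pos.reshape(self.n_ent, ns, 3)
        V = vel.reshape(self.n_ent, ns, 3).copy()
        m = np.array([s.mass for s in self.spec.sites])
        for _ in range(self.SHAKE_MAX_ITER):
            max_dev = 0.0
            for a, b, d in self.constraints:
                r = P[:, a] - P[:, b]
                dv = V[:, a] - V[:, b]
                rv = np.einsum("ij,ij->i", r, dv)
                dev = np.max(np.abs(rv)) / (d * d)
                max_dev = max(max_dev, dev)
                if dev <= self.SHAKE_TOL:
                    continue
                k = rv / ((1.0 / m[a] + 1.0 / m[b]) * np.einsum("ij,ij->i", r, r))
                V[:, a] -= (k / m[a])[:, None] * r
                V[:, b] += (k / m[b])[:, None] * r
            if max_dev <= self.SHAKE_TOL:
                break
        return V.reshape(-1, 3)

    # -- dynamics ---------------------------------------------------------

    def verlet_step(self, dt: float):
        m = self.masses[:, None]
        self.vel += 0.5 * dt * self.F / m
        pos_ref = self.pos
        pos_new = self.pos + dt * self.vel
        if self.constraints:
            corrected = self._shake(pos_new, pos_ref, dt)
            self.vel += (corrected - pos_new) / dt
            pos_new = corrected
        else:
            self._w_constraint = np.zeros((3, 3))
        self.pos = pos_new
        self.E, self.F, self.W = self.ff.evaluate(self.pos, self.box)
        if not (np.isfinite(self.E) and np.isfinite(self.kinetic_energy())):
            raise RuntimeError(
                "energy blow-up detected (non-finite energy); "
                "reduce the timestep or check parameters"
            )
        self.vel += 0.5 * dt * self.F / m
        if self.constraints:
            self.vel = self._rattle(self.pos, self.vel)

    def ou_step(self, dt: float):
        c1 = math.exp(-self.friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * units.KB * self.T / self.masses)
        self.vel = c1 * self.vel + c2[:, None] * self.rng.standard_normal(
            self.vel.shape
        )
        if self.constraints:
            self.vel = self._rattle(self.pos, self.vel)

    def barostat_move(self, pressure_internal: float, dlnv_max: float = 0.04):
        """Isotropic MC volume move scaling entity centers of mass."""
        V = float(np.prod(self.box))
        dlnv = self.rng.uniform(-dlnv_max, dlnv_max)
        V_new = V * math.exp(dlnv)
        s = (V_new / V) ** (1.0 / 3.0)
        P = self.pos.reshape(self.n_ent, self.ns, 3)
        m = np.array([s_.mass for s_ in self.spec.sites])
        com = (m[None, :, None] * P).sum(axis=1) / m.sum()
        pos_new = (P + (s - 1.0) * com[:, None, :]).reshape(-1, 3)
        box_new = self.box * s
        e_new, _, _ = self.ff.evaluate(pos_new, box_new, want_forces=False)
        beta = 1.0 / (units.KB * self.T)
        log_acc = (
            -beta * (e_new - self.E)
            - beta * pressure_internal * (V_new - V)
            + (self.n_ent + 1) * dlnv
        )
        if math.log(self.rng.uniform()) < log_acc:
            self.pos = pos_new
            self.box = box_new
            self.E, self.F, self.W = self.ff.evaluate(self.pos, self.box)
            return True
        return False

    # -- bookkeeping ------------------------------------------------------

    @property
    def dof(self) -> int:
        return 3 * len(self.masses) - self.n_constraints

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.vel**2))

    def kinetic_tensor(self) -> np.ndarray:
        mv = self.masses[:, None] * self.vel
        return mv.T @ self.vel

    def pressure_tensor(self) -> np.ndarray:
        V = float(np.prod(self.box))
        return (self.kinetic_tensor() + self.W + self._w_constraint) / V

    def dipole(self) -> np.ndarray:
        return self.ff.site_charges @ self.pos

    def momentum(self) -> np.ndarray:
        return (self.masses[:, None] * self.vel).sum(axis=0)


def run_md(
    spec: CGModelSpec,
    phi_c,
    ensemble: str,
    temperature: float,
    pressure: float = 1.0,
    n_entities: int = 125,
    steps: int = 2000,
    dt: Optional[float] = None,
    seed: int = 0,
    sample_every: int = 5,
    box=None,
    density: float = 0.95,
    slab: bool = False,
    friction: float = 2.0,
    barostat_every: int = 20,
    rcut: float = 1.2,
    initial_state=None,
    traj_every: int = 0,
    remove_com_momentum: Optional[bool] = None,
) -> Trajectory:
    """Run one MD trajectory and record scalar time series.

    ``ensemble`` is NVE, NVT or NPT; ``pressure`` is in bar (NPT only);
    ``dt`` defaults to the model's recommended maximum.  The same seed on
    the same build reproduces the trajectory bit-identically.
    """
    ensemble = ensemble.upper()
    if ensemble not in ("NVE", "NVT", "NPT"):
        raise ValueError(f"unknown ensemble {ensemble!r}")
    if dt is None:
        dt = default_max_dt(spec)
    max_dt = default_max_dt(spec)
    if dt > max_dt * 1.5:
        raise ValueError(
            f"dt={dt} ps exceeds the recommended maximum {max_dt} ps "
            f"for {spec.label}"
        )
    sim = Simulation(
        spec, phi_c, n_entities, temperature,
        box=box, density=density, slab=slab, seed=seed,
        rcut=rcut, friction=friction, initial_state=initial_state,
    )
    if remove_com_momentum is None:
        remove_com_momentum = ensemble == "NVE"
    if remove_com_momentum and initial_state is not None:
        p_tot = sim.momentum()
        sim.vel -= p_tot / sim.masses.sum()

    p_int = pressure / units.PRESSURE_BAR

    times, pot, kin, vol, ptens, dip, boxes = [], [], [], [], [], [], []
    frames = [] if traj_every else None
    n_baro_try = n_baro_acc = 0

    for step in range(steps):
        sim.verlet_step(dt)
        if ensemble in ("NVT", "NPT"):
            sim.ou_step(dt)
        if ensemble == "NPT" and (step + 1) % barostat_every == 0:
            n_baro_try += 1
            n_baro_acc += sim.barostat_move(p_int)
        if (step + 1) % sample_every == 0:
            times.append((step + 1) * dt)
            pot.append(sim.E)
            kin.append(sim.kinetic_energy())
            vol.append(float(np.prod(sim.box)))
            ptens.append(sim.pressure_tensor())
            dip.append(sim.dipole())
            boxes.append(sim.box.copy())
            if traj_every and (step + 1) % traj_every == 0:
                frames.append(sim.pos.copy())

    dof = sim.dof - (3 if ensemble == "NVE" else 0)
    meta = {
        "dof": dof,
        "friction": friction if ensemble != "NVE" else None,
        "barostat_acceptance": (n_baro_acc / n_baro_try) if n_baro_try else None,
        "slab": slab,
        "rcut": rcut,
        "fidelity": "desk-scale (far below production system size/length)",
        "n_constraints": sim.n_constraints,
    }
    return Trajectory(
        spec_label=spec.label,
        ensemble=ensemble,
        temperature=temperature,
        dt=dt,
        seed=seed,
        n_entities=n_entities,
        sample_every=sample_every,
        times=np.array(times),
        potential=np.array(pot),
        kinetic=np.array(kin),
        volume=np.array(vol),
        pressure_tensor=np.array(ptens),
        dipole=np.array(dip),
        box_series=np.array(boxes),
        final_positions=sim.pos.copy(),
        final_velocities=sim.vel.copy(),
        final_box=sim.box.copy(),
        pressure=pressure if ensemble == "NPT" else None,
        metadata=meta,
        frames=frames,
    )
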