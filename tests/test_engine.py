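"""MD engine: integrator, constraints, thermostat/barostat, estimators."""

import numpy as np
import pytest

from cgwater import units
from cgwater.engine import (
    MDForward,
    ObservableVector,
    Trajectory,
    estimate_static_qoi,
    estimate_viscosity,
    forward_model,
    run_md,
    surface_tension_with_error,
)
from cgwater.model_zoo import ForceField, build_model

TINY_BUDGET = {
    "n_entities": 64,
    "npt_steps": 600,
    "nvt_steps": 900,
    "slab_steps": 600,
}


class TestIntegration:
    def test_same_seed_reproduces_trajectory_bit_identically(self, lj_spec):
        kw = dict(n_entities=64, steps=200, dt=0.004, seed=9, density=0.85)
        a = run_md(lj_spec, (0.3, 1.2), "NVT", 120.0, **kw)
        b = run_md(lj_spec, (0.3, 1.2), "NVT", 120.0, **kw)
        assert np.array_equal(a.potential, b.potential)
        assert np.array_equal(a.final_positions, b.final_positions)

    def test_nve_conserves_momentum(self, lj_spec, lj_equilibrated):
        pos, vel, box = lj_equilibrated
        traj = run_md(
            lj_spec, (0.3, 1.2), "NVE", 120.0, n_entities=125, steps=500,
            dt=0.004, seed=1, box=box, initial_state=(pos, vel, box),
        )
        p = (traj.final_velocities * lj_spec.total_mass).sum(axis=0)
        # u nm/ps per site; thermal scale is ~1e2
        assert np.abs(p).max() < 1e-8

    def test_thermostat_holds_target_temperature(self, lj_nvt_production):
        t_inst = lj_nvt_production.instantaneous_temperature
        mean_t = t_inst[len(t_inst) // 4:].mean()
        assert abs(mean_t - 120.0) / 120.0 < 0.02

    @pytest.mark.parametrize("label,phi", [
        ("2S", (0.45, 2.0, 0.5, 0.2)),
        ("3S", (0.45, 2.0, 0.6, 0.18, 1.9)),
        ("3SF", (0.45, 2.0, 0.6, 0.18, 1.9, 200.0)),
    ])
    def test_rigid_constraints_hold_to_1e8(self, label, phi):
        spec = build_model(label, 4)
        dt = 0.002 if spec.is_flexible else 0.004
        traj = run_md(
            spec, phi, "NVT", 300.0, n_entities=48, steps=300,
            dt=dt, seed=6, density=0.9,
        )
        pos = traj.final_positions.reshape(48, spec.n_sites, 3)
        for i, j, d in spec.constraint_lengths(spec.params(phi)):
            r = np.linalg.norm(pos[:, i] - pos[:, j], axis=1)
            assert np.abs(r - d).max() / d < 1e-8

    def test_timestep_guard_and_minimum_size(self, lj_spec):
        with pytest.raises(ValueError, match="exceeds"):
            run_md(lj_spec, (0.3, 1.2), "NVT", 120.0, steps=10, dt=0.1)
        with pytest.raises(ValueError, match="two entities"):
            run_md(lj_spec, (0.3, 1.2), "NVT", 120.0, n_entities=1, steps=10)

    def test_unknown_ensemble_rejected(self, lj_spec):
        with pytest.raises(ValueError, match="ensemble"):
            run_md(lj_spec, (0.3, 1.2), "NVA", 120.0, steps=10)

    def test_energy_blowup_detected(self, lj_spec):
        # a run whose state overflows must abort with a diagnostic, not
        # silently emit non-finite samples
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 2.0, (27, 3))
        vel = np.full((27, 3), 1e160)
        box = np.array([2.0, 2.0, 2.0])
        with pytest.raises(RuntimeError, match="blow-up"):
            run_md(
                lj_spec, (0.3, 1.0), "NVE", 120.0, n_entities=27,
                steps=50, dt=0.008, box=box, seed=0,
                initial_state=(pos, vel, box), remove_com_momentum=False,
            )

    def test_entity_relabeling_leaves_energy_invariant(self):
        spec = build_model("2S", 4)
        phi = (0.45, 2.0, 0.5, 0.2)
        rng = np.random.default_rng(0)
        n_ent = 16
        ff = ForceField(spec, phi, n_ent)
        ref = spec.reference_geometry(spec.params(phi))
        pos = np.vstack(
            [rng.uniform(0, 2.0, 3) + ref for _ in range(n_ent)]
        )
        box = np.array([2.0, 2.0, 2.0])
        e0, _, _ = ff.evaluate(pos, box)
        perm = rng.permutation(n_ent)
        pos_p = pos.reshape(n_ent, 2, 3)[perm].reshape(-1, 3)
        e1, _, _ = ff.evaluate(pos_p, box)
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_box_origin_shift_leaves_energy_invariant(self):
        spec = build_model("1S", 1)
        rng = np.random.default_rng(1)
        ff = ForceField(spec, (0.3, 1.0), 32)
        pos = rng.uniform(0, 2.0, (32, 3))
        box = np.array([2.0, 2.0, 2.0])
        e0, _, _ = ff.evaluate(pos, box)
        e1, _, _ = ff.evaluate(pos + np.array([0.71, -1.3, 4.2]), box)
        assert e1 == pytest.approx(e0, rel=1e-10)


class TestStaticEstimators:
    def test_ideal_gas_pressure_matches_equation_of_state(self, lj_spec):
        # epsilon = 0: no interactions; P V = N k_B T
        T, box = 298.0, np.array([5.0, 5.0, 5.0])
        traj = run_md(
            lj_spec, (0.3, 0.0), "NVT", T, n_entities=125, steps=3000,
            dt=0.008, seed=3, box=box, sample_every=5,
        )
        p_series = np.trace(traj.pressure_tensor, axis1=1, axis2=2) / 3
        n0 = traj.n_frames // 5
        p_mean = p_series[n0:].mean()
        blocks = np.array_split(p_series[n0:], 10)
        se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(10)
        expected = 125 / box.prod() * units.KB * T
        assert abs(p_mean - expected) < 3 * se

    def test_dielectric_is_exactly_one_without_charges(self):
        spec = build_model("2S", 4)
        traj = run_md(
            spec, (0.45, 2.0, 0.0, 0.2), "NPT", 300.0, n_entities=48,
            steps=500, dt=0.004, seed=8, density=0.9,
        )
        ov = estimate_static_qoi(traj, spec)
        assert ov.values["epsilon"] == 1.0

    def test_chargeless_structure_omits_dielectric(self, lj_spec):
        traj = run_md(
            lj_spec, (0.3, 1.2), "NPT", 120.0, n_entities=48, steps=500,
            dt=0.004, seed=9, density=0.85,
        )
        ov = estimate_static_qoi(traj, lj_spec)
        assert "epsilon" not in ov.values
        assert set(ov.values) == {"rho", "kappa"}

    def test_static_estimators_require_npt(self, lj_nvt_production, lj_spec):
        with pytest.raises(ValueError, match="NPT"):
            estimate_static_qoi(lj_nvt_production, lj_spec)

    def test_too_short_trajectory_rejected(self, lj_spec):
        traj = run_md(
            lj_spec, (0.3, 1.2), "NPT", 120.0, n_entities=27, steps=60,
            dt=0.004, seed=1, density=0.85, sample_every=5,
        )
        with pytest.raises(ValueError, match="block"):
            estimate_static_qoi(traj, lj_spec)


class TestSurfaceTensionAndViscosity:
    def test_homogeneous_bulk_has_zero_surface_tension(
        self, lj_nvt_production, lj_spec
    ):
        with pytest.warns(UserWarning, match="non-slab"):
            gamma, err = surface_tension_with_error(
                lj_nvt_production, lj_spec
            )
        assert abs(gamma) < 3 * err

    def test_slab_trajectory_does_not_warn(self, lj_spec):
        import warnings

        traj = run_md(
            lj_spec, (0.3, 1.2), "NVT", 110.0, n_entities=64, steps=400,
            dt=0.004, seed=12, density=0.85, slab=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            surface_tension_with_error(traj, lj_spec)

    def test_uncorrelated_pressure_noise_gives_negligible_viscosity(
        self, lj_spec
    ):
        rng = np.random.default_rng(0)
        n = 4000
        ptens = np.zeros((n, 3, 3))
        amp = 0.5
        for a, b in ((0, 1), (0, 2), (1, 2)):
            s = amp * rng.standard_normal(n)
            ptens[:, a, b] = s
            ptens[:, b, a] = s
        traj = Trajectory(
            spec_label="1S,1", ensemble="NVT", temperature=120.0, dt=0.004,
            seed=0, n_entities=125, sample_every=1,
            times=np.arange(n) * 0.004,
            potential=np.zeros(n), kinetic=np.zeros(n),
            volume=np.full(n, 6.0), pressure_tensor=ptens,
            dipole=np.zeros((n, 3)), box_series=np.full((n, 3), 6 ** (1 / 3)),
            final_positions=np.zeros((125, 3)),
            final_velocities=np.zeros((125, 3)),
            final_box=np.full(3, 6 ** (1 / 3)),
            metadata={"dof": 375, "slab": False},
        )
        eta, err, flagged = estimate_viscosity(traj, lj_spec)
        # scale of the lag-0 term alone
        lag0 = (
            6.0 / (units.KB * 120.0) * amp**2 * 0.004 * units.VISCOSITY_MPAS
        )
        assert not flagged
        assert abs(eta) < lag0


class TestForwardModel:
    def test_chargeless_model_yields_four_observables(self, lj_spec):
        ov = forward_model(
            build_model("1S", 4), (0.47, 3.0), 298.0,
            budget=TINY_BUDGET, seed=5,
        )
        assert ov.labels == ("rho", "gamma", "kappa", "eta")
        assert all(np.isfinite(v) for v in ov.values.values())

    def test_repeated_call_is_bit_identical(self):
        spec = build_model("1S", 4)
        a = forward_model(spec, (0.47, 3.0), 298.0, budget=TINY_BUDGET, seed=5)
        b = forward_model(spec, (0.47, 3.0), 298.0, budget=TINY_BUDGET, seed=5)
        assert a.values == b.values

    def test_surrogate_backend_bypasses_md_exactly(self):
        from cgwater.synthetic import SurrogateForward

        spec = build_model("3S*", 4)
        sur = SurrogateForward(spec)
        ov = forward_model(
            spec, sur.phi0, 298.0, backend="surrogate", surrogate=sur
        )
        np.testing.assert_allclose(
            ov.as_array(sur.labels), sur(sur.phi0, 298.0), rtol=1e-14
        )
        with pytest.raises(ValueError, match="surrogate"):
            forward_model(spec, sur.phi0, 298.0, backend="surrogate")

    def test_md_forward_adapter_batches_rows(self):
        fwd = MDForward(build_model("1S", 4), budget=TINY_BUDGET, seed=3)
        out = fwd(np.array([[0.47, 3.0], [0.5, 2.0]]), 298.0)
        assert out.shape == (2, 4)
        assert np.all(np.isfinite(out))

    def test_observable_vector_validation(self):
        with pytest.raises(ValueError, match="non-finite"):
            ObservableVector(values={"rho": np.nan})
        with pytest.raises(ValueError, match="positive"):
            ObservableVector(values={"rho": -1.0})
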