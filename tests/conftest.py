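import numpy as np
import pytest

from cgwater.engine import run_md
from cgwater.model_zoo import build_model

# A moderately dense single-site Lennard-Jones liquid state used by several
# engine tests: phi = (sigma, epsilon) in nm / kJ/mol at 120 K.
LJ_PHI = (0.30, 1.2)
LJ_TEMPERATURE = 120.0


@pytest.fixture(scope="session")
def lj_spec():
    return build_model("1S", 1)


@pytest.fixture(scope="session")
def lj_equilibrated(lj_spec):
    """An equilibrated LJ liquid: (positions, velocities, box)."""
    traj = run_md(
        lj_spec, LJ_PHI, "NVT", LJ_TEMPERATURE,
        n_entities=125, steps=1200, dt=0.004, seed=101, density=0.85,
    )
    return traj.final_positions, traj.final_velocities, traj.final_box


@pytest.fixture(scope="session")
def lj_nvt_production(lj_spec, lj_equilibrated):
    """A longer NVT run from the equilibrated state, sampled every step
    (shared by the viscosity and bulk-surface-tension tests)."""
    pos, vel, box = lj_equilibrated
    return run_md(
        lj_spec, LJ_PHI, "NVT", LJ_TEMPERATURE,
        n_entities=125, steps=12000, dt=0.004, seed=102,
        box=box, initial_state=(pos, vel, box), sample_every=1,
    )
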