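import numpy as np
import pytest

import azipart as az

AMPHIPHILE_PARAMS = {"well_depth": 45.0, "well_position": 1.0, "barrier_height": 10.0}


@pytest.fixture(scope="session")
def amphiphile():
    """The standard deep double-well membrane profile (D=45, B=10, z_well=1)."""
    return az.make_model_potential("amphiphile", AMPHIPHILE_PARAMS)


@pytest.fixture(scope="session")
def shallow_well():
    """A shallow double well an unbiased walker can equilibrate on."""
    return az.make_model_potential(
        "amphiphile",
        {"well_depth": 3.0, "well_position": 1.0, "barrier_height": 1.0},
    )


@pytest.fixture(scope="session")
def converged_run(amphiphile):
    """One biased run taken through the full extension protocol (seed 1)."""
    run = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=1)
    bias, report, n_ext = az.extend_until_converged(run)
    return {"run": run, "bias": bias, "report": report, "n_extensions": n_ext}


@pytest.fixture(scope="session")
def oriented_traj(converged_run):
    """Converged-run trajectory with the default z-coupled orientation."""
    traj = converged_run["run"].trajectory()
    return az.attach_orientation(
        traj, az.SoluteGeometry(), {"strength": 4.0}, seed=11
    )


@pytest.fixture()
def grid_z():
    return np.linspace(-6.0, 6.0, 601)
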