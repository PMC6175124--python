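import numpy as np
import pytest

from spinline import (
    BrownianModelParams,
    SpinParameters,
    generate_trajectory,
)


@pytest.fixture(scope="session")
def default_spin():
    """Spin parameters with a field window wide enough for the rigid pattern."""
    return SpinParameters(field_range=(3300.0, 3500.0), n_field_points=512)


@pytest.fixture(scope="session")
def isotropic_traj():
    """Free isotropic diffusion, D = 0.1 rad^2/ns (tau_2 = 1.67 ns)."""
    params = BrownianModelParams(
        D_parallel=0.1, D_perp=0.1, lambda_order=0.0,
        dt_internal=1.0, n_frames=20000, n_probes=6, seed=101,
    )
    return generate_trajectory(params)


@pytest.fixture(scope="session")
def ordered_fast_traj():
    """Fast motion (tau ~ 28 ps) in a lambda=2 ordering potential."""
    params = BrownianModelParams(
        D_parallel=6.0, D_perp=6.0, lambda_order=2.0,
        dt_internal=0.25, n_frames=12000, n_probes=12, seed=21,
    )
    return generate_trajectory(params)
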