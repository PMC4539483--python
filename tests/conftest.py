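import numpy as np
import pytest

from astroca.gca import (
    CellGeometry,
    PhysiologicalParams,
    fd_oracle,
    field_solve,
    linearize,
)
from astroca.ip3r import DKMRates


@pytest.fixture(scope="session")
def rates():
    return DKMRates.from_config()


@pytest.fixture(scope="session")
def small_cell():
    """3-cluster test cell, positions aligned to the 0.4 um oracle grid."""
    params = PhysiologicalParams(radius=4.0)
    geometry = CellGeometry(
        positions=[[0.8, 0.0, 0.0], [-1.2, 0.4, 0.0], [0.0, -1.6, 1.2]],
        channels=[4, 8, 12],
        radius=4.0,
    )
    return params, geometry


@pytest.fixture(scope="session")
def small_coeffs(small_cell):
    params, _ = small_cell
    return linearize(params, 86.0)


@pytest.fixture(scope="session")
def oracle_setup(small_cell, small_coeffs):
    """One source on cluster 0 for 2 s; spectral and FD solutions at 1.5 s
    (source on) and 4.0 s (after switch-off), as 0.45 um ball averages."""
    params, geo = small_cell
    hist = [(0, 6, (0.0, 2.0))]
    pc, rb = 50.0, 0.45
    probe = np.array([[2.8, 0.0, 0.0]])  # 2 um from the source cluster
    spec, fd = {}, {}
    for t in (1.5, 4.0):
        spec[t] = {
            "sites": field_solve(small_coeffs, geo, hist, geo.positions, t,
                                 channel_flux=pc, eval_smoothing_radius=rb),
            "probe": field_solve(small_coeffs, geo, hist, probe, t,
                                 channel_flux=pc, eval_smoothing_radius=rb),
        }
        sol = fd_oracle(small_coeffs, geo, hist, grid_spacing=0.4, t=t,
                        channel_flux=pc, dt=2e-3)
        fd[t] = {
            "sites": np.array(
                [sol.ball_average(p, rb, 0) for p in geo.positions]
            ),
            "probe": np.array([sol.ball_average(probe[0], rb, 0)]),
        }
    return spec, fd
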