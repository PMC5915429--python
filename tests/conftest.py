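import numpy as np
import pytest

from emtrace import DensityGrid, LocalDensePoint


@pytest.fixture
def tiny_grid():
    """4x4x4 grid, 1 A spacing, a single bright voxel at index (1,2,3)."""
    values = np.zeros((4, 4, 4))
    values[1, 2, 3] = 5.0
    return DensityGrid(origin=np.zeros(3), spacing=np.ones(3), values=values)


def make_ldp(id_, pos, theta=1.0, members=((0, 0, 0),), v_raw=1.0,
             adjacent=()):
    """Hand-constructed LDP for tree/threading unit tests."""
    return LocalDensePoint(id=id_, position=np.asarray(pos, dtype=float),
                           theta_raw=theta, theta_norm=theta,
                           member_grid_indices=np.array(members),
                           v_raw=v_raw, theta_profile=theta,
                           adjacent_ids=set(adjacent))


def fully_adjacent(ldps):
    ids = {l.id for l in ldps}
    for l in ldps:
        l.adjacent_ids = ids - {l.id}
    return ldps


@pytest.fixture
def make_ldp_factory():
    return make_ldp


@pytest.fixture
def line_ldps():
    """Three collinear LDPs at 0, 1, 2 A, mutually adjacent."""
    ldps = [make_ldp(0, (0, 0, 0)), make_ldp(1, (1, 0, 0)),
            make_ldp(2, (2, 0, 0))]
    return fully_adjacent(ldps)
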