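import numpy as np
import pytest
from scipy import sparse

import imctplan as ip


@pytest.fixture(scope="session")
def machine():
    return ip.default_machine_model()


@pytest.fixture(scope="session")
def water_box():
    return ip.build_water_box(side_mm=80.0, spacing=2.0)


@pytest.fixture(scope="session")
def rtog_coarse():
    return ip.build_rtog_phantom(heterogeneous=False, spacing=4.0)


@pytest.fixture(scope="session")
def rtog_het_coarse():
    return ip.build_rtog_phantom(heterogeneous=True, spacing=4.0)


def random_influence(rng, n_vox=20, n_spots=10, n_fields=1, alpha_scale=0.6,
                     beta_scale=0.05):
    """Small random single- or multi-field influence set for objective tests."""
    per_field = {}
    field_cols = {}
    cols = np.array_split(np.arange(n_spots), n_fields)
    spots = []
    for fid, cc in enumerate(cols):
        D = rng.uniform(0.0, 0.5, size=(n_vox, len(cc)))
        D[rng.uniform(size=D.shape) < 0.3] = 0.0
        alpha = rng.uniform(0.2, 1.2, size=D.shape) * alpha_scale
        beta = rng.uniform(0.5, 1.5, size=D.shape) * beta_scale
        per_field[fid] = (
            sparse.csc_matrix(D),
            sparse.csc_matrix(alpha * D),
            sparse.csc_matrix(beta * D),
        )
        field_cols[fid] = cc
        spots += [ip.Spot(fid, 100.0, 0.0, 0.0, 1.0) for _ in cc]
    return ip.InfluenceSet(
        scenario=ip.nominal_scenario(), grid=None, voxel_idx=np.arange(n_vox),
        spots=spots, per_field=per_field, field_cols=field_cols,
    )


def fd_gradient(fun, x, h=1e-6):
    """Central finite differences of a scalar function."""
    g = np.zeros_like(x)
    for j in range(len(x)):
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        g[j] = (fun(xp) - fun(xm)) / (2 * h)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
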