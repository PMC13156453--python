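import numpy as np
import pytest

from sarbound import (GridSpec, PhantomModel, SyntheticSpec, generate_fieldset,
                      make_canonical_modes, qmatrices_from_fieldset)
from sarbound.sar import sar_at_locations


@pytest.fixture(scope="session")
def fieldset():
    """8-channel Maxwell-consistent fixture on the default 32^3 grid."""
    return generate_fieldset(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def qset(fieldset):
    q = qmatrices_from_fieldset(fieldset)
    q.validate()
    return q


@pytest.fixture(scope="session")
def canonical_modes():
    return make_canonical_modes(8, seed=5)


@pytest.fixture(scope="session")
def cp_mode(canonical_modes):
    return canonical_modes[0]


@pytest.fixture(scope="session")
def probe_qset(qset, cp_mode):
    """Eight probe locations drawn from the top-20% CP-mode SAR voxels.

    Temperature probes only give usable heating slopes where SAR is
    appreciable, so the probe fixture avoids near-null locations where
    relative SAR error is unbounded for any method.
    """
    vals = sar_at_locations(qset, cp_mode)
    top = np.flatnonzero(vals >= np.quantile(vals, 0.8))
    rng = np.random.default_rng(7)
    probes = qset.subset(rng.choice(top, 8, replace=False))
    probes.labels = [f"probe{i}" for i in range(8)]
    return probes


def make_uniform_fieldset(n_channels=1, shape=(8, 8, 8), voxel=0.004,
                          B_builder=None, sigma=0.5, eps_r=78.0, rho=1000.0):
    """Small field set with an all-true mask and caller-defined B, for
    closed-form operator checks."""
    from sarbound import ChannelFieldSet
    grid = GridSpec(shape=shape, voxel_size_m=(voxel,) * 3)
    mask = np.ones(shape, dtype=bool)
    phantom = PhantomModel(mask=mask, sigma_S_per_m=sigma, eps_r=eps_r,
                           rho_kg_per_m3=rho)
    B = np.zeros((n_channels, 3) + shape, dtype=complex)
    if B_builder is not None:
        B_builder(B, grid)
    return ChannelFieldSet(grid=grid, phantom=phantom, B=B)
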