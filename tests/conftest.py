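import numpy as np
import pytest

from patchykin.geometry import BoxSpec, random_packing
from patchykin.state import InteractionParams, SystemState


@pytest.fixture(scope="session")
def packed_state():
    """A valid packed (120, 48) mixture at phi = 0.30 (smallest size whose
    box satisfies the minimum-image constraint for A-A contacts)."""
    return random_packing((120, 48), 0.30, np.random.default_rng(1234))


@pytest.fixture()
def two_body_factory():
    """States with two particles in a huge box (no images, no neighbors)."""

    def make(species, pos, vel, quat=None, angmom=None, edge=400.0):
        species = np.asarray(species, dtype=np.int8)
        n = len(species)
        pos = np.asarray(pos, dtype=float)
        vel = np.asarray(vel, dtype=float)
        quat = (np.tile([1.0, 0.0, 0.0, 0.0], (n, 1)) if quat is None
                else np.asarray(quat, dtype=float))
        angmom = (np.zeros((n, 3)) if angmom is None
                  else np.asarray(angmom, dtype=float))
        return SystemState(pos=pos, quat=quat, vel=vel, angmom=angmom,
                           species_id=species,
                           box=BoxSpec(np.full(3, edge)))

    return make


@pytest.fixture()
def default_params():
    return InteractionParams()
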