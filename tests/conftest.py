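import numpy as np
import pytest

from chrompair import ChainState, PairingState, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def free_space_config():
    """Huge nucleus, tether disabled: chains feel only internal forces."""
    return SimulationConfig(
        nucleus_radius=1000.0, rabl_patch_radius=2000.0, n_pairs=1
    )


def make_chain(positions, buttons=(), chain_id=0, homolog_id=0):
    positions = np.asarray(positions, dtype=float)
    return ChainState(
        positions=positions,
        buttons=np.asarray(buttons, dtype=np.int64),
        homolog_id=homolog_id,
        chain_id=chain_id,
    )


@pytest.fixture
def straight_chain():
    """Ten nodes at rest length along z, inside any reasonable nucleus."""
    pos = np.zeros((10, 3))
    pos[:, 2] = -np.arange(10.0)
    pos[:, 2] += 5.0
    return make_chain(pos, buttons=[0, 3, 6, 9])


def random_two_chain_system(rng, n_nodes=6, scale=0.5):
    """Small random two-chain system with a few bonds, for gradient checks."""
    chains = []
    for cid in range(2):
        pos = rng.normal(scale=scale, size=(n_nodes, 3))
        pos[:, 2] += np.arange(n_nodes)  # roughly extended, avoids coincident nodes
        chains.append(make_chain(pos, buttons=[0, 2, 4], chain_id=cid))
    pairing = PairingState({((0, 0), (1, 0)), ((0, 2), (1, 4))})
    return chains, pairing
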