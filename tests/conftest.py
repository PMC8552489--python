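import numpy as np
import pytest

import nanotaxis as nt
from nanotaxis.forcefield import ForceField, PairTable, WallParams, mcg_pair_table


@pytest.fixture(scope="session")
def small_mcg_np():
    return nt.build_nanoparticle_mcg(100, 5, seed=3)


@pytest.fixture(scope="session")
def trivalent_np():
    return nt.build_nanoparticle_fcg(n_oligomers=44, n_guests=10, seed=1)


@pytest.fixture()
def random_mixed_system():
    """50 random beads of two types in a periodic slab, no overlaps removed."""
    rng = np.random.default_rng(0)
    types = [nt.BeadType("M"), nt.BeadType("G", charge=-0.5),
             nt.BeadType("RH", charge=1.0)]
    pos = rng.uniform(0, 4.0, (50, 3))
    pos[:, 2] += 0.5
    return nt.System(
        positions=pos, types=types,
        type_index=rng.integers(0, 3, 50).astype(int),
        box=nt.Box(6.0, 6.0, 8.0),
    )


@pytest.fixture(scope="session")
def mcg_ff():
    return ForceField(mcg_pair_table(), wall=WallParams())


@pytest.fixture()
def ideal_gas():
    """Non-interacting 200-bead gas for thermostat checks."""
    types = [nt.BeadType("X", mass=72.0)]
    rng = np.random.default_rng(1)
    sys_ = nt.System(
        positions=rng.uniform(0, 10, (200, 3)), types=types,
        type_index=np.zeros(200, dtype=int), box=nt.Box(10, 10, 10),
    )
    ff = ForceField(PairTable({"X": 0.47}, {"X": 0.0}))
    return sys_, ff
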