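import numpy as np
import pytest

from lipidfield.chemistry import default_stoichiometry
from lipidfield.energy import MembraneScorer, WeightSet
from lipidfield.fixtures import (
    bilayer_density_grid,
    make_profile_params,
    synthetic_profile,
)
from lipidfield.helix import build_ideal_helix, walp_sequence
from lipidfield.transfer import AtomScale


@pytest.fixture(scope="session")
def profile_params():
    """Self-consistent analytical profile parameters (z_c = 17 Å)."""
    return make_profile_params()


@pytest.fixture(scope="session")
def density_grid():
    return bilayer_density_grid()


@pytest.fixture(scope="session")
def salty_density_grid():
    return bilayer_density_grid(with_salt=True)


@pytest.fixture(scope="session")
def clean_profile(profile_params):
    return synthetic_profile(profile_params)


@pytest.fixture(scope="session")
def atom_scale():
    """Deterministic synthetic per-type transfer energies covering every
    transfer type the embedded chemistry emits."""
    types = default_stoichiometry().atom_types
    rng = np.random.default_rng(7)
    return AtomScale({t: float(v) for t, v in
                      zip(types, rng.normal(0.0, 0.8, len(types)))})


@pytest.fixture(scope="session")
def walp23():
    return build_ideal_helix(walp_sequence(8))


@pytest.fixture()
def scorer(profile_params, atom_scale):
    return MembraneScorer(profile_params, atom_scale, WeightSet())
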