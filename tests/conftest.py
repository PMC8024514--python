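import numpy as np
import pytest

from ugdyn import make_conformer, make_glycoprotein


@pytest.fixture()
def rng():
    return np.random.default_rng(20211)


@pytest.fixture()
def conformer():
    """A mid-range synthetic conformer with its planted CC ground truth."""
    return make_conformer((40.0, 120.0, 15.0), seed=7)


@pytest.fixture()
def glyco_two_sites():
    """Toy random-walk glycoprotein with two declared sites and a
    brute-force reach table."""
    return make_glycoprotein(n_residues=40, site_residues=(5, 30), seed=11)


def rigid_transform(rng):
    """Random proper rotation + translation pair."""
    from ugdyn._geom import random_rotation

    return random_rotation(rng), rng.uniform(-50, 50, 3)


def apply_rigid(structure, R, t):
    coords = structure.coords_array() @ R.T + t
    return structure.with_coords(coords)
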