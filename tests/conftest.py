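import numpy as np
import pytest

from hergscreen.chemio import from_smiles, generate_conformers, standardize


@pytest.fixture(scope="session")
def benzene():
    return generate_conformers(standardize(from_smiles("c1ccccc1", "benzene")), seed=7)


@pytest.fixture(scope="session")
def acetone():
    return generate_conformers(standardize(from_smiles("CC(C)=O", "acetone")), seed=1)


@pytest.fixture(scope="session")
def final_pharmacophore():
    from hergscreen.reference_models import final_model

    return final_model()


@pytest.fixture(scope="session")
def small_sar():
    """A 60-compound synthetic SAR set shared across tests."""
    from hergscreen.synthetic_data import SarSpec, make_sar_dataset

    return make_sar_dataset(SarSpec(n_compounds=60, seed=11, noise_sd=0.3))


def rigid_transform(coords, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = rng.uniform(-5, 5, 3)
    return coords @ rot.T + shift
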