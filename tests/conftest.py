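import numpy as np
import pytest

from idpens import ConformationSet


def make_cset(coords, masses=None, atom_names=None, elements=None,
              residue_index=None, residue_name=None):
    """Small-molecule ConformationSet builder for geometry tests."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    return ConformationSet(
        coords=coords,
        atom_names=atom_names if atom_names is not None
        else [f"A{i}" for i in range(n_atoms)],
        elements=elements if elements is not None else ["C"] * n_atoms,
        residue_index=residue_index if residue_index is not None
        else [0] * n_atoms,
        residue_name=residue_name if residue_name is not None
        else ["ALA"] * n_atoms,
        frame_times=np.arange(coords.shape[0], dtype=float),
        masses=masses if masses is not None else [1.0] * n_atoms,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_features(rng):
    """Two well-separated (10σ) Gaussian blobs with ground-truth labels."""
    from idpens import FeatureMatrix

    X = np.vstack([rng.normal(0.0, 1.0, (100, 5)),
                   rng.normal(10.0, 1.0, (100, 5))])
    labels = np.repeat([0, 1], 100)
    fm = FeatureMatrix(X, "PHI_PSI", [f"f{i}" for i in range(5)])
    return fm, labels


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng)
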