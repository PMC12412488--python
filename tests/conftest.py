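import numpy as np
import pytest

from trigraph.fixtures import attach_conformers, builtin_dataset, druglike_subset
from trigraph.molgraph import build_trigraph, compute_geometry, featurize

# A compact but structurally varied slice of the builtin set used by most
# geometry / network tests: includes the degenerate cases (single atom,
# diatomic, linear nitrile), rings, heteroatoms and stereocenters.
_SMALL_IDS = 24


@pytest.fixture(scope="session")
def small_molecules():
    """Parsed molecules without conformers (fast)."""
    return builtin_dataset()[:_SMALL_IDS]


@pytest.fixture(scope="session")
def small_conformers(small_molecules):
    """The same molecules with MMFF94 conformers attached (cached per session)."""
    return attach_conformers(small_molecules, seed=0, n_candidates=1)


@pytest.fixture(scope="session")
def druglike_conformers():
    """20 drug-like molecules with conformers, for network/embedding tests."""
    mols = druglike_subset(builtin_dataset())[:20]
    return attach_conformers(mols, seed=1, n_candidates=1)


@pytest.fixture(scope="session")
def encoded_small(small_conformers):
    """(mol, graph, geo, feats) tuples for the small conformer set."""
    out = []
    for m in small_conformers:
        g = build_trigraph(m)
        geo = compute_geometry(m.coords, g)
        out.append((m, g, geo, featurize(m, g, geo)))
    return out


@pytest.fixture(scope="session")
def feature_dims(encoded_small):
    return encoded_small[0][3].dims


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
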