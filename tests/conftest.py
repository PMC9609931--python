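import numpy as np
import pytest

from mutadimer import synthdata
from mutadimer.structio import ResidueKey


@pytest.fixture(scope="session")
def helix20():
    return synthdata.make_monomer(20, "helix", seed=7)


@pytest.fixture(scope="session")
def receptor_trp():
    """16-residue helix with a tryptophan tag at the middle."""
    return synthdata.make_monomer(16, "helix", seed=1, site_residue="TRP")


@pytest.fixture(scope="session")
def ligand10():
    return synthdata.make_monomer(10, "helix", seed=2)


@pytest.fixture(scope="session")
def tag_key(receptor_trp) -> ResidueKey:
    return synthdata.site_key(receptor_trp)


@pytest.fixture(scope="session")
def small_poseset(receptor_trp, ligand10, tag_key):
    ps, truth = synthdata.make_pose_ensemble(
        receptor_trp, ligand10, n_poses=12, burial_prob=0.5,
        tagged=tag_key, seed=42, condition_label="fixture")
    return ps, truth


def random_rigid_transform(rng):
    """Random proper rotation + translation for invariance tests."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])
    t = rng.uniform(-20, 20, size=3)
    return R, t
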