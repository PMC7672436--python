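import numpy as np
import pytest

from pairscape import constants as C
from pairscape.nucleic_geometry import AtomRecord
from pairscape.synthetic_data import build_base_pair, build_duplex


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def standard_guanine():
    return [AtomRecord(n, e, np.array(xyz), 1, "DG")
            for n, e, xyz in C.STANDARD_NUCLEOTIDES["DG"]]


@pytest.fixture(scope="session")
def class_i_duplex():
    """Default-built class I duplex with X = A (sequence GGTTAAATTAACC)."""
    return build_duplex("GGTTAAATTAACC")


@pytest.fixture(scope="session")
def ideal_gc_pair():
    return build_base_pair("G", "C")


@pytest.fixture(scope="session")
def ideal_at_pair():
    return build_base_pair("A", "T")


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_atoms(atoms, R, t):
    from dataclasses import replace
    return [replace(a, position=R @ a.position + t) for a in atoms]
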