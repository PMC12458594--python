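import numpy as np
import pytest

from isletsim.lattice import BOUNDARY, HEALTHY, TUMOR, Lattice


@pytest.fixture
def cube3() -> Lattice:
    """All-healthy 3x3x3 non-periodic lattice at dx = 0.3 mm."""
    return Lattice(np.zeros((3, 3, 3), np.int8), 0.3)


@pytest.fixture
def center_tumor(cube3) -> Lattice:
    cube3.states[1, 1, 1] = TUMOR
    return cube3


def random_lattice(rng: np.random.Generator, shape=(4, 4, 4), periodic=False,
                   p=(0.5, 0.35, 0.15)) -> Lattice:
    states = rng.choice(
        [HEALTHY, TUMOR, BOUNDARY], size=shape, p=list(p)
    ).astype(np.int8)
    return Lattice(states, 0.5, periodic=(periodic,) * 3)
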