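import numpy as np
import pytest

import porefpt as p


@pytest.fixture(scope="session")
def dsdna_sequence():
    """Surrogate for 10 kbp double-stranded DNA: A(E)98X at 34 nm/residue.

    Carries 100 negative charge units after terminal corrections and has a
    contour length of 3400 nm.
    """
    return p.parse_sequence("A" + "E" * 98 + "X", laa=34.0)


@pytest.fixture(scope="session")
def zero_potential():
    """U = 0 on the standard 100 nm / 0.5 nm-spacing grid."""
    grid = np.linspace(0.0, 100.0, 201)
    return p.PotentialProfile(grid=grid, U=np.zeros(201))


def make_potential(grid, U):
    return p.PotentialProfile(grid=np.asarray(grid, float),
                              U=np.asarray(U, float))
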