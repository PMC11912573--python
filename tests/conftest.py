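import numpy as np
import pytest

from pentatube import (
    LatticeParams,
    make_dodecahedron,
    solve_lattice,
    wrap_to_cylinder,
)

#: Analytic dodecahedron dihedral angle, arccos(-1/sqrt(5)).
DODECA_BENDING = float(np.degrees(np.arccos(-1.0 / np.sqrt(5.0))))


@pytest.fixture(scope="session")
def dodecahedron():
    return make_dodecahedron()


@pytest.fixture(scope="session")
def lattice_34():
    return solve_lattice(LatticeParams(b=2.18, n_h=3, n_p=4))


@pytest.fixture(scope="session")
def tube_34(lattice_34):
    return wrap_to_cylinder(lattice_34, n_turns=2.0)


def thread_of(label: str) -> int:
    return int(label.split("_t")[1].split("_")[0])
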