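import random

import numpy as np
import pytest

from stemca.lattice import Lattice, RegionMasks
from stemca.params import ParameterSet


@pytest.fixture
def lat7():
    return Lattice((7, 7, 7))


@pytest.fixture
def lat5():
    return Lattice((5, 5, 5))


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def empty_masks(lat7):
    return RegionMasks.empty(lat7)


@pytest.fixture
def rng():
    return random.Random(20240917)


def dense_solve_dirichlet(lattice, diffusion, k, source, bc_value):
    """Independent dense direct solve of the assembled Dirichlet system."""
    from stemca.microenvironment import assemble_dirichlet_system

    A, b, int_nodes = assemble_dirichlet_system(
        lattice, diffusion, k, source, bc_value
    )
    x = np.linalg.solve(A.toarray(), b)
    out = np.full(lattice.n_nodes, float(bc_value))
    out[int_nodes] = x
    return out.reshape(lattice.shape)


def dense_solve_neumann(lattice, diffusion, k, source):
    from stemca.microenvironment import assemble_neumann_system

    A, b = assemble_neumann_system(lattice, diffusion, k, source)
    return np.linalg.solve(A.toarray(), b).reshape(lattice.shape)
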