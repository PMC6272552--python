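import numpy as np
import pytest

from auxqmmm.chem_model import Atom, _water_template_ang
from auxqmmm.gto_integrals import BasisSetLibrary, build_ao_basis, build_aux_basis
from auxqmmm.units import ANGSTROM_TO_BOHR


@pytest.fixture(scope="session")
def minimal_lib():
    return BasisSetLibrary.builtin("minimal")


@pytest.fixture(scope="session")
def dzvp_lib():
    return BasisSetLibrary.builtin("dzvp-like")


@pytest.fixture(scope="session")
def water_atoms():
    t = _water_template_ang() * ANGSTROM_TO_BOHR
    return [
        Atom("O", 8, t[0], mass=15.9994),
        Atom("H", 1, t[1], mass=1.00794),
        Atom("H", 1, t[2], mass=1.00794),
    ]


@pytest.fixture(scope="session")
def water_minimal(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    aux = build_aux_basis(water_atoms, minimal_lib)
    return basis, aux


@pytest.fixture(scope="session")
def eri4_tensor_water(water_minimal):
    """Full 4-center ERI tensor of water/minimal (brute-force oracle)."""
    from auxqmmm.gto_integrals import eri4

    basis, _ = water_minimal
    fns = basis.functions
    n = len(fns)
    T = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(i + 1):
            for k in range(n):
                for l in range(k + 1):
                    if (i, j) < (k, l):
                        continue
                    v = eri4(fns[i], fns[j], fns[k], fns[l])
                    for (a, b) in ((i, j), (j, i)):
                        for (c, d) in ((k, l), (l, k)):
                            T[a, b, c, d] = v
                            T[c, d, a, b] = v
    return T
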