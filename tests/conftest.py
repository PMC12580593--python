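"""Shared fixtures: small model atoms and the (session-cached) Ti SCF runs."""

import numpy as np
import pytest

from nmrdkh import atomic_scf as asc
from nmrdkh import contraction, welltempered


@pytest.fixture(scope="session")
def ti_primitives():
    return welltempered.build_ti_primitives()


@pytest.fixture(scope="session")
def ti_ao_basis(ti_primitives):
    return asc.AOBasis.from_primitives(ti_primitives)


@pytest.fixture(scope="session")
def ti_eri(ti_ao_basis):
    return asc.two_electron_integrals(ti_ao_basis)


@pytest.fixture(scope="session")
def ti_scf_nr(ti_ao_basis, ti_eri):
    return asc.uhf_scf(asc.ti_ground_state(hamiltonian="NR"), ti_ao_basis, eri=ti_eri)


@pytest.fixture(scope="session")
def ti_scf_dkh2(ti_ao_basis, ti_eri):
    return asc.uhf_scf(asc.ti_ground_state(hamiltonian="DKH2"), ti_ao_basis, eri=ti_eri)


@pytest.fixture(scope="session")
def ti_tz_basis(ti_scf_dkh2, ti_primitives):
    """The contracted [12s6p3d] triple-zeta stage."""
    scheme = contraction.parse_scheme("(18s11p6d)->[12s6p3d]")
    return contraction.build_contraction(ti_scf_dkh2, ti_primitives, scheme)


def even_tempered_s(z_hi, z_lo, n):
    return asc.AOBasis(
        [asc.Shell(l=0, exps=(z,), coefs=(1.0,)) for z in np.geomspace(z_hi, z_lo, n)]
    )


@pytest.fixture(scope="session")
def hydrogen_basis():
    return even_tempered_s(1e4, 1e-2, 20)
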