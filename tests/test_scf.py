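"""UHF engine and DKH2 Hamiltonian: exact limits, literature anchors,
symmetry and determinism properties."""

import numpy as np
import pytest
import scipy.linalg

from nmrdkh import atomic_scf as asc

from conftest import even_tempered_s


def even_tempered(l, z_hi, z_lo, n):
    return [asc.Shell(l=l, exps=(z,), coefs=(1.0,)) for z in np.geomspace(z_hi, z_lo, n)]


class TestExactAnchors:
    def test_hydrogen_ground_state(self, hydrogen_basis):
        res = asc.uhf_scf(asc.hydrogenic(1.0), hydrogen_basis)
        assert res.converged
        assert res.E_total == pytest.approx(-0.5, abs=1e-4)

    def test_helium_rhf_limit(self):
        # independent literature anchor: He RHF limit -2.8616799 hartree
        basis = even_tempered_s(1e4, 5e-2, 16)
        sys_he = asc.AtomSystem(Z=2.0, occupations={0: ((1.0,), (1.0,))})
        res = asc.uhf_scf(sys_he, basis)
        assert res.E_total == pytest.approx(-2.8616799, abs=5e-4)

    def test_neon_rhf_limit(self):
        # Ne RHF limit -128.5471 hartree: exercises the s and p ERI blocks
        shells = even_tempered(0, 2e5, 0.15, 16) + even_tempered(1, 6e2, 0.2, 12)
        sys_ne = asc.AtomSystem(
            Z=10.0,
            occupations={0: ((1.0, 1.0), (1.0, 1.0)), 1: ((1.0,), (1.0,))},
        )
        res = asc.uhf_scf(sys_ne, asc.AOBasis(shells))
        assert res.E_total == pytest.approx(-128.5471, abs=0.02)

    def test_virial_ratio_ti(self, ti_scf_nr):
        assert -ti_scf_nr.E_potential / ti_scf_nr.E_kinetic == pytest.approx(
            2.0, abs=5e-3
        )


class TestDKH2:
    def test_nonrelativistic_limit(self, hydrogen_basis):
        ints = asc.one_center_integrals(hydrogen_basis, 1.0)
        h = asc.dkh2_transform(ints.S, ints.T, ints.V, ints.pVp, c_light=1e8)
        assert np.abs(h - ints.T - ints.V).max() < 1e-6

    def test_hydrogen_dkh2_matches_dirac_shift(self, hydrogen_basis):
        # exact Dirac 1s for Z=1: -0.5000066566; DKH2 is exact to this order
        ints = asc.one_center_integrals(hydrogen_basis, 1.0)
        h = asc.dkh2_transform(ints.S, ints.T, ints.V, ints.pVp)
        e0 = scipy.linalg.eigh(h, ints.S, eigvals_only=True)[0]
        assert e0 == pytest.approx(-0.5000066, abs=2e-6)

    def test_heavy_ion_stabilization(self):
        # one-electron Z=90: scalar relativity lowers the 1s level
        basis = asc.AOBasis(even_tempered(0, 5e7, 1.0, 28))
        ints = asc.one_center_integrals(basis, 90.0)
        e_nr = scipy.linalg.eigh(ints.T + ints.V, ints.S, eigvals_only=True)[0]
        h = asc.dkh2_transform(ints.S, ints.T, ints.V, ints.pVp)
        e_rel = scipy.linalg.eigh(h, ints.S, eigvals_only=True)[0]
        assert e_rel < e_nr

    def test_monotone_approach_to_nr(self):
        basis = asc.AOBasis(even_tempered(0, 5e7, 1.0, 24))
        ints = asc.one_center_integrals(basis, 90.0)
        e_nr = scipy.linalg.eigh(ints.T + ints.V, ints.S, eigvals_only=True)[0]
        energies = []
        for c in (137.035999, 1e3, 1e4, 1e6):
            h = asc.dkh2_transform(ints.S, ints.T, ints.V, ints.pVp, c_light=c)
            energies.append(scipy.linalg.eigh(h, ints.S, eigvals_only=True)[0])
        assert all(a < b for a, b in zip(energies, energies[1:]))
        assert all(e < e_nr for e in energies)
        assert energies[-1] == pytest.approx(e_nr, abs=1e-5)

    def test_requires_positive_definite_overlap(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        T = np.eye(2)
        with pytest.raises(asc.SCFError):
            asc.dkh2_transform(S, T, -T, T)


class TestSymmetryAndDeterminism:
    def test_energy_invariant_under_primitive_reordering(self):
        sys_he = asc.AtomSystem(Z=2.0, occupations={0: ((1.0,), (1.0,))})
        zs = [9.0, 0.7, 2.5, 31.0, 0.2]
        e1 = asc.uhf_scf(
            sys_he, asc.AOBasis([asc.Shell(0, (z,), (1.0,)) for z in zs])
        ).E_total
        e2 = asc.uhf_scf(
            sys_he, asc.AOBasis([asc.Shell(0, (z,), (1.0,)) for z in sorted(zs)])
        ).E_total
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_zero_field_m_degeneracy(self, ti_scf_dkh2):
        # all m components of a (n, l) shell share the orbital energy
        basis = ti_scf_dkh2.basis
        for l in (1, 2):
            eps_by_m = {}
            for label, idx in ti_scf_dkh2.blocks:
                if isinstance(label, tuple) and label[0] == l:
                    eps_by_m[label[1]] = np.sort(ti_scf_dkh2.eps_alpha[idx])
            ref = eps_by_m[0]
            for m, eps in eps_by_m.items():
                assert np.abs(eps - ref).max() < 1e-9

    def test_scf_idempotency(self, ti_scf_nr, ti_ao_basis, ti_eri):
        res2 = asc.uhf_scf(
            asc.ti_ground_state(hamiltonian="NR"),
            ti_ao_basis,
            eri=ti_eri,
            guess=ti_scf_nr._density,
        )
        assert res2.n_iter <= 2
        assert res2.E_total == pytest.approx(ti_scf_nr.E_total, abs=1e-10)

    def test_field_sign_immaterial(self):
        sys_p = asc.AtomSystem(
            Z=4.0, occupations={0: ((1.0, 1.0), (1.0, 1.0))}, field_F=0.05
        )
        shells = even_tempered(0, 50.0, 0.08, 8) + even_tempered(1, 2.0, 0.2, 3)
        basis = asc.AOBasis(shells)
        e_plus = asc.uhf_scf(sys_p, basis).E_total
        sys_m = asc.AtomSystem(
            Z=4.0, occupations={0: ((1.0, 1.0), (1.0, 1.0))}, field_F=-0.05
        )
        e_minus = asc.uhf_scf(sys_m, basis).E_total
        assert e_plus == pytest.approx(e_minus, abs=1e-9)

    def test_orthonormal_orbitals(self, ti_scf_dkh2):
        C, S = ti_scf_dkh2.C_alpha, ti_scf_dkh2.S
        gram = C.T @ S @ C
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-8

    def test_nonconvergence_error_carries_energy(self, hydrogen_basis):
        with pytest.raises(asc.SCFError) as err:
            asc.uhf_scf(asc.hydrogenic(1.0), hydrogen_basis, max_iter=1)
        assert err.value.last_energy is not None


class TestFieldResponse:
    def test_energy_lowered_by_field(self):
        sys0 = asc.AtomSystem(Z=4.0, occupations={0: ((1.0, 1.0), (1.0, 1.0))})
        shells = even_tempered(0, 50.0, 0.08, 8) + even_tempered(1, 2.0, 0.2, 3)
        basis = asc.AOBasis(shells)
        e0 = asc.uhf_scf(sys0, basis).E_total
        sysF = asc.AtomSystem(
            Z=4.0, occupations={0: ((1.0, 1.0), (1.0, 1.0))}, field_F=0.05
        )
        eF = asc.uhf_scf(sysF, basis).E_total
        assert eF < e0

    def test_quadratic_stark_regime(self):
        # polarizability regime: E(F) - E(0) ~ -alpha F^2 / 2
        sys_ = lambda F: asc.AtomSystem(
            Z=2.0, occupations={0: ((1.0,), (1.0,))}, field_F=F
        )
        shells = even_tempered(0, 1e3, 0.1, 10) + even_tempered(1, 1.5, 0.3, 3)
        basis = asc.AOBasis(shells)
        e0 = asc.uhf_scf(sys_(0.0), basis).E_total
        d1 = asc.uhf_scf(sys_(0.02), basis).E_total - e0
        d2 = asc.uhf_scf(sys_(0.04), basis).E_total - e0
        assert d2 / d1 == pytest.approx(4.0, rel=0.05)
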