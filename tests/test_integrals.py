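"""One-center integral engine against independent symbolic/quadrature oracles."""

import math

import mpmath as mp
import numpy as np
import pytest

from nmrdkh import _integrals as gi
from nmrdkh import atomic_scf as asc

mp.mp.dps = 30


def norm(z, l):
    return float(gi.radial_norm(z, l))


class TestOneElectronRadial:
    @pytest.mark.parametrize("l", [0, 1, 2, 3])
    def test_identical_normalized_overlap_is_one(self, l):
        z = 2.37
        s = norm(z, l) ** 2 * gi.overlap_radial(z, z, l)
        assert s == pytest.approx(1.0, rel=1e-14)

    def test_kinetic_diagonal_closed_form(self):
        # normalized s Gaussian: <T> = 3 zeta / 2
        z = 1.618
        t = norm(z, 0) ** 2 * gi.kinetic_radial(z, z, 0)
        assert t == pytest.approx(1.5 * z, rel=1e-14)

    @pytest.mark.parametrize("l,a,b", [(0, 1.7, 0.9), (1, 3.0, 0.4), (2, 5.5, 5.5), (3, 0.8, 2.2)])
    def test_kinetic_vs_quadrature(self, l, a, b):
        def dR(z):
            return lambda r: ((l * r ** (l - 1) if l else 0) - 2 * z * r ** (l + 1)) * mp.e ** (-z * r**2)
        ref = mp.mpf(1) / 2 * mp.quad(
            lambda r: (dR(a)(r) * dR(b)(r)
                       + l * (l + 1) * r ** (2 * l - 2) * mp.e ** (-(a + b) * r**2)) * r**2,
            [0, mp.inf],
        )
        assert gi.kinetic_radial(a, b, l) == pytest.approx(float(ref), rel=1e-12)

    def test_nuclear_attraction_vs_symbolic(self):
        # <g| -Z/r |g> for normalized s Gaussian, zeta = 1, Z = 1:
        # symbolic integration gives -2 sqrt(2/pi) sqrt(zeta)
        z = 1.0
        v = norm(z, 0) ** 2 * gi.nuclear_radial(z, z, 0, Z=1.0)
        ref = mp.quad(
            lambda r: -(norm(z, 0)) ** 2 * r ** 2 * mp.e ** (-2 * z * r**2) / r,
            [0, mp.inf],
        )
        assert v == pytest.approx(float(ref), rel=1e-13)
        assert v == pytest.approx(-2.0 * math.sqrt(2.0 / math.pi), rel=1e-13)

    @pytest.mark.parametrize("l,a,b", [(0, 2.0, 0.5), (1, 1.1, 4.0), (2, 3.3, 3.3), (3, 0.7, 1.9)])
    def test_pvp_vs_quadrature(self, l, a, b):
        def dR(z):
            return lambda r: ((l * r ** (l - 1) if l else 0) - 2 * z * r ** (l + 1)) * mp.e ** (-z * r**2)
        ref = mp.quad(
            lambda r: (-1 / r) * (dR(a)(r) * dR(b)(r)
                                  + l * (l + 1) * r ** (2 * l - 2) * mp.e ** (-(a + b) * r**2)) * r**2,
            [0, mp.inf],
        )
        assert gi.pvp_radial(a, b, l, Z=1.0) == pytest.approx(float(ref), rel=1e-12)


class TestSlaterRadial:
    @staticmethod
    def _oracle(p, n1, q, n2, L):
        p, q = mp.mpf(p), mp.mpf(q)
        def lower(n, x):
            return mp.gammainc(mp.mpf(n + 1) / 2, 0, q * x**2) / (2 * q ** (mp.mpf(n + 1) / 2))
        def upper(n, x):
            return mp.gammainc(mp.mpf(n + 1) / 2, q * x**2, mp.inf) / (2 * q ** (mp.mpf(n + 1) / 2))
        f = lambda r1: r1 ** (n1 + 2) * mp.e ** (-p * r1**2) * (
            lower(n2 + 2 + L, r1) / r1 ** (L + 1) + r1**L * upper(n2 + 1 - L, r1)
        )
        r0, r1s = 1 / mp.sqrt(p), 1 / mp.sqrt(q)
        pts = sorted({r0 / 10, r0, 10 * r0, r1s / 10, r1s, 10 * r1s})
        return float(mp.quad(f, [0] + pts + [mp.inf]))

    @pytest.mark.parametrize("n1,n2,L", [(0, 0, 0), (2, 2, 0), (2, 2, 2), (4, 2, 2),
                                         (3, 3, 1), (6, 6, 0), (5, 3, 3), (4, 4, 4)])
    @pytest.mark.parametrize("p,q", [(1.3, 0.7), (50.0, 20.0), (0.05, 0.05),
                                     (2.6e5, 0.2), (7.0, 300.0)])
    def test_vs_quadrature(self, n1, n2, L, p, q):
        got = float(gi.slater_rl(p, n1, q, n2, L))
        assert got == pytest.approx(self._oracle(p, n1, q, n2, L), rel=1e-9)

    def test_symmetry_under_pair_swap(self):
        for (p, n1, q, n2, L) in [(2.6e5, 6, 0.2, 6, 6), (3.0, 2, 9.0, 4, 2)]:
            a = float(gi.slater_rl(p, n1, q, n2, L))
            b = float(gi.slater_rl(q, n2, p, n1, L))
            assert a == pytest.approx(b, rel=1e-13)

    def test_ssss_boys_closed_form(self):
        # independent route: the textbook (ss|ss) formula for s Gaussians
        a, b, c, d = 1.1, 0.3, 2.7, 0.9
        p, q = a + b, c + d
        ref = 2 * math.pi**2.5 / (p * q * math.sqrt(p + q))
        # strip the (4 pi) angular factors and the multipole L=0 weight
        radial = float(gi.slater_rl(p, 0, q, 0, 0))
        assert (4 * math.pi) ** 2 * radial == pytest.approx(ref, rel=1e-13)

    def test_invalid_multipole_combination(self):
        with pytest.raises(ValueError):
            gi.slater_rl(1.0, 1, 1.0, 1, 0)  # parity violation


class TestAngular:
    def test_real_gaunt_vs_sympy(self):
        real_gaunt = pytest.importorskip("sympy.physics.wigner").real_gaunt
        for (l1, l2, L) in [(1, 1, 2), (2, 2, 2), (3, 2, 1), (3, 3, 6)]:
            G = gi.real_gaunt(l1, l2, L)
            for m1 in range(-l1, l1 + 1):
                for m2 in range(-l2, l2 + 1):
                    for M in range(-L, L + 1):
                        ref = float(real_gaunt(l1, l2, L, m1, m2, M))
                        assert G[m1 + l1, m2 + l2, M + L] == pytest.approx(
                            ref, abs=1e-12
                        )

    def test_dipole_selection_rule(self):
        A = gi.dipole_angular(1, 2)
        # z couples only equal real-m labels
        for i, m1 in enumerate(range(-1, 2)):
            for j, m2 in enumerate(range(-2, 3)):
                if m1 != m2:
                    assert A[i, j] == 0.0

    def test_dipole_sp_value(self):
        # <S_00|cos theta|S_10> = 1/sqrt(3)
        A = gi.dipole_angular(0, 1)
        assert A[0, 1] == pytest.approx(1.0 / math.sqrt(3.0), rel=1e-12)


class TestERITensor:
    def test_s_only_vs_boys_formula(self):
        zs = (0.5, 1.4, 3.9)
        basis = asc.AOBasis([asc.Shell(l=0, exps=(z,), coefs=(1.0,)) for z in zs])
        eri = asc.two_electron_integrals(basis)
        for i, a in enumerate(zs):
            for j, b in enumerate(zs):
                for k, c in enumerate(zs):
                    for l, d in enumerate(zs):
                        p, q = a + b, c + d
                        raw = 2 * math.pi**2.5 / (p * q * math.sqrt(p + q))
                        # normalized 3d s Gaussian: N = (2 z / pi)^(3/4)
                        ref = raw * math.prod((2 * z / math.pi) ** 0.75 for z in (a, b, c, d))
                        assert eri[i, j, k, l] == pytest.approx(ref, rel=1e-10)

    def test_permutational_symmetry(self):
        basis = asc.AOBasis(
            [
                asc.Shell(l=0, exps=(1.3,), coefs=(1.0,)),
                asc.Shell(l=1, exps=(0.9,), coefs=(1.0,)),
                asc.Shell(l=2, exps=(0.6,), coefs=(1.0,)),
            ]
        )
        eri = asc.two_electron_integrals(basis)
        assert np.allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-12)
        assert np.allclose(eri, eri.transpose(0, 1, 3, 2), atol=1e-12)
        assert np.allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-12)

    def test_pf_element_vs_independent_factors(self):
        # one p and one f primitive: cross-check (pp|ff) m=0 elements from
        # sympy real Gaunt + mpmath radial quadrature
        real_gaunt = pytest.importorskip("sympy.physics.wigner").real_gaunt
        zp, zf = 1.7, 0.8
        basis = asc.AOBasis(
            [
                asc.Shell(l=1, exps=(zp,), coefs=(1.0,)),
                asc.Shell(l=3, exps=(zf,), coefs=(1.0,)),
            ]
        )
        eri = asc.two_electron_integrals(basis)
        iz, jz = 1, 3 + 3  # m=0 of p block; m=0 of f block
        got = eri[iz, iz, jz, jz]
        ref = 0.0
        for L in (0, 2):
            ang1 = float(real_gaunt(1, 1, L, 0, 0, 0))
            ang2 = float(real_gaunt(3, 3, L, 0, 0, 0))
            rad = float(gi.slater_rl(2 * zp, 2, 2 * zf, 6, L))
            nrm = norm(zp, 1) ** 2 * norm(zf, 3) ** 2
            ref += 4 * math.pi / (2 * L + 1) * ang1 * ang2 * rad * nrm
        assert got == pytest.approx(ref, rel=1e-11)

    def test_memory_guard(self):
        basis = asc.AOBasis(
            [asc.Shell(l=0, exps=(z,), coefs=(1.0,)) for z in np.geomspace(1e4, 1e-2, 20)]
        )
        with pytest.raises(MemoryError):
            asc.two_electron_integrals(basis, max_functions=10)


class TestOneElectronMatrices:
    def test_block_structure_and_condition(self, hydrogen_basis):
        ints = asc.one_center_integrals(hydrogen_basis, 1.0)
        assert np.allclose(ints.S, ints.S.T, atol=1e-12)
        assert np.allclose(ints.T, ints.T.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(ints.S) > 0)
        assert np.all(np.linalg.eigvalsh(ints.T) > 0)

    def test_dz_couples_only_adjacent_l(self):
        basis = asc.AOBasis(
            [
                asc.Shell(l=0, exps=(1.0,), coefs=(1.0,)),
                asc.Shell(l=1, exps=(0.8,), coefs=(1.0,)),
                asc.Shell(l=2, exps=(0.6,), coefs=(1.0,)),
            ]
        )
        ints = asc.one_center_integrals(basis, 1.0)
        sd_block = ints.Dz[0:1, 4:9]  # s x d functions: Delta l = 2
        assert np.all(sd_block == 0.0)
        sp_block = ints.Dz[0:1, 1:4]
        assert np.any(sp_block != 0.0)

    def test_duplicate_exponent_warns(self):
        basis = asc.AOBasis(
            [
                asc.Shell(l=0, exps=(1.0,), coefs=(1.0,)),
                asc.Shell(l=0, exps=(1.0,), coefs=(1.0,)),
            ]
        )
        with pytest.warns(UserWarning, match="duplicate exponent"):
            # an exactly duplicated primitive also makes S numerically singular
            with pytest.raises(asc.SCFError, match="ill-conditioned"):
                asc.one_center_integrals(basis, 1.0)
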