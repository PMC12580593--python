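"""One-center unrestricted Hartree-Fock over spherical Gaussian basis sets.

This engine serves the basis-set construction pipeline: it supplies the
relativistically corrected atomic orbital coefficients from which the
segmented contraction is built, and the finite-field total energy that the
f-polarization exponents minimize.

Model
-----
* Single nucleus of charge Z (point nucleus), spherical Gaussians up to f.
* Spin-unrestricted SCF with per-shell fractional occupations.  For an
  open-shell atom the d^n configuration is spherically averaged (equal
  fractional occupation of the five d spin-orbitals), which keeps the
  zero-field density totally symmetric and the per-shell contraction
  coefficients rotationally well defined.
* One-electron Hamiltonian either nonrelativistic (T + V) or scalar
  second-order Douglas-Kroll-Hess (DKH2), built per angular-momentum
  channel in the kinetic-energy eigenbasis from the V and pVp matrices.
* Optional axial electric field F adds +F*z to the one-electron
  Hamiltonian.  The energy is even in F for an atom, so the sign
  convention is immaterial.  With the field on, the symmetry blocks are
  labelled by the real-m quantum number only; occupations follow aufbau
  ordering of the perturbed orbital energies with the zero-field
  fractional weights.

Convergence uses a core-Hamiltonian guess and DIIS (8-vector window) with
damping fallback, which makes every run deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.optimize

from . import _integrals as gi
from .welltempered import PrimitiveBasis

__all__ = [
    "Shell",
    "AOBasis",
    "AtomSystem",
    "OneElectronMatrices",
    "SCFResult",
    "SCFError",
    "ti_ground_state",
    "one_center_integrals",
    "two_electron_integrals",
    "dkh2_transform",
    "uhf_scf",
    "optimize_f_exponents",
]

C_LIGHT = 137.035999084  # CODATA speed of light in atomic units
_L_OF = {"s": 0, "p": 1, "d": 2, "f": 3}
_L_LABEL = "spdf"


class SCFError(RuntimeError):
    """SCF failure (non-convergence, singular overlap, bad inputs)."""

    def __init__(self, message, last_energy=None):
        super().__init__(message)
        self.last_energy = last_energy


# ------------------------------------------------------------------ basis

@dataclass(frozen=True)
class Shell:
    """One radial shell: a fixed contraction of primitives of a single l.

    ``coefs`` refer to *normalized* primitives; a free primitive is the
    special case of a single unit coefficient.
    """

    l: int
    exps: tuple
    coefs: tuple

    def __post_init__(self):
        if len(self.exps) != len(self.coefs) or not self.exps:
            raise ValueError("exps and coefs must be equal-length and nonempty")
        if any(e <= 0 for e in self.exps):
            raise ValueError("exponents must be positive")


class AOBasis:
    """A list of radial shells expanded into real spherical AO functions.

    Functions are ordered by angular momentum, then by shell, then by the
    real-m component (m = -l..l), so each l makes one contiguous block.
    """

    def __init__(self, shells: Sequence[Shell]):
        self.shells: List[Shell] = sorted(shells, key=lambda s: s.l)
        if not self.shells:
            raise ValueError("empty basis")
        if self.shells[-1].l > gi.MAX_L:
            raise ValueError(f"angular momentum above {gi.MAX_L} not supported")
        self.ls = sorted({s.l for s in self.shells})
        self.shells_by_l: Dict[int, List[int]] = {
            l: [i for i, s in enumerate(self.shells) if s.l == l] for l in self.ls
        }
        # function bookkeeping
        self.fn_shell: List[int] = []
        self.fn_m: List[int] = []  # real-m label, signed
        self.shell_off: List[int] = []
        off = 0
        for i, s in enumerate(self.shells):
            self.shell_off.append(off)
            for m in range(-s.l, s.l + 1):
                self.fn_shell.append(i)
                self.fn_m.append(m)
            off += 2 * s.l + 1
        self.n_fn = off
        self.l_slices: Dict[int, slice] = {}
        for l in self.ls:
            idx = [self.shell_off[i] for i in self.shells_by_l[l]]
            start = idx[0]
            stop = idx[-1] + 2 * l + 1
            self.l_slices[l] = slice(start, stop)

    @classmethod
    def from_primitives(cls, primitives: PrimitiveBasis, extra_shells=()):
        shells = [
            Shell(l=_L_OF[lab], exps=(z,), coefs=(1.0,))
            for lab, series in primitives.channels.items()
            for z in series.exponents
        ]
        return cls(list(shells) + list(extra_shells))

    def radial_coef_arrays(self):
        """Per-shell (exponents, norm-weighted coefficients) arrays."""
        out = []
        for s in self.shells:
            e = np.asarray(s.exps, dtype=float)
            c = np.asarray(s.coefs, dtype=float) * gi.radial_norm(e, s.l)
            out.append((e, c))
        return out


def _radial_pair_matrix(basis: AOBasis, kernel, l_pairs=None):
    """Shell-by-shell radial matrix <R_i | op | R_j> for an l-diagonal op."""
    arr = basis.radial_coef_arrays()
    n = len(basis.shells)
    M = np.zeros((n, n))
    for i in range(n):
        li = basis.shells[i].l
        ei, ci = arr[i]
        for j in range(i, n):
            if basis.shells[j].l != li:
                continue
            ej, cj = arr[j]
            raw = kernel(ei[:, None], ej[None, :], li)
            M[i, j] = M[j, i] = ci @ raw @ cj
    return M


# ------------------------------------------------- one-electron matrices

@dataclass
class OneElectronMatrices:
    """Overlap, kinetic, nuclear-attraction, axial-dipole (and pVp) matrices."""

    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    Dz: np.ndarray
    pVp: np.ndarray

    def core(self) -> np.ndarray:
        return self.T + self.V


def one_center_integrals(basis, Z: float) -> OneElectronMatrices:
    """Analytic one-electron matrices over the AO functions of ``basis``.

    Accepts an :class:`AOBasis`, a :class:`~nmrdkh.welltempered.PrimitiveBasis`
    or a contracted basis exposing ``to_ao_basis``.
    """
    basis = as_ao_basis(basis)
    for l in basis.ls:
        zs = [z for i in basis.shells_by_l[l] for z in basis.shells[i].exps]
        zs = sorted(zs)
        for a, b in zip(zs, zs[1:]):
            if abs(a - b) <= 1e-12 * a:
                warnings.warn(
                    f"duplicate exponent {a:g} in the {_L_LABEL[l]} channel: "
                    "near-singular overlap",
                    stacklevel=2,
                )
    n = basis.n_fn
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    pVp = np.zeros((n, n))
    Dz = np.zeros((n, n))

    Sr = _radial_pair_matrix(basis, gi.overlap_radial)
    Tr = _radial_pair_matrix(basis, gi.kinetic_radial)
    Vr = _radial_pair_matrix(basis, lambda a, b, l: gi.nuclear_radial(a, b, l, Z))
    Pr = _radial_pair_matrix(basis, lambda a, b, l: gi.pvp_radial(a, b, l, Z))
    arr = basis.radial_coef_arrays()
    for i, si in enumerate(basis.shells):
        oi, di = basis.shell_off[i], 2 * si.l + 1
        for j, sj in enumerate(basis.shells):
            oj, dj = basis.shell_off[j], 2 * sj.l + 1
            if si.l == sj.l:
                eye = np.eye(di)
                S[oi : oi + di, oj : oj + dj] = Sr[i, j] * eye
                T[oi : oi + di, oj : oj + dj] = Tr[i, j] * eye
                V[oi : oi + di, oj : oj + dj] = Vr[i, j] * eye
                pVp[oi : oi + di, oj : oj + dj] = Pr[i, j] * eye
            if abs(si.l - sj.l) == 1:
                ei, ci = arr[i]
                ej, cj = arr[j]
                raw = gi.dipole_radial(ei[:, None], ej[None, :], min(si.l, sj.l))
                rad = ci @ raw @ cj
                ang = gi.dipole_angular(si.l, sj.l)
                Dz[oi : oi + di, oj : oj + dj] = rad * ang

    cond = np.linalg.cond(S)
    if cond > 1e14:
        raise SCFError(f"overlap matrix ill-conditioned (cond = {cond:.2e})")
    return OneElectronMatrices(S=S, T=T, V=V, Dz=Dz, pVp=pVp)


# ------------------------------------------------------------------- ERIs

def _pair_tables(basis: AOBasis):
    """Primitive-product tables for every unordered shell pair."""
    arr = basis.radial_coef_arrays()
    nsh = len(basis.shells)
    pid = -np.ones((nsh, nsh), dtype=int)
    P, W, nsum, bounds = [], [], [], []
    for i in range(nsh):
        ei, ci = arr[i]
        for j in range(i, nsh):
            ej, cj = arr[j]
            pid[i, j] = pid[j, i] = len(nsum)
            P.append((ei[:, None] + ej[None, :]).ravel())
            W.append((ci[:, None] * cj[None, :]).ravel())
            nsum.append(basis.shells[i].l + basis.shells[j].l)
    return pid, P, W, np.array(nsum)


def _radial_slater_tables(basis: AOBasis):
    """Dense R^L matrices over all shell pairs, for L = 0 .. 2*l_max."""
    pid, P, W, nsum = _pair_tables(basis)
    npair = len(P)
    lmax = max(basis.ls)
    RL = {L: np.zeros((npair, npair)) for L in range(0, 2 * lmax + 1)}
    # group pairs by their radial power n = l_i + l_j
    groups: Dict[int, List[int]] = {}
    for pidx, n in enumerate(nsum):
        groups.setdefault(int(n), []).append(pidx)
    for n1, ids1 in groups.items():
        U1 = np.concatenate([P[i] for i in ids1])
        s1 = np.cumsum([0] + [len(P[i]) for i in ids1])
        W1 = np.zeros((len(U1), len(ids1)))
        for k, i in enumerate(ids1):
            W1[s1[k] : s1[k + 1], k] = W[i]
        for n2, ids2 in groups.items():
            U2 = np.concatenate([P[i] for i in ids2])
            s2 = np.cumsum([0] + [len(P[i]) for i in ids2])
            W2 = np.zeros((len(U2), len(ids2)))
            for k, i in enumerate(ids2):
                W2[s2[k] : s2[k + 1], k] = W[i]
            for L in range(0, min(n1, n2) + 1):
                if (n1 + L) % 2 or (n2 + L) % 2:
                    continue
                K = gi.slater_rl(U1[:, None], n1, U2[None, :], n2, L)
                RL[L][np.ix_(ids1, ids2)] = W1.T @ K @ W2
    return pid, RL


def two_electron_integrals(basis, max_functions: int = 400) -> np.ndarray:
    """Full ERI tensor (chemists' notation (ab|cd)) over the AO functions.

    Built from the one-center multipole expansion; the tensor carries the
    8-fold permutational symmetry by construction of its factors.  Raises
    for more than ``max_functions`` functions (the dense tensor would not
    fit); such systems should contract Coulomb/exchange on the fly.
    """
    basis = as_ao_basis(basis)
    n = basis.n_fn
    if n > max_functions:
        raise MemoryError(
            f"{n} basis functions would need a {8 * n**4 / 1e9:.1f} GB ERI "
            "tensor; use an on-the-fly Fock build instead"
        )
    pid, RL = _radial_slater_tables(basis)
    eri = np.zeros((n, n, n, n))
    for lA in basis.ls:
        shA = basis.shells_by_l[lA]
        for lB in basis.ls:
            shB = basis.shells_by_l[lB]
            pAB = pid[np.ix_(shA, shB)]
            for lC in basis.ls:
                shC = basis.shells_by_l[lC]
                for lD in basis.ls:
                    shD = basis.shells_by_l[lD]
                    pCD = pid[np.ix_(shC, shD)]
                    block = None
                    for L in range(
                        max(abs(lA - lB), abs(lC - lD)), min(lA + lB, lC + lD) + 1
                    ):
                        if (lA + lB + L) % 2 or (lC + lD + L) % 2:
                            continue
                        G1 = gi.real_gaunt(lA, lB, L)
                        G2 = gi.real_gaunt(lC, lD, L)
                        theta = (
                            4.0
                            * math.pi
                            / (2 * L + 1)
                            * np.einsum("abM,cdM->abcd", G1, G2)
                        )
                        if not np.any(theta):
                            continue
                        R4 = RL[L][pAB.ravel()][:, pCD.ravel()].reshape(
                            len(shA), len(shB), len(shC), len(shD)
                        )
                        contrib = np.multiply.outer(R4, theta)
                        block = contrib if block is None else block + contrib
                    if block is None:
                        continue
                    # (A,B,C,D, ma,mb,mc,md) -> (A,ma, B,mb, C,mc, D,md)
                    block = block.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
                        len(shA) * (2 * lA + 1),
                        len(shB) * (2 * lB + 1),
                        len(shC) * (2 * lC + 1),
                        len(shD) * (2 * lD + 1),
                    )
                    eri[
                        basis.l_slices[lA],
                        basis.l_slices[lB],
                        basis.l_slices[lC],
                        basis.l_slices[lD],
                    ] = block
    return eri


# ------------------------------------------------------------------- DKH2

def dkh2_transform(S, T, V, pVp, c_light: float = C_LIGHT) -> np.ndarray:
    """Scalar second-order Douglas-Kroll-Hess one-electron Hamiltonian.

    Diagonalizes the kinetic energy in the S-orthonormal basis, applies the
    free-particle Foldy-Wouthuysen kinematic factors to V and pVp, adds the
    second-order even term built from the odd block through the standard
    energy denominators, and back-transforms to the original basis.
    """
    S = np.asarray(S, dtype=float)
    ew = np.linalg.eigvalsh(S)
    if ew[0] <= 0:
        raise SCFError("overlap matrix not positive definite")
    # canonical orthogonalization, then kinetic eigenbasis
    w, U = np.linalg.eigh(S)
    X = U / np.sqrt(w)
    t, Ut = np.linalg.eigh(X.T @ T @ X)
    t = np.clip(t, 1e-14, None)
    Bt = X @ Ut  # AO -> p2 eigenbasis coefficients
    p2 = 2.0 * t
    p = np.sqrt(p2)
    c = float(c_light)
    Ep = c * np.sqrt(p2 + c * c)
    A = np.sqrt((Ep + c * c) / (2.0 * Ep))
    Kf = c / (Ep + c * c)

    Vp = Bt.T @ V @ Bt
    Wp = Bt.T @ pVp @ Bt

    E0 = p2 / (np.sqrt(p2 / (c * c) + 1.0) + 1.0)  # Ep - c^2, cancellation-free
    AVA = A[:, None] * Vp * A[None, :]
    APVPA = (A * Kf)[:, None] * Wp * (A * Kf)[None, :]
    E1 = AVA + APVPA

    # odd (large-small) block and its energy-weighted partner
    odd = A[:, None] * A[None, :] * (
        (Kf * p)[:, None] * (Wp / (p[:, None] * p[None, :]))
        - Vp * (p * Kf)[None, :]
    )
    Wmat = odd / (Ep[:, None] + Ep[None, :])
    E2 = 0.5 * (Wmat @ odd.T + odd @ Wmat.T)

    Hp = np.diag(E0) + E1 + E2
    back = S @ Bt
    return back @ Hp @ back.T


# ------------------------------------------------------------ atom systems

@dataclass(frozen=True)
class AtomSystem:
    """Nuclear charge, spin occupations, Hamiltonian level and field."""

    Z: float
    occupations: dict  # l -> (alpha per-m occupations, beta per-m occupations)
    field_F: float = 0.0
    hamiltonian: str = "NR"  # "NR" | "DKH2"
    c_light: float = C_LIGHT

    def __post_init__(self):
        if self.hamiltonian not in ("NR", "DKH2"):
            raise ValueError("hamiltonian must be 'NR' or 'DKH2'")
        for l, (oa, ob) in self.occupations.items():
            if any(not 0.0 <= o <= 1.0 for o in tuple(oa) + tuple(ob)):
                raise ValueError("fractional occupations must lie in [0, 1]")

    @property
    def n_alpha(self) -> float:
        return sum((2 * l + 1) * sum(oa) for l, (oa, _) in self.occupations.items())

    @property
    def n_beta(self) -> float:
        return sum((2 * l + 1) * sum(ob) for l, (_, ob) in self.occupations.items())


def ti_ground_state(field_F: float = 0.0, hamiltonian: str = "DKH2") -> AtomSystem:
    """Neutral Ti, [Ar]4s2 3d2, spherically averaged (3F term).

    The two d electrons are alpha-spin, spread 0.4 per d orbital over the
    five alpha d spin-orbitals; 12 alpha + 10 beta = 22 electrons.
    """
    occ = {
        0: ((1.0, 1.0, 1.0, 1.0), (1.0, 1.0, 1.0, 1.0)),  # 1s2s3s4s
        1: ((1.0, 1.0), (1.0, 1.0)),  # 2p3p
        2: ((0.4,), ()),  # 3d^2, spherically averaged, parallel spins
    }
    return AtomSystem(Z=22.0, occupations=occ, field_F=field_F, hamiltonian=hamiltonian)


def hydrogenic(Z: float = 1.0) -> AtomSystem:
    return AtomSystem(Z=Z, occupations={0: ((1.0,), ())})


def as_ao_basis(basis) -> AOBasis:
    if isinstance(basis, AOBasis):
        return basis
    if isinstance(basis, PrimitiveBasis):
        return AOBasis.from_primitives(basis)
    if hasattr(basis, "to_ao_basis"):
        return basis.to_ao_basis()
    raise TypeError(f"cannot interpret {type(basis).__name__} as a basis")


# -------------------------------------------------------------------- SCF

@dataclass
class SCFResult:
    """Converged (or final) state of a UHF run."""

    E_total: float
    eps_alpha: np.ndarray
    eps_beta: np.ndarray
    C_alpha: np.ndarray
    C_beta: np.ndarray
    occ_alpha: np.ndarray
    occ_beta: np.ndarray
    n_iter: int
    converged: bool
    hamiltonian: str
    basis: AOBasis
    blocks: list  # list of (label, index array)
    S: np.ndarray = field(repr=False, default=None)
    E_kinetic: float = 0.0
    E_potential: float = 0.0

    def orbital_block_coefficients(self, l: int, spin: str = "alpha"):
        """Radial coefficient matrix and energies for one (l, m=0) block.

        Returns (eps, C) with C[(shell index within l), orbital]; valid for
        zero-field runs where blocks are (l, m)-pure.
        """
        C = self.C_alpha if spin == "alpha" else self.C_beta
        eps = self.eps_alpha if spin == "alpha" else self.eps_beta
        for label, idx in self.blocks:
            if label == (l, 0):
                e = eps[idx]
                order = np.argsort(e)
                sub = C[np.ix_(idx, idx)]
                return e[order], sub[:, order]
        raise KeyError(f"no (l={l}, m=0) block; run was field-on or l absent")


def _symmetry_blocks(basis: AOBasis, field_on: bool):
    """Index sets of symmetry-equivalent function groups.

    Zero field: one block per (l, m).  Axial field: one block per real-m
    label (the field preserves m and parity about the field axis).
    """
    blocks: Dict[object, List[int]] = {}
    for fi in range(basis.n_fn):
        sh = basis.shells[basis.fn_shell[fi]]
        m = basis.fn_m[fi]
        label = m if field_on else (sh.l, m)
        blocks.setdefault(label, []).append(fi)
    return [(lab, np.array(idx)) for lab, idx in sorted(blocks.items(), key=str)]


def _block_occupations(system: AtomSystem, basis: AOBasis, blocks, field_on: bool):
    """Per-block descending occupation weights for each spin."""
    out = []
    for label, idx in blocks:
        if field_on:
            ls = sorted({basis.shells[basis.fn_shell[i]].l for i in idx})
            oa = sorted(
                (o for l in ls for o in system.occupations.get(l, ((), ()))[0]),
                reverse=True,
            )
            ob = sorted(
                (o for l in ls for o in system.occupations.get(l, ((), ()))[1]),
                reverse=True,
            )
        else:
            l, _m = label
            oa, ob = system.occupations.get(l, ((), ()))
            oa, ob = sorted(oa, reverse=True), sorted(ob, reverse=True)
        out.append((list(oa), list(ob)))
    return out


class _DIIS:
    def __init__(self, window: int = 8):
        self.window = window
        self.focks: List[Tuple[np.ndarray, np.ndarray]] = []
        self.errs: List[np.ndarray] = []

    def push(self, fa, fb, err):
        self.focks.append((fa.copy(), fb.copy()))
        self.errs.append(err.copy())
        if len(self.errs) > self.window:
            self.focks.pop(0)
            self.errs.pop(0)

    def extrapolate(self):
        m = len(self.errs)
        if m < 2:
            return None
        Bm = np.empty((m + 1, m + 1))
        Bm[-1, :] = -1.0
        Bm[:, -1] = -1.0
        Bm[-1, -1] = 0.0
        for i in range(m):
            for j in range(m):
                Bm[i, j] = float(self.errs[i] @ self.errs[j])
        rhs = np.zeros(m + 1)
        rhs[-1] = -1.0
        try:
            coef = np.linalg.solve(Bm, rhs)[:m]
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(coef)) or np.abs(coef).max() > 1e6:
            return None
        fa = sum(c * f[0] for c, f in zip(coef, self.focks))
        fb = sum(c * f[1] for c, f in zip(coef, self.focks))
        return fa, fb


def uhf_scf(
    system: AtomSystem,
    basis,
    eri: Optional[np.ndarray] = None,
    ints: Optional[OneElectronMatrices] = None,
    max_iter: int = 200,
    e_tol: float = 1e-10,
    g_tol: float = 1e-7,
    guess: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> SCFResult:
    """Converge the UHF equations for a one-center system.

    Deterministic: core-Hamiltonian guess (unless ``guess`` densities are
    given), DIIS acceleration with damping fallback.  Raises
    :class:`SCFError` carrying the last energy on non-convergence.
    """
    basis = as_ao_basis(basis)
    if ints is None:
        ints = one_center_integrals(basis, system.Z)
    S = ints.S
    if system.hamiltonian == "DKH2":
        h = np.zeros_like(S)
        # DKH2 is block-diagonal in l for a spherical potential
        for l in basis.ls:
            sl = basis.l_slices[l]
            h[sl, sl] = dkh2_transform(
                S[sl, sl], ints.T[sl, sl], ints.V[sl, sl], ints.pVp[sl, sl],
                system.c_light,
            )
    else:
        h = ints.T + ints.V
    field_on = system.field_F != 0.0
    if field_on:
        h = h + system.field_F * ints.Dz
    if eri is None:
        eri = two_electron_integrals(basis)
    n = basis.n_fn
    eri_mat = eri.reshape(n * n, n * n)
    # exchange layout (pr|qs): transpose axes 1<->2 once
    eri_k = np.ascontiguousarray(eri.transpose(0, 2, 1, 3)).reshape(n * n, n * n)

    blocks = _symmetry_blocks(basis, field_on)
    occs = _block_occupations(system, basis, blocks, field_on)

    w, U = np.linalg.eigh(S)
    if w[0] < 1e-14 * w[-1]:
        raise SCFError("singular overlap matrix")
    X = U / np.sqrt(w)

    def diag_blocks(Fa, Fb):
        Ca = np.zeros((n, n))
        Cb = np.zeros((n, n))
        ea = np.full(n, np.inf)
        eb = np.full(n, np.inf)
        oa = np.zeros(n)
        ob = np.zeros(n)
        orb_map: Dict[object, List[int]] = {}
        for (label, idx), (wa, wb) in zip(blocks, occs):
            Sb = S[np.ix_(idx, idx)]
            for F, C, e, o, wts in ((Fa, Ca, ea, oa, wa), (Fb, Cb, eb, ob, wb)):
                ev, vec = scipy.linalg.eigh(F[np.ix_(idx, idx)], Sb)
                C[np.ix_(idx, idx)] = vec
                e[idx] = ev
                for k, wt in enumerate(wts):
                    o[idx[k]] = wt
            orb_map[label] = list(idx)
        return Ca, Cb, ea, eb, oa, ob, orb_map

    def density(C, occ):
        return (C * occ[None, :]) @ C.T

    def fock(Da, Db):
        Dt = (Da + Db).ravel()
        J = (eri_mat @ Dt).reshape(n, n)
        Ka = (eri_k @ Da.ravel()).reshape(n, n)
        Kb = (eri_k @ Db.ravel()).reshape(n, n)
        return h + J - Ka, h + J - Kb, J, Ka, Kb

    def energy(Da, Db, J, Ka, Kb):
        one = np.sum((Da + Db) * h)
        two = 0.5 * (np.sum((Da + Db) * J) - np.sum(Da * Ka) - np.sum(Db * Kb))
        return one + two

    if guess is not None:
        Da, Db = guess
    else:
        Ca, Cb, ea, eb, oa, ob, _ = diag_blocks(h, h)
        Da, Db = density(Ca, oa), density(Cb, ob)

    diis = _DIIS()
    E_old = np.inf
    converged = False
    it = 0
    Fa_old = Fb_old = None
    for it in range(1, max_iter + 1):
        Fa, Fb, J, Ka, Kb = fock(Da, Db)
        E = energy(Da, Db, J, Ka, Kb)
        erra = X.T @ (Fa @ Da @ S - S @ Da @ Fa) @ X
        errb = X.T @ (Fb @ Db @ S - S @ Db @ Fb) @ X
        gmax = max(np.abs(erra).max(), np.abs(errb).max())
        if abs(E - E_old) < e_tol and gmax < g_tol:
            converged = True
            break
        E_old = E
        diis.push(Fa, Fb, np.concatenate([erra.ravel(), errb.ravel()]))
        ext = diis.extrapolate()
        if ext is not None:
            Fa_use, Fb_use = ext
        elif Fa_old is not None:
            Fa_use = 0.7 * Fa + 0.3 * Fa_old
            Fb_use = 0.7 * Fb + 0.3 * Fb_old
        else:
            Fa_use, Fb_use = Fa, Fb
        Fa_old, Fb_old = Fa_use, Fb_use
        Ca, Cb, ea, eb, oa, ob, orb_map = diag_blocks(Fa_use, Fb_use)
        Da, Db = density(Ca, oa), density(Cb, ob)

    Fa, Fb, J, Ka, Kb = fock(Da, Db)
    E = energy(Da, Db, J, Ka, Kb)
    Ca, Cb, ea, eb, oa, ob, orb_map = diag_blocks(Fa, Fb)
    if not converged:
        raise SCFError(
            f"SCF not converged in {max_iter} iterations (E = {E:.10f})",
            last_energy=E,
        )
    Ek = float(np.sum((Da + Db) * ints.T))
    res = SCFResult(
        E_total=float(E),
        eps_alpha=ea,
        eps_beta=eb,
        C_alpha=Ca,
        C_beta=Cb,
        occ_alpha=oa,
        occ_beta=ob,
        n_iter=it,
        converged=converged,
        hamiltonian=system.hamiltonian,
        basis=basis,
        blocks=blocks,
        S=S,
        E_kinetic=Ek,
        E_potential=float(E) - Ek,
    )
    res._block_orbs = orb_map
    res._density = (Da, Db)
    return res


# ----------------------------------------------- f-exponent optimization

def optimize_f_exponents(
    system: AtomSystem,
    base_basis,
    n_f: int = 3,
    field_F: float = 0.01,
    start: Optional[Sequence[float]] = None,
    f_tol: float = 1e-8,
    max_iter_opt: int = 400,
    scf_kwargs: Optional[dict] = None,
) -> np.ndarray:
    """Optimize f-polarization exponents against the field-perturbed energy.

    Minimizes the UHF total energy of ``system`` (with the axial field
    ``field_F`` switched on) over ``n_f`` independent f exponents added to
    ``base_basis``, using Nelder-Mead in log-exponent space with warm-started
    SCF densities.  Returns the exponents in descending order.

    With no field and no occupied f shell the objective is flat; that case
    is detected and flagged with a warning, returning the start exponents.
    """
    base = as_ao_basis(base_basis)
    scf_kwargs = dict(scf_kwargs or {})
    scf_kwargs.setdefault("e_tol", 1e-10)
    scf_kwargs.setdefault("g_tol", 1e-6)
    sysF = replace(system, field_F=field_F)
    if start is None:
        start = np.geomspace(3.0, 0.3, n_f)
    start = np.sort(np.asarray(start, dtype=float))[::-1]

    def make_basis(fexps):
        shells = list(base.shells) + [
            Shell(l=3, exps=(float(z),), coefs=(1.0,)) for z in fexps
        ]
        return AOBasis(shells)

    def objective(logx):
        fexps = np.exp(logx)
        if fexps.max() > 5e3 or fexps.min() < 1e-4:
            return 1e6  # keep the simplex in a sane region
        b = make_basis(fexps)
        try:
            res = uhf_scf(sysF, b, guess=None, **scf_kwargs)
        except SCFError as exc:
            if exc.last_energy is None:
                raise
            return float(exc.last_energy)
        return res.E_total

    x0 = np.log(start)
    e0 = objective(x0)
    probe = objective(x0 + 0.05)
    if abs(probe - e0) < 1e-9:
        warnings.warn(
            "flat objective: the field-free atomic energy is insensitive to "
            "the f exponents (no occupied f character); returning the start "
            "exponents",
            stacklevel=2,
        )
        return start

    res = scipy.optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "fatol": f_tol,
            "xatol": 1e-4,
            "maxfev": max_iter_opt,
            "initial_simplex": x0[None, :] + 0.15 * np.vstack(
                [np.zeros(n_f), np.eye(n_f)]
            ),
        },
    )
    if not res.success and res.fun > e0:
        raise SCFError(f"f-exponent optimization failed: {res.message}")
    fexps = np.sort(np.exp(res.x))[::-1]
    ratios = fexps[:-1] / fexps[1:]
    if np.any(ratios < 1.2):
        warnings.warn(
            f"near-collapsing f exponents (ratio {ratios.min():.3f} < 1.2)",
            stacklevel=2,
        )
    return fexps
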