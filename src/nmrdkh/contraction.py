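"""Segmented contraction of the primitive set from atomic SCF coefficients.

The target pattern is a strictly segmented triple-zeta contraction in which
only the innermost (largest-exponent) primitives of each channel form a
single contracted function and every remaining primitive stays free:

    (18s 11p 6d 3f)  ->  [12s 6p 3d 2f]

so the single contracted segment of a channel holds
``n_prim - (n_contr - 1)`` primitives (7s / 6p / 4d / 2f for titanium).
The segment coefficients are read from the deepest converged atomic
orbital of that symmetry (1s, 2p, 3d) of a scalar-relativistic UHF run,
restricted to the segment primitives and renormalized; the f segment takes
the f-channel components of the lowest field-perturbed orbital with f
character.  Each contracted column is normalized under the overlap metric
and signed so its innermost coefficient is positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _integrals as gi
from .atomic_scf import AOBasis, SCFResult, Shell
from .welltempered import PrimitiveBasis

__all__ = [
    "ContractionScheme",
    "ContractedBasis",
    "parse_scheme",
    "derive_segments",
    "build_contraction",
    "count_functions",
    "TI_SCHEME",
]

TI_SCHEME = "(18s11p6d3f)->[12s6p3d2f]"

_L_OF = {"s": 0, "p": 1, "d": 2, "f": 3}
_L_LABEL = "spdf"
_SPHERICAL_MULT = {0: 1, 1: 3, 2: 5, 3: 7}
_CARTESIAN_MULT = {0: 1, 1: 3, 2: 6, 3: 10}


@dataclass(frozen=True)
class ContractionScheme:
    """Per-channel primitive/contracted counts and segment layout."""

    channels: tuple  # tuple of (l label, n_prim, n_contr)

    def counts(self) -> Dict[str, Tuple[int, int]]:
        return {l: (np_, nc) for l, np_, nc in self.channels}

    def segments(self, l: str) -> List[int]:
        for lab, np_, nc in self.channels:
            if lab == l:
                return _segment_sizes(np_, nc)
        raise KeyError(f"channel {l!r} not in scheme")


def _segment_sizes(n_prim: int, n_contr: int) -> List[int]:
    head = n_prim - (n_contr - 1)
    return [head] + [1] * (n_contr - 1)


_SCHEME_RE = re.compile(
    r"^\(\s*((?:\d+[spdf])+)\s*\)\s*(?:->|→)\s*\[\s*((?:\d+[spdf])+)\s*\]$"
)
_PART_RE = re.compile(r"(\d+)([spdf])")


def parse_scheme(text: str) -> ContractionScheme:
    """Parse ``(18s11p6d3f)->[12s6p3d2f]`` style contraction notation."""
    m = _SCHEME_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed contraction scheme: {text!r}")
    prim = {l: int(n) for n, l in _PART_RE.findall(m.group(1))}
    contr = {l: int(n) for n, l in _PART_RE.findall(m.group(2))}
    if set(prim) != set(contr):
        raise ValueError(
            f"channel mismatch between primitive ({sorted(prim)}) and "
            f"contracted ({sorted(contr)}) sides"
        )
    chans = []
    for l in "spdf":
        if l not in prim:
            continue
        if contr[l] > prim[l]:
            raise ValueError(
                f"channel {l}: cannot contract {prim[l]} primitives into "
                f"{contr[l]} functions"
            )
        if contr[l] < 1:
            raise ValueError(f"channel {l}: need at least one contracted function")
        chans.append((l, prim[l], contr[l]))
    return ContractionScheme(channels=tuple(chans))


def derive_segments(scheme: ContractionScheme) -> Dict[str, List[int]]:
    """Segment layout per channel: one leading contracted segment, rest free.

    The leading segment collects the largest exponents; its size is forced
    by the counts (n_prim - n_contr + 1).
    """
    return {l: _segment_sizes(np_, nc) for l, np_, nc in scheme.channels}


def count_functions(scheme, spherical: bool = True) -> Tuple[int, int]:
    """(primitive GTO count, contracted CGTO count) including m multiplicity."""
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    mult = _SPHERICAL_MULT if spherical else _CARTESIAN_MULT
    n_gto = sum(np_ * mult[_L_OF[l]] for l, np_, _ in scheme.channels)
    n_cgto = sum(nc * mult[_L_OF[l]] for l, _, nc in scheme.channels)
    return n_gto, n_cgto


@dataclass
class ContractedBasis:
    """The deliverable basis: per-shell exponents and coefficient columns."""

    element: str
    shells: list  # list of (l label, exponents tuple, coefficients tuple)
    scheme_text: str = ""
    provenance: dict = field(default_factory=dict)

    def shell_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for l, _, _ in self.shells:
            out[l] = out.get(l, 0) + 1
        return out

    def to_ao_basis(self) -> AOBasis:
        return AOBasis(
            [Shell(l=_L_OF[l], exps=tuple(e), coefs=tuple(c)) for l, e, c in self.shells]
        )

    def channel_shells(self, l: str):
        return [(e, c) for lab, e, c in self.shells if lab == l]


def _normalize_segment(exps: np.ndarray, coefs: np.ndarray, l: int) -> np.ndarray:
    """Normalize a contracted column under the overlap metric, sign-fixed."""
    norms = gi.radial_norm(exps, l)
    w = coefs * norms
    Sseg = gi.overlap_radial(exps[:, None], exps[None, :], l)
    nrm2 = w @ Sseg @ w
    if nrm2 <= 0 or not np.isfinite(nrm2):
        raise ValueError("zero-norm contracted segment")
    out = coefs / np.sqrt(nrm2)
    if out[0] < 0:
        out = -out
    return out


def _deepest_orbital_coefs(scf: SCFResult, l: int) -> np.ndarray:
    """Radial coefficients of the lowest orbital of angular momentum l."""
    eps, C = scf.orbital_block_coefficients(l, spin="alpha")
    return C[:, 0]


def _lowest_f_orbital_coefs(scf_field: SCFResult, weight_tol: float = 0.2) -> np.ndarray:
    """f-channel coefficients of the lowest field-perturbed orbital with
    appreciable f character, from the m = 0 symmetry block."""
    basis = scf_field.basis
    for label, idx in scf_field.blocks:
        if label == 0:  # real-m = 0 block of a field-on run
            idx = np.asarray(idx)
            f_rows = np.array(
                [basis.shells[basis.fn_shell[i]].l == 3 for i in idx]
            )
            if not f_rows.any():
                break
            eps = scf_field.eps_alpha[idx]
            C = scf_field.C_alpha[np.ix_(idx, idx)]
            Sb = scf_field.S[np.ix_(idx, idx)]
            SC = Sb @ C
            # Mulliken-style f weight per orbital
            wf = np.sum(C[f_rows] * SC[f_rows], axis=0)
            order = np.argsort(eps)
            for k in order:
                if wf[k] >= weight_tol:
                    return C[f_rows, k]
            raise ValueError(
                f"no orbital with f weight >= {weight_tol} in the m=0 block"
            )
    raise ValueError("field-on SCF result with f shells required")


def build_contraction(
    scf: SCFResult,
    primitives: PrimitiveBasis,
    scheme,
    f_exponents: Optional[Sequence[float]] = None,
    scf_field: Optional[SCFResult] = None,
    element: str = "Ti",
) -> ContractedBasis:
    """Assemble the segmented contracted basis from SCF orbital coefficients.

    ``scf`` is the converged zero-field run on the primitive s/p/d set;
    ``scf_field`` (required when the scheme has an f channel) the field-on
    run including the optimized f primitives.
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    if not scf.converged:
        raise ValueError("refusing to contract from an unconverged SCF")
    segments = derive_segments(scheme)
    shells: List[Tuple[str, tuple, tuple]] = []
    for lab, n_prim, n_contr in scheme.channels:
        l = _L_OF[lab]
        if lab == "f":
            if f_exponents is None or scf_field is None:
                raise ValueError(
                    "f channel requires f_exponents and a field-on SCF result"
                )
            exps = np.sort(np.asarray(f_exponents, dtype=float))[::-1]
            if len(exps) != n_prim:
                raise ValueError(
                    f"scheme wants {n_prim} f primitives, got {len(exps)}"
                )
            coefs_full = _lowest_f_orbital_coefs(scf_field)
        else:
            series = primitives.channels[lab]
            exps = np.asarray(series.exponents, dtype=float)
            if len(exps) != n_prim:
                raise ValueError(
                    f"scheme wants {n_prim} {lab} primitives, basis has {len(exps)}"
                )
            coefs_full = _deepest_orbital_coefs(scf, l)
        head = segments[lab][0]
        c_seg = _normalize_segment(exps[:head], np.asarray(coefs_full)[:head], l)
        shells.append((lab, tuple(exps[:head]), tuple(c_seg)))
        for z in exps[head:]:
            shells.append((lab, (float(z),), (1.0,)))
    prim_txt = "".join(f"{np_}{lab}" for lab, np_, _ in scheme.channels)
    contr_txt = "".join(f"{nc}{lab}" for lab, _, nc in scheme.channels)
    return ContractedBasis(
        element=element,
        shells=shells,
        scheme_text=f"({prim_txt})->[{contr_txt}]",
        provenance={"hamiltonian": scf.hamiltonian},
    )
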