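"""Read, write and compare basis sets in common exchange dialects.

Supported dialects:

``gaussian``
    General-basis ("gen") input block: ``Ti 0`` element header, per-shell
    ``<L>  <nprim>  1.00`` lines, exponent/coefficient rows in Fortran
    D-notation at 14 significant digits, ``****`` terminator.
``nwchem``
    ``basis "ti nmr-dkh" SPHERICAL`` block with ``Ti <L>`` shell headers.
``json``
    Exchange-style JSON carrying full double precision; this is the native
    archival dialect (write -> read is bit-exact).

The comparison helper aligns shells, signs and tolerances to report
exponent/coefficient differences against an external reference file, e.g.
a published basis-set-exchange download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .contraction import ContractedBasis

__all__ = [
    "BasisDocument",
    "write_basis",
    "read_basis",
    "compare_basis",
    "render_deck",
    "BasisParseError",
]

_L_OF = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}
_L_LABEL = "spdfg"


class BasisParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class BasisDocument:
    """Element symbol plus per-shell exponent/coefficient tables."""

    element: str
    shells: list  # list of (l label, exponents tuple, coefficients tuple)
    dialect: str = "json"
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_contracted(cls, basis: ContractedBasis, dialect: str = "json"):
        return cls(
            element=basis.element,
            shells=[(l, tuple(e), tuple(c)) for l, e, c in basis.shells],
            dialect=dialect,
            metadata=dict(basis.provenance, scheme=basis.scheme_text),
        )

    def shell_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for l, _, _ in self.shells:
            out[l] = out.get(l, 0) + 1
        return out


def _fmt_d(x: float) -> str:
    """Fortran D-notation with 14 significant digits."""
    s = f"{x:.13E}"
    mant, expo = s.split("E")
    return f"{mant}D{int(expo):+03d}"


def write_basis(basis, dialect: str) -> str:
    """Serialize a basis to text in the requested dialect."""
    if isinstance(basis, ContractedBasis):
        doc = BasisDocument.from_contracted(basis, dialect)
    elif isinstance(basis, BasisDocument):
        doc = basis
    else:
        raise TypeError("expected ContractedBasis or BasisDocument")
    if dialect == "json":
        payload = {
            "element": doc.element,
            "shells": [
                {"l": l, "exponents": list(e), "coefficients": list(c)}
                for l, e, c in doc.shells
            ],
            "metadata": doc.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if dialect == "gaussian":
        lines = [f"{doc.element:<2s} 0"]
        for l, exps, coefs in doc.shells:
            lines.append(f"{l.upper():<1s}   {len(exps)}   1.00")
            for z, c in zip(exps, coefs):
                lines.append(f"      {_fmt_d(z):>20s}  {_fmt_d(c):>20s}")
        lines.append("****")
        return "\n".join(lines) + "\n"
    if dialect == "nwchem":
        lines = [f'basis "{doc.element.lower()} nmr-dkh" SPHERICAL']
        for l, exps, coefs in doc.shells:
            lines.append(f"{doc.element} {l}")
            for z, c in zip(exps, coefs):
                lines.append(f"      {_fmt_d(z).replace('D', 'E'):>20s}  "
                             f"{_fmt_d(c).replace('D', 'E'):>20s}")
        lines.append("end")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def _to_float(tok: str, lineno: int) -> float:
    try:
        return float(tok.replace("D", "E").replace("d", "e"))
    except ValueError:
        raise BasisParseError(f"bad number {tok!r}", lineno) from None


def read_basis(text: str, dialect: str) -> BasisDocument:
    """Parse basis text in a supported dialect into a BasisDocument."""
    if dialect == "json":
        payload = json.loads(text)
        return BasisDocument(
            element=payload["element"],
            shells=[
                (s["l"], tuple(s["exponents"]), tuple(s["coefficients"]))
                for s in payload["shells"]
            ],
            dialect="json",
            metadata=payload.get("metadata", {}),
        )
    if dialect == "gaussian":
        return _read_gaussian(text)
    if dialect == "nwchem":
        return _read_nwchem(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gaussian(text: str) -> BasisDocument:
    lines = text.splitlines()
    i = 0
    # skip blanks/comments
    while i < len(lines) and (not lines[i].strip() or lines[i].lstrip().startswith("!")):
        i += 1
    if i >= len(lines):
        raise BasisParseError("empty basis block", i + 1)
    element = lines[i].split()[0]
    i += 1
    shells = []
    while i < len(lines):
        line = lines[i].strip()
        if line == "****":
            return BasisDocument(element=element, shells=shells, dialect="gaussian")
        parts = line.split()
        if len(parts) < 2 or parts[0].lower() not in _L_OF:
            raise BasisParseError(f"expected shell header, got {line!r}", i + 1)
        l = parts[0].lower()
        try:
            nprim = int(parts[1])
        except ValueError:
            raise BasisParseError(f"bad primitive count {parts[1]!r}", i + 1) from None
        exps, coefs = [], []
        for k in range(nprim):
            i += 1
            if i >= len(lines):
                raise BasisParseError(
                    f"truncated shell: expected {nprim} primitive rows", i
                )
            toks = lines[i].split()
            if len(toks) < 2:
                raise BasisParseError("expected exponent and coefficient", i + 1)
            exps.append(_to_float(toks[0], i + 1))
            coefs.append(_to_float(toks[1], i + 1))
        shells.append((l, tuple(exps), tuple(coefs)))
        i += 1
    raise BasisParseError("missing '****' terminator", len(lines))


def _read_nwchem(text: str) -> BasisDocument:
    lines = text.splitlines()
    element = None
    shells = []
    cur: Optional[Tuple[str, list, list]] = None
    for ln, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("basis"):
            continue
        if line.lower() == "end":
            if cur:
                shells.append((cur[0], tuple(cur[1]), tuple(cur[2])))
            if element is None:
                raise BasisParseError("no shells found", ln)
            return BasisDocument(element=element, shells=shells, dialect="nwchem")
        parts = line.split()
        if len(parts) == 2 and parts[1].lower() in _L_OF:
            if cur:
                shells.append((cur[0], tuple(cur[1]), tuple(cur[2])))
            element = parts[0]
            cur = (parts[1].lower(), [], [])
        elif cur is not None and len(parts) >= 2:
            cur[1].append(_to_float(parts[0], ln))
            cur[2].append(_to_float(parts[1], ln))
        else:
            raise BasisParseError(f"unexpected content {line!r}", ln)
    raise BasisParseError("missing 'end' terminator", len(lines))


# ------------------------------------------------------------- comparison

@dataclass
class ShellDiff:
    l: str
    index: int
    max_rel_exp: float
    max_abs_coef: float


@dataclass
class BasisDiff:
    structural: bool
    message: str
    shells: list
    max_rel_exp: float
    max_abs_coef: float
    exponents_match: bool
    coefficients_match: bool

    def __str__(self) -> str:
        if self.structural:
            return f"structural difference: {self.message}"
        return (
            f"max rel exponent diff {self.max_rel_exp:.3e} "
            f"({'ok' if self.exponents_match else 'EXCEEDS tol'}), "
            f"max abs coefficient diff {self.max_abs_coef:.3e} "
            f"({'ok' if self.coefficients_match else 'EXCEEDS tol'})"
        )


def compare_basis(a: BasisDocument, b: BasisDocument,
                  tol_exp: float = 1e-9, tol_coef: float = 1e-6) -> BasisDiff:
    """Shell-by-shell diff report; structural mismatches are reported, not raised."""
    if a.element.lower() != b.element.lower():
        raise ValueError(f"different elements: {a.element} vs {b.element}")
    sig_a = [(l, len(e)) for l, e, _ in a.shells]
    sig_b = [(l, len(e)) for l, e, _ in b.shells]
    if sig_a != sig_b:
        return BasisDiff(
            structural=True,
            message=f"shell structure differs: {sig_a} vs {sig_b}",
            shells=[],
            max_rel_exp=float("inf"),
            max_abs_coef=float("inf"),
            exponents_match=False,
            coefficients_match=False,
        )
    diffs = []
    for k, ((l, ea, ca), (_, eb, cb)) in enumerate(zip(a.shells, b.shells)):
        ea, eb = np.asarray(ea), np.asarray(eb)
        ca, cb = np.asarray(ca), np.asarray(cb)
        rel = np.abs(ea - eb) / np.maximum(np.abs(ea), np.abs(eb))
        # sign alignment: a contracted column is defined up to global sign
        if np.dot(ca, cb) < 0:
            cb = -cb
        diffs.append(ShellDiff(l, k, float(rel.max()), float(np.abs(ca - cb).max())))
    mre = max(d.max_rel_exp for d in diffs)
    mac = max(d.max_abs_coef for d in diffs)
    return BasisDiff(
        structural=False,
        message="",
        shells=diffs,
        max_rel_exp=mre,
        max_abs_coef=mac,
        exponents_match=mre <= tol_exp,
        coefficients_match=mac <= tol_coef,
    )


# ----------------------------------------------------------- input decks

_DECK_STEPS = {
    "opt": {
        "route": "#P BLYP/def2SVP Opt Freq SCRF=(IEFPCM,Solvent={solvent},Read)",
        "title": "geometry optimization, BLYP/def2-SVP/IEF-PCM(UFF)",
        "basis": False,
    },
    "nmr": {
        "route": "#P OLYP NMR=GIAO Gen SCRF=(IEFPCM,Solvent={solvent},Read)",
        "title": "Ti-49 shielding, GIAO-OLYP/NMR-DKH/IEF-PCM(UFF)",
        "basis": True,
    },
}


def render_deck(step: str, xyz: str, basis=None, solvent: str = "Chloroform",
                charge: int = 0, multiplicity: int = 1) -> str:
    """Render a ready-to-run external-engine input deck (text only).

    ``step='opt'`` emits the geometry/frequency protocol; ``step='nmr'``
    the GIAO shielding protocol with the basis embedded as a general-basis
    block.  No engine is invoked.
    """
    if step not in _DECK_STEPS:
        raise ValueError(f"unknown step {step!r}; expected one of {sorted(_DECK_STEPS)}")
    spec = _DECK_STEPS[step]
    lines = [spec["route"].format(solvent=solvent), "", spec["title"], "",
             f"{charge} {multiplicity}"]
    lines += [ln.rstrip() for ln in xyz.strip().splitlines()]
    lines.append("")
    if spec["basis"]:
        if basis is None:
            raise ValueError("nmr deck needs the basis to embed")
        lines.append(write_basis(basis, "gaussian").rstrip())
        lines.append("")
    lines.append("Radii=UFF")
    lines.append("")
    return "\n".join(lines)
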