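"""Well-tempered primitive exponent generation.

The primitive radial exponents of each angular-momentum channel form a
descending geometric ladder

    zeta_j = alpha_l * chi**(-j),   j = 0 .. n_prim - 1,

where the maximum exponent ``alpha_l`` is fixed by the innermost radial
extent ``r_l`` of the atomic charge distribution through

    alpha_l = k_l**2 * f_l**2 / (pi * r_l**2),

with dimensionless channel factors ``k_l`` and ``f_l``.  For titanium the
packaged channel constants give an 18s/11p/6d primitive set with spacing
ratios chi = 2.50 (s), 2.75 (p) and 3.00 (d); the f-polarization exponents
are not generated here but optimized variationally (see
:mod:`nmrdkh.atomic_scf`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Optional

__all__ = [
    "ChannelSpec",
    "PrimitiveSeries",
    "PrimitiveBasis",
    "compute_alpha",
    "invert_radius",
    "generate_series",
    "build_ti_primitives",
    "load_ti_channels",
]

_L_LABELS = ("s", "p", "d", "f")


class DegenerateSpacingError(ValueError):
    """Raised when the geometric spacing ratio chi does not exceed 1."""


def compute_alpha(k_l: float, f_l: float, r_l: float) -> float:
    """Maximum channel exponent from the innermost radial value.

    alpha_l = k_l^2 f_l^2 / (pi r_l^2), in bohr^-2 when r_l is in bohr.
    """
    if k_l <= 0 or f_l <= 0 or r_l <= 0:
        raise ValueError("k_l, f_l and r_l must all be positive")
    return (k_l * f_l) ** 2 / (math.pi * r_l**2)


def invert_radius(alpha_l: float, k_l: float, f_l: float) -> float:
    """Innermost radial value consistent with a maximum exponent.

    Closure of :func:`compute_alpha`: r_l = k_l f_l / sqrt(pi alpha_l).
    """
    if alpha_l <= 0 or k_l <= 0 or f_l <= 0:
        raise ValueError("alpha_l, k_l and f_l must all be positive")
    return k_l * f_l / math.sqrt(math.pi * alpha_l)


@dataclass(frozen=True)
class ChannelSpec:
    """Parameters defining one angular-momentum channel of the ladder.

    Either ``alpha_l`` is given directly, or it is derived from
    (``k_l``, ``f_l``, ``r_l``).  If both routes are supplied they must
    agree to 1e-10 relative.
    """

    l: str
    chi: float
    n_prim: int
    alpha_l: Optional[float] = None
    k_l: Optional[float] = None
    f_l: Optional[float] = None
    r_l: Optional[float] = None

    def __post_init__(self) -> None:
        if self.l not in _L_LABELS:
            raise ValueError(f"unknown angular-momentum label {self.l!r}")
        if self.chi <= 1:
            raise DegenerateSpacingError("chi must exceed 1 for a descending ladder")
        if self.n_prim < 1:
            raise ValueError("n_prim must be at least 1")
        has_radial = all(v is not None for v in (self.k_l, self.f_l, self.r_l))
        if self.alpha_l is None and not has_radial:
            raise ValueError("provide alpha_l or the full (k_l, f_l, r_l) triple")
        if self.alpha_l is not None and self.alpha_l <= 0:
            raise ValueError("alpha_l must be positive")
        if self.alpha_l is not None and has_radial:
            derived = compute_alpha(self.k_l, self.f_l, self.r_l)
            if abs(derived - self.alpha_l) > 1e-10 * abs(self.alpha_l):
                raise ValueError(
                    "alpha_l inconsistent with (k_l, f_l, r_l): "
                    f"{self.alpha_l!r} vs {derived!r}"
                )

    @property
    def alpha(self) -> float:
        if self.alpha_l is not None:
            return self.alpha_l
        return compute_alpha(self.k_l, self.f_l, self.r_l)


@dataclass(frozen=True)
class PrimitiveSeries:
    """Descending geometric ladder of Gaussian exponents for one channel."""

    l: str
    exponents: tuple

    def __post_init__(self) -> None:
        if self.l not in _L_LABELS:
            raise ValueError(f"unknown angular-momentum label {self.l!r}")
        z = self.exponents
        if len(z) == 0:
            raise ValueError("empty exponent series")
        if any(e <= 0 for e in z):
            raise ValueError("exponents must be positive")
        if any(z[i] <= z[i + 1] for i in range(len(z) - 1)):
            raise ValueError("exponents must be strictly descending")

    def __len__(self) -> int:
        return len(self.exponents)

    @property
    def ratio(self) -> float:
        """Common ratio of consecutive exponents (chi)."""
        if len(self.exponents) < 2:
            raise ValueError("ratio undefined for a single-exponent series")
        return self.exponents[0] / self.exponents[1]


@dataclass(frozen=True)
class PrimitiveBasis:
    """Map from angular-momentum label to its primitive exponent series."""

    channels: dict = field(default_factory=dict)

    def counts(self) -> dict:
        return {l: len(s) for l, s in self.channels.items()}

    def n_primitive_shells(self) -> int:
        return sum(len(s) for s in self.channels.values())


def generate_series(alpha_l: float, chi: float, n_prim: int, l: str = "s") -> PrimitiveSeries:
    """Generate the descending ladder zeta_j = alpha_l * chi**(-j).

    The index runs j = 0 .. n_prim-1 so that the largest exponent equals
    alpha_l, consistent with its role as the maximum channel exponent.
    """
    if alpha_l <= 0:
        raise ValueError("alpha_l must be positive")
    if chi <= 1:
        raise DegenerateSpacingError("chi must exceed 1 for a descending ladder")
    if n_prim < 1:
        raise ValueError("n_prim must be at least 1")
    expo = tuple(alpha_l * chi ** (-j) for j in range(n_prim))
    return PrimitiveSeries(l=l, exponents=expo)


def series_from_spec(spec: ChannelSpec) -> PrimitiveSeries:
    return generate_series(spec.alpha, spec.chi, spec.n_prim, l=spec.l)


def load_ti_channels() -> dict:
    """Read the packaged Ti channel parameters (alpha, chi, n, k, f)."""
    text = resources.files("nmrdkh.data").joinpath("ti_channels.tsv").read_text()
    channels = {}
    header = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        channels[row["l"]] = ChannelSpec(
            l=row["l"],
            alpha_l=float(row["alpha"]),
            chi=float(row["chi"]),
            n_prim=int(row["n_prim"]),
            k_l=float(Fraction(row["k"])),
            f_l=float(Fraction(row["f"])),
            r_l=invert_radius(
                float(row["alpha"]), float(Fraction(row["k"])), float(Fraction(row["f"]))
            ),
        )
    return channels


def build_ti_primitives() -> PrimitiveBasis:
    """The 18s/11p/6d well-tempered primitive set for titanium."""
    specs = load_ti_channels()
    return PrimitiveBasis(channels={l: series_from_spec(s) for l, s in specs.items()})
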