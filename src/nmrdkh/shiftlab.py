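"""Chemical-shift model, calibration regression and benchmark statistics.

The Ti-49 chemical shift of a complex follows from computed isotropic
shieldings via the reference difference

    delta = sigma_ref - sigma_calc                  (direct model)

with sigma_ref the shielding of neat TiCl4, or from the fitted linear
calibration

    delta = a * sigma_calc + b                      (regression model)

which reduces to the direct model when a = -1 and b = sigma_ref.  Protocol
quality is summarized by the absolute deviation from experiment AD_i =
|delta_expt,i - delta_calc,i|, its mean (MAD) and sample standard
deviation, the relative deviation RD_i = 100 AD_i / |delta_expt,i| and its
mean (MRD), plus the slope and R^2 of calculated against experimental
shifts.

When only calculated *shifts* are available (as in the packaged benchmark
tables), the shielding predictor is reconstructed as sigma = K -
delta_calc for an arbitrary constant K; ordinary least squares is affine
equivariant, so slope and R^2 are exact and only the intercept depends on
K.  The reference shielding itself can be recovered by jointly inverting
the direct and regression columns of an external-validation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "ShiftRecord",
    "ShieldingRecord",
    "GeometryRecord",
    "RegressionModel",
    "ProtocolStats",
    "delta_from_sigma",
    "fit_shift_model",
    "predict_shift",
    "recover_sigma_ref",
    "summarize_protocol",
    "geometry_stats",
    "evaluate_fixture",
    "EQ6_MODEL",
]


@dataclass(frozen=True)
class ShiftRecord:
    complex_id: str
    delta_calc: float  # ppm
    delta_expt: float  # ppm
    solvent: str = ""


@dataclass(frozen=True)
class ShieldingRecord:
    complex_id: str
    sigma_calc: float  # ppm
    functional: str = ""


@dataclass(frozen=True)
class GeometryRecord:
    complex_id: str
    bond: str
    calc: float  # angstrom
    expt: float  # angstrom

    def __post_init__(self):
        if self.calc <= 0 or self.expt <= 0:
            raise ValueError("bond lengths must be positive")


@dataclass(frozen=True)
class RegressionModel:
    """delta = a * sigma + b with goodness-of-fit metadata."""

    a: float
    b: float
    r2: float
    n: int

    def __post_init__(self):
        if self.n >= 2 and not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 outside [0, 1]")


#: The published calibration of the OLYP protocol (slope, intercept in ppm).
EQ6_MODEL = RegressionModel(a=-1.0027, b=-1000.0, r2=0.9888, n=41)


@dataclass(frozen=True)
class ProtocolStats:
    """Aggregated deviation statistics of one shift protocol."""

    n: int
    mad: float  # ppm
    sd_ad: float  # ppm, sample (n-1) convention
    mrd: Optional[float]  # percent
    sd_rd: Optional[float]  # percent
    slope: Optional[float]
    r2: Optional[float]
    sd_convention: str = "sample (n-1)"


def delta_from_sigma(sigma_ref: float, sigma_calc):
    """Chemical shift (ppm) from reference and computed shieldings."""
    return np.asarray(sigma_ref, dtype=float) - np.asarray(sigma_calc, dtype=float)


def fit_shift_model(sigmas, deltas_expt) -> RegressionModel:
    """Ordinary least squares of experimental shift on computed shielding."""
    x = np.asarray(sigmas, dtype=float)
    y = np.asarray(deltas_expt, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: shieldings show no variation")
    res = scipy.stats.linregress(x, y)
    return RegressionModel(
        a=float(res.slope), b=float(res.intercept),
        r2=float(res.rvalue**2), n=int(x.size),
    )


def predict_shift(model: RegressionModel, sigma_calc):
    """Evaluate the calibration line at the given shielding(s)."""
    return model.a * np.asarray(sigma_calc, dtype=float) + model.b


def recover_sigma_ref(delta_direct, delta_model, model: RegressionModel = EQ6_MODEL):
    """Recover the reference shielding from paired direct/model columns.

    Each row satisfies  delta_model = a (sigma_ref - delta_direct) + b,
    hence a per-row estimate  sigma_ref = (delta_model - b)/a + delta_direct.
    Returns (least-squares sigma_ref, per-row residuals in ppm).  A root
    mean square residual above 5 ppm indicates inconsistent columns and is
    flagged in the second return value's metadata by the caller.
    """
    d3 = np.asarray(delta_direct, dtype=float)
    d6 = np.asarray(delta_model, dtype=float)
    if d3.size != d6.size or d3.size < 1:
        raise ValueError("need at least one paired row")
    per_row = (d6 - model.b) / model.a + d3
    sigma_ref = float(per_row.mean())
    resid = model.a * (sigma_ref - d3) + model.b - d6
    return sigma_ref, resid


def summarize_protocol(
    delta_calc, delta_expt, with_mrd: bool = True
) -> ProtocolStats:
    """Deviation statistics of calculated against experimental shifts.

    AD_i = |expt_i - calc_i|; MAD is the mean AD, SD_AD its sample
    standard deviation (n-1 divisor; zero for a single row); RD_i =
    100 AD_i / |expt_i| and MRD its mean.  Also reports the slope and R^2
    of the calc-versus-expt line when n >= 2.
    """
    calc = np.asarray(delta_calc, dtype=float)
    expt = np.asarray(delta_expt, dtype=float)
    if calc.size != expt.size or calc.size < 1:
        raise ValueError("need at least one paired observation")
    ad = np.abs(expt - calc)
    mad = float(ad.mean())
    sd_ad = float(ad.std(ddof=1)) if ad.size > 1 else 0.0
    mrd = sd_rd = None
    if with_mrd:
        if np.any(expt == 0):
            raise ValueError(
                "relative deviations undefined: an experimental shift is zero"
            )
        rd = 100.0 * ad / np.abs(expt)
        mrd = float(rd.mean())
        sd_rd = float(rd.std(ddof=1)) if rd.size > 1 else 0.0
    slope = r2 = None
    if calc.size >= 2 and np.ptp(expt) > 0:
        res = scipy.stats.linregress(expt, calc)
        slope, r2 = float(res.slope), float(res.rvalue**2)
    return ProtocolStats(
        n=int(calc.size), mad=mad, sd_ad=sd_ad, mrd=mrd, sd_rd=sd_rd,
        slope=slope, r2=r2,
    )


def geometry_stats(records: Sequence[GeometryRecord]):
    """Per-bond relative deviations (percent) and their mean.

    RD_i = 100 |calc - expt| / expt, against the experimental length.
    Returns (list of per-row RD, MRD).
    """
    if not records:
        raise ValueError("no geometry records")
    rds = [100.0 * abs(r.calc - r.expt) / r.expt for r in records]
    return rds, float(np.mean(rds))


def evaluate_fixture(table_id: str, functional: Optional[str] = None):
    """Statistics plus the per-complex deviation list for a packaged table.

    ``table3`` needs a functional column; ``table4`` one of the model
    columns (``delta_direct``/``delta_model``); ``table2`` takes no
    functional and returns geometry statistics.
    """
    from . import fixtures

    fx = fixtures.load_fixture(table_id)
    if table_id == "table2":
        recs = [
            GeometryRecord(r.complex_id, r.bond, r.calc, r.expt)
            for r in fx.frame.itertuples()
        ]
        rds, mrd = geometry_stats(recs)
        report = [
            {"complex_id": r.complex_id, "bond": r.bond, "rd": rd}
            for r, rd in zip(recs, rds)
        ]
        return {"mrd": mrd, "rows": report}
    frame = fx.frame
    value_cols = [c for c in frame.columns if c not in ("complex_id", "solvent", "expt")]
    if functional not in value_cols:
        raise KeyError(
            f"unknown column {functional!r} for {table_id}; available: {value_cols}"
        )
    stats = summarize_protocol(frame[functional], frame["expt"])
    report = [
        {
            "complex_id": cid,
            "delta_calc": float(c),
            "delta_expt": float(e),
            "ad": abs(float(e) - float(c)),
        }
        for cid, c, e in zip(frame["complex_id"], frame[functional], frame["expt"])
    ]
    return {"stats": stats, "rows": report}
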