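"""Packaged benchmark tables and their integrity-checked loaders.

Three plain-text tab-separated fixtures ship with the package:

* ``table2`` — seven Ti-ligand bond lengths (optimized vs X-ray) for the
  five protocol-construction complexes;
* ``table3`` — calculated vs experimental Ti-49 shifts for the 41-complex
  calibration set under five density functionals;
* ``table4`` — the nine-complex external validation set with the direct
  (shielding-difference) and regression-model shift columns.

Each row carries its source table and row label so downstream reports can
cite provenance; a SHA-256 manifest guards against silent fixture edits.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["BenchmarkFixture", "load_fixture", "FixtureIntegrityError", "FIXTURE_FILES"]

FIXTURE_FILES = {
    "table2": "table2_geometry.tsv",
    "table3": "table3_shifts.tsv",
    "table4": "table4_external.tsv",
}

_EXPECTED_SHAPES = {
    "table2": (7, {"complex_id", "bond", "calc", "expt"}),
    "table3": (41, {"complex_id", "solvent", "expt", "mPWLYP", "OLYP", "BLYP",
                    "tHCTH", "B97-D3BJ"}),
    "table4": (9, {"complex_id", "solvent", "delta_direct", "delta_model", "expt"}),
}


class FixtureIntegrityError(RuntimeError):
    pass


@dataclass
class BenchmarkFixture:
    table_id: str
    frame: pd.DataFrame
    sha256: str
    comment: str

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def _manifest() -> dict:
    text = resources.files("nmrdkh.data").joinpath("manifest.json").read_text()
    return json.loads(text)


def load_fixture(table_id: str) -> BenchmarkFixture:
    """Load and validate a packaged benchmark table."""
    if table_id not in FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {table_id!r}; valid ids: {sorted(FIXTURE_FILES)}"
        )
    fname = FIXTURE_FILES[table_id]
    raw = resources.files("nmrdkh.data").joinpath(fname).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _manifest().get(fname)
    if expected is not None and digest != expected:
        raise FixtureIntegrityError(
            f"{fname}: checksum mismatch ({digest[:12]}... != {expected[:12]}...)"
        )
    text = raw.decode()
    comment = "\n".join(
        ln[1:].strip() for ln in text.splitlines() if ln.startswith("#")
    )
    frame = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    n_expected, cols = _EXPECTED_SHAPES[table_id]
    if len(frame) != n_expected:
        raise FixtureIntegrityError(
            f"{table_id}: expected {n_expected} rows, found {len(frame)}"
        )
    if not cols.issubset(frame.columns):
        raise FixtureIntegrityError(
            f"{table_id}: missing columns {cols - set(frame.columns)}"
        )
    frame = frame.copy()
    frame.attrs["table_id"] = table_id
    frame.attrs["source_rows"] = [f"{table_id}:{cid}" for cid in frame["complex_id"]]
    return BenchmarkFixture(
        table_id=table_id, frame=frame, sha256=digest, comment=comment
    )
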