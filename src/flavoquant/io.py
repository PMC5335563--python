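"""Tabular input, run reports and schemas shared by the CLI.

CSV with a header row is the interchange format for all measured data;
JSON for machine-readable result reports; YAML for protocol/config
blocks. Headers are matched case-insensitively and column order is
irrelevant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["SchemaError", "RunReport", "read_table", "write_report", "file_digest"]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


# column schemas per data kind
SCHEMAS = {
    "titration": ["added_volume_ul", "fluorescence"],
    "spectrum": ["wavelength_nm", "intensity"],
    "absorbance_spectrum": ["wavelength_nm", "absorbance"],
    "rates": ["substrate_mm", "rate"],
    "melt": ["temperature_c", "signal"],
    "mrm": ["species", "transition", "area"],
    "standards": ["species", "conc_nm", "area"],
}

_NUMERIC_EXEMPT = {"species", "transition"}


def read_table(path, schema) -> pd.DataFrame:
    """Read a CSV against a schema (a key of ``SCHEMAS`` or a column list).

    Headers are matched case-insensitively; columns may appear in any
    order. Raises :class:`SchemaError` naming missing columns, and a
    ``ValueError`` locating the first malformed (non-numeric) cell by
    line number.
    """
    columns = SCHEMAS[schema] if isinstance(schema, str) else [c.lower() for c in schema]
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise SchemaError(f"{path.name}: no data rows")
    out = df[columns].copy()
    for col in columns:
        if col in _NUMERIC_EXEMPT:
            continue
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path.name}: non-numeric value {out[col][row]!r} in column "
                f"'{col}' at line {row + 2}"  # +1 header, +1 one-based
            )
        out[col] = parsed
    return out


def file_digest(path) -> str:
    """SHA-256 digest of a file, for provenance in run reports."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    """Provenance-complete record of one analysis run.

    Re-running the same command on identical inputs with the same seed
    reproduces ``results`` bit-for-bit for deterministic stages.
    """

    command: str
    parameters: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    seed: int | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "parameters": self.parameters,
            "results": self.results,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=float)


def write_report(report: RunReport, path) -> None:
    """Serialize a run report to JSON."""
    Path(path).write_text(report.to_json() + "\n")
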