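"""Long-format plate-table CSV dialect: schema, reader and writer.

A plate table is a pandas DataFrame with one row per well measurement and
exactly the columns in :data:`PLATE_COLUMNS`.  Concentrations are nM at
the file boundary (molar inside the fitting code), times are minutes,
and inapplicable fields (e.g. ``time_min`` for an endpoint assay) are
empty cells / NaN.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PLATE_COLUMNS",
    "MODES",
    "WELL_TYPES",
    "PlateSchemaError",
    "ConfigurationError",
    "read_plate_csv",
    "write_plate_csv",
    "empty_plate",
    "validate_plate",
]

#: Required columns, in canonical order.
PLATE_COLUMNS = [
    "experiment_id",
    "mode",
    "well_id",
    "well_type",
    "probe_conc_nM",
    "competitor_conc_nM",
    "time_min",
    "donor_em",
    "acceptor_em",
    "bret_ratio",
]

MODES = ("saturation", "association", "competition", "concentration_response")
WELL_TYPES = ("total", "nsb", "vehicle")

_NUMERIC_COLUMNS = [
    "probe_conc_nM",
    "competitor_conc_nM",
    "time_min",
    "donor_em",
    "acceptor_em",
    "bret_ratio",
]

# common aliases worth a helpful error message
_MODE_SUGGESTIONS = {
    "kinetic": "association",
    "kinetics": "association",
    "sat": "saturation",
    "displacement": "competition",
    "dose_response": "concentration_response",
    "cr": "concentration_response",
}


class PlateSchemaError(ValueError):
    """The file or table does not conform to the plate-table dialect."""


class ConfigurationError(ValueError):
    """A run or simulation configuration is invalid or incomplete."""


def empty_plate() -> pd.DataFrame:
    """An empty table with the canonical columns."""
    return pd.DataFrame({c: pd.Series(dtype=float) for c in PLATE_COLUMNS}).astype(
        {c: object for c in ("experiment_id", "mode", "well_id", "well_type")}
    )


def validate_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema of an in-memory table; returns the table on success."""
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise PlateSchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in table.columns if c not in PLATE_COLUMNS]
    if extra:
        raise PlateSchemaError(f"unexpected column(s): {', '.join(extra)}")

    if len(table):
        bad_mode = sorted(set(table["mode"].dropna()) - set(MODES))
        if bad_mode:
            hints = [
                f"{m!r} (did you mean {_MODE_SUGGESTIONS[m]!r}?)"
                if m in _MODE_SUGGESTIONS
                else repr(m)
                for m in bad_mode
            ]
            raise PlateSchemaError(
                f"invalid mode value(s): {', '.join(hints)}; "
                f"valid modes are {', '.join(MODES)}"
            )
        bad_wt = sorted(set(table["well_type"].dropna()) - set(WELL_TYPES))
        if bad_wt:
            raise PlateSchemaError(
                f"invalid well_type value(s): {bad_wt}; valid types are "
                f"{', '.join(WELL_TYPES)}"
            )
    return table


def read_plate_csv(path) -> pd.DataFrame:
    """Read and validate a plate-table CSV.

    Raises
    ------
    PlateSchemaError
        On a missing/unknown column, invalid mode or well type, or
        non-numeric values in numeric columns (reported with row numbers).
    """
    path = Path(path)
    table = pd.read_csv(
        path,
        dtype={c: str for c in ("experiment_id", "mode", "well_id", "well_type")},
        float_precision="round_trip",
    )
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    # a ratio column may be omitted when both emission channels are present;
    # the ratio is then computed downstream
    if missing == ["bret_ratio"] and {"donor_em", "acceptor_em"} <= set(table.columns):
        table["bret_ratio"] = np.nan
        missing = []
    if missing:
        raise PlateSchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )

    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            rows = ", ".join(str(i + 2) for i in bad[:10])
            raise PlateSchemaError(
                f"{path.name}: non-numeric value(s) in column {col!r} "
                f"at file row(s) {rows}"
            )
        table[col] = coerced

    for col in ("probe_conc_nM", "competitor_conc_nM"):
        neg = table.index[table[col] < 0]
        if len(neg):
            rows = ", ".join(str(i + 2) for i in neg[:10])
            raise PlateSchemaError(
                f"{path.name}: negative concentration(s) in {col!r} at row(s) {rows}"
            )

    validate_plate(table)
    return table[PLATE_COLUMNS]


def write_plate_csv(table: pd.DataFrame, path) -> None:
    """Write a plate table with deterministic column and row order.

    Rows are sorted by (experiment_id, mode, well_id, time_min); repeated
    writes of the same table are byte-identical.  Floats are written with
    ``%.17g`` so values round-trip exactly.
    """
    validate_plate(table)
    out = table[PLATE_COLUMNS].copy()
    out = out.sort_values(
        ["experiment_id", "mode", "well_id", "time_min"],
        kind="mergesort",
        na_position="first",
    )
    out.to_csv(path, index=False, float_format="%.17g", na_rep="", lineterminator="\n")
    logger.info("wrote %d plate records to %s", len(out), path)
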