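"""CSV/JSON input and output with explicit schemas.

Each reader validates the declared header up front and reports malformed
rows with their line numbers, so CLI users get a schema error (exit code
2) rather than a traceback from deep inside a fit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .orthogonal import DesignTable

DESIGN_COLUMNS = ["run", "A", "B", "C", "D", "response"]


def _read_csv(path, required, optional=()) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"input file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}; expected header "
            f"{','.join(list(required) + list(optional))}"
        )
    return frame


def _check_numeric(frame: pd.DataFrame, columns, path) -> None:
    for col in columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna() & frame[col].notna()].tolist()
        nan_rows = frame.index[frame[col].isna()].tolist()
        problem = bad + nan_rows
        if problem:
            # +2: header line plus 1-based numbering
            rows = ", ".join(str(i + 2) for i in sorted(problem)[:5])
            raise SchemaError(f"{path}: non-numeric or missing '{col}' at line(s) {rows}")
        frame[col] = vals


def read_design_csv(path) -> DesignTable:
    """Read an L16 design table (``run,A,B,C,D,response``)."""
    frame = _read_csv(path, DESIGN_COLUMNS[:-1], optional=("response",))
    if "response" in frame.columns:
        _check_numeric(frame, ["response"], path)
    _check_numeric(frame, DESIGN_COLUMNS[:-1], path)
    return DesignTable(frame)


def write_design_csv(design: DesignTable, path) -> None:
    design.frame.to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    """Fe2+ depletion series: ``time,fe2_gL[,biomass]``."""
    frame = _read_csv(path, ["time", "fe2_gL"], optional=("biomass",))
    cols = ["time", "fe2_gL"] + (["biomass"] if "biomass" in frame.columns else [])
    _check_numeric(frame, cols, path)
    return frame


def read_conversion_csv(path, percent: bool = False) -> pd.DataFrame:
    """Desulfurization series: ``time,conversion`` (fraction, or % with
    ``percent=True``)."""
    frame = _read_csv(path, ["time", "conversion"])
    _check_numeric(frame, ["time", "conversion"], path)
    if percent:
        frame["conversion"] = frame["conversion"] / 100.0
    return frame


def read_tg_csv(path) -> pd.DataFrame:
    """TG data: either ``temperature_K,conversion`` or ``temperature_C,mass``."""
    frame = _read_csv(path, [], optional=("temperature_K", "conversion",
                                          "temperature_C", "mass"))
    if {"temperature_K", "conversion"} <= set(frame.columns):
        _check_numeric(frame, ["temperature_K", "conversion"], path)
    elif {"temperature_C", "mass"} <= set(frame.columns):
        _check_numeric(frame, ["temperature_C", "mass"], path)
    else:
        raise SchemaError(
            f"{path}: expected columns temperature_K,conversion or temperature_C,mass"
        )
    return frame


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return v if np.isfinite(v) else None
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, cls=_JsonEncoder)
        fh.write("\n")
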