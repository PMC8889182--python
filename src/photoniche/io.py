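"""Validated CSV readers for the four field-data tables.

Each reader checks the header against the required schema (a missing
column is a hard :class:`~photoniche.errors.SchemaError` naming the
column), converts and range-checks every cell, and rejects malformed rows
individually with a line-numbered log message rather than aborting the
whole file. Depth is positive downward in metres with the surface at 0;
negative depths are rejected.
"""

from __future__ import annotations

import logging
import os
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError
from .fitness import STATUSES
from .fluorometry import TREATMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "read_light_profile",
    "read_loggers",
    "read_pam",
    "read_outcomes",
    "read_tables",
]


def _float(lo=None, hi=None, lo_open=False, nullable=False) -> Callable:
    def convert(raw: str):
        if raw == "":
            if nullable:
                return np.nan
            raise ValueError("empty cell")
        val = float(raw)
        if not np.isfinite(val):
            raise ValueError(f"non-finite value {raw!r}")
        if lo is not None and (val <= lo if lo_open else val < lo):
            raise ValueError(f"value {val} below bound {lo}")
        if hi is not None and val > hi:
            raise ValueError(f"value {val} above bound {hi}")
        return val
    return convert


def _category(allowed, nullable=False) -> Callable:
    allowed = set(allowed)

    def convert(raw: str):
        if raw == "" and nullable:
            return np.nan
        if raw not in allowed:
            raise ValueError(f"value {raw!r} not in {sorted(allowed)}")
        return raw
    return convert


def _string(raw: str):
    if raw == "":
        raise ValueError("empty cell")
    return raw


def _timestamp(raw: str):
    try:
        pd.Timestamp(raw)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp {raw!r}") from exc
    return raw


def _read_table(path, schema: dict[str, Callable], label: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"{label} file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(schema) - set(raw.columns)
    if missing:
        raise SchemaError(f"{label} table {path} missing column(s): {sorted(missing)}")
    if len(raw) == 0:
        raise DegenerateDataError(f"{label} table {path} contains no data rows")
    records: list[dict] = []
    n_rejected = 0
    for idx, row in raw.iterrows():
        parsed = {}
        try:
            for col, convert in schema.items():
                parsed[col] = convert(row[col].strip())
        except ValueError as exc:
            n_rejected += 1
            # +2: header line plus 1-based numbering
            logger.warning("%s %s line %d rejected: %s", label, path, idx + 2, exc)
            continue
        records.append(parsed)
    if not records:
        raise DegenerateDataError(f"{label} table {path}: every row was malformed")
    logger.info("%s %s: %d rows read, %d rejected", label, path, len(records), n_rejected)
    return pd.DataFrame.from_records(records)


def read_light_profile(path) -> pd.DataFrame:
    """Light-depth profile: columns ``depth_m`` (>= 0 m), ``irradiance`` (> 0)."""
    return _read_table(path, {
        "depth_m": _float(lo=0.0),
        "irradiance": _float(lo=0.0, lo_open=True),
    }, "light-profile")


def read_loggers(path) -> pd.DataFrame:
    """Logger series: ``timestamp,site,temperature_c,relative_light``."""
    return _read_table(path, {
        "timestamp": _timestamp,
        "site": _category({"shallow", "deep"}),
        "temperature_c": _float(),
        "relative_light": _float(lo=0.0),
    }, "logger")


def read_pam(path) -> pd.DataFrame:
    """PAM records; yield cells may be empty (missing measurement)."""
    return _read_table(path, {
        "species": _string,
        "colony_id": _string,
        "depth_m": _float(lo=0.0, lo_open=True),
        "treatment": _category(set(TREATMENTS) | {"survey"}),
        "timepoint_d": _float(lo=0.0, nullable=True),
        "delta_f_fm_prime": _float(lo=0.0, hi=1.0, nullable=True),
        "fv_fm": _float(lo=0.0, hi=1.0, lo_open=True, nullable=True),
    }, "PAM")


def read_outcomes(path) -> pd.DataFrame:
    """Transplant census: ``species,treatment,genotype_id,status``."""
    return _read_table(path, {
        "species": _string,
        "treatment": _category(TREATMENTS),
        "genotype_id": _string,
        "status": _category(STATUSES),
    }, "outcomes")


def read_tables(paths: dict) -> dict[str, pd.DataFrame]:
    """Read any subset of the four campaign tables.

    ``paths`` maps table names (``profile``, ``loggers``, ``pam``,
    ``outcomes``) to file paths; unknown names raise.
    """
    readers = {
        "profile": read_light_profile,
        "loggers": read_loggers,
        "pam": read_pam,
        "outcomes": read_outcomes,
    }
    unknown = set(paths) - set(readers)
    if unknown:
        raise SchemaError(f"unknown table name(s): {sorted(unknown)}")
    return {name: readers[name](path) for name, path in paths.items()}
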