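"""Readers/writers for the flat-file formats the pipeline consumes.

The core runtime format is a comma-separated UTF-8 table with a header
row, one row per fish, holding the biological covariates, the otolith
reading columns and the shape-variable columns side by side.  Column
names are resolved through a schema mapping so that externally produced
tables (e.g. converted spreadsheet supplements) can be ingested without
renaming files by hand.  Rows that fail to parse or violate a record
invariant are collected into a rejection report with a reason string —
never silently dropped.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    SHAPE_VARS,
    FishRecord,
    InvariantError,
    OtolithReading,
    QCReport,
    ShapeTable,
)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SCHEMA",
    "QCPolicy",
    "ParsedTable",
    "read_fish_table",
    "write_fish_table",
    "reconcile_readers",
    "qc_filter",
    "convert_xlsx_to_csv",
]

#: canonical field -> CSV column name.  Shape variables keep their own names.
DEFAULT_SCHEMA: dict[str, str] = {
    "fish_id": "fish_id",
    "site": "site",
    "sex": "sex",
    "maturity": "maturity",
    "capture_date": "capture_date",
    "fl_cm": "fl_cm",
    "tl_cm": "tl_cm",
    "sl_cm": "sl_cm",
    "ww_g": "ww_g",
    "gw_g": "gw_g",
    "ow_g": "ow_g",
    "annuli_reader1": "annuli_reader1",
    "annuli_reader2": "annuli_reader2",
    "annuli_auto": "annuli_auto",
    "consensus_annuli": "consensus_annuli",
    "otolith_radius_mm": "otolith_radius_mm",
    "last_annulus_mm": "last_annulus_mm",
    "penultimate_annulus_mm": "penultimate_annulus_mm",
    "edge_opaque": "edge_opaque",
    "broken": "broken",
    "illegible": "illegible",
}

MANDATORY_FIELDS = ("fish_id", "site", "sex", "maturity", "capture_date", "fl_cm")
_OPTIONAL_FLOAT = ("tl_cm", "sl_cm", "ww_g", "gw_g", "ow_g",
                   "otolith_radius_mm", "last_annulus_mm", "penultimate_annulus_mm")
_READER_FIELDS = ("annuli_reader1", "annuli_reader2", "annuli_auto")
_BOOL_FIELDS = ("edge_opaque", "broken", "illegible")


class SchemaError(ValueError):
    """A mandatory column could not be resolved through the schema."""


@dataclass
class QCPolicy:
    """Policy for reader reconciliation and otolith rejection.

    ``discordance_tolerance``: maximum absolute difference between the two
    human readers accepted as agreement (0 = exact match, the default).
    ``second_read_resolves``: whether a recorded consensus value overrides
    a first-pass disagreement (mirrors one reconciliation re-read).
    """

    discordance_tolerance: int = 0
    second_read_resolves: bool = True


@dataclass
class ParsedTable:
    """Result of :func:`read_fish_table`."""

    fish: list[FishRecord]
    readings: list[OtolithReading]
    shape: ShapeTable
    rejections: pd.DataFrame  # columns: row, fish_id, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _parse_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v).strip())


def _parse_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
        return None
    return float(v)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise ValueError(f"unparseable boolean {v!r}")


def read_fish_table(path, schema: Optional[dict[str, str]] = None,
                    sites: Optional[Sequence[str]] = None,
                    study_window: Optional[tuple[dt.date, dt.date]] = None,
                    ) -> ParsedTable:
    """Read a fish table CSV into typed records.

    Raises :class:`SchemaError` when a mandatory column is missing;
    per-row parse failures or invariant violations go to the rejection
    report instead.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, dtype=str)
    for f in MANDATORY_FIELDS:
        if schema[f] not in raw.columns:
            raise SchemaError(f"mandatory column {schema[f]!r} (field {f}) missing")

    fish: list[FishRecord] = []
    readings: list[OtolithReading] = []
    shape_rows: list[dict] = []
    shape_index: list[str] = []
    rejections: list[dict] = []
    shape_cols = [c for c in SHAPE_VARS if c in raw.columns]

    for i, row in raw.iterrows():
        fid = str(row.get(schema["fish_id"], f"row{i}"))
        try:
            rec = FishRecord(
                fish_id=fid,
                site=str(row[schema["site"]]).strip(),
                sex=str(row[schema["sex"]]).strip(),
                maturity=str(row[schema["maturity"]]).strip(),
                capture_date=_parse_date(row[schema["capture_date"]]),
                fl_cm=float(row[schema["fl_cm"]]),
                **{f: _parse_float(row.get(schema[f])) for f in _OPTIONAL_FLOAT[:5]},
            )
            rec.validate(sites=sites, study_window=study_window)

            counts = []
            for f in _READER_FIELDS:
                v = _parse_float(row.get(schema[f]))
                if v is not None:
                    counts.append(int(v))
            cons = _parse_float(row.get(schema["consensus_annuli"]))
            reading = OtolithReading(
                fish_id=fid,
                annuli_counts=tuple(counts),
                consensus_annuli=None if cons is None else int(cons),
                otolith_radius_mm=_parse_float(row.get(schema["otolith_radius_mm"])),
                last_annulus_mm=_parse_float(row.get(schema["last_annulus_mm"])),
                penultimate_annulus_mm=_parse_float(
                    row.get(schema["penultimate_annulus_mm"])),
                **{f: _parse_bool(row.get(schema[f], False)) for f in _BOOL_FIELDS},
            )
            reading.validate()
        except (InvariantError, ValueError, KeyError) as exc:
            rejections.append({"row": int(i), "fish_id": fid, "reason": str(exc)})
            continue

        fish.append(rec)
        readings.append(reading)
        if shape_cols:
            vals = {}
            for c in shape_cols:
                v = _parse_float(row.get(c))
                if v is not None:
                    vals[c] = v
            if vals:
                shape_rows.append(vals)
                shape_index.append(fid)

    shape_df = pd.DataFrame(shape_rows, index=pd.Index(shape_index, name="fish_id"))
    table = ParsedTable(fish=fish, readings=readings,
                        shape=ShapeTable(values=shape_df),
                        rejections=pd.DataFrame(
                            rejections, columns=["row", "fish_id", "reason"]))
    if rejections:
        log.info("read_fish_table: %d rows parsed, %d rejected",
                 len(fish), len(rejections))
    return table


def write_fish_table(path, fish: Iterable[FishRecord],
                     readings: Optional[Iterable[OtolithReading]] = None,
                     shape: Optional[ShapeTable] = None) -> pd.DataFrame:
    """Write typed records back to the canonical CSV layout.

    Returns the DataFrame that was written (useful for round-trip checks).
    """
    rows = {}
    for rec in fish:
        rows[rec.fish_id] = {
            "fish_id": rec.fish_id, "site": rec.site, "sex": rec.sex,
            "maturity": rec.maturity,
            "capture_date": rec.capture_date.isoformat(),
            "fl_cm": rec.fl_cm, "tl_cm": rec.tl_cm, "sl_cm": rec.sl_cm,
            "ww_g": rec.ww_g, "gw_g": rec.gw_g, "ow_g": rec.ow_g,
        }
    if readings is not None:
        for rd in readings:
            r = rows.setdefault(rd.fish_id, {"fish_id": rd.fish_id})
            for j, c in enumerate(rd.annuli_counts):
                r[_READER_FIELDS[j]] = c
            r["consensus_annuli"] = rd.consensus_annuli
            r["otolith_radius_mm"] = rd.otolith_radius_mm
            r["last_annulus_mm"] = rd.last_annulus_mm
            r["penultimate_annulus_mm"] = rd.penultimate_annulus_mm
            r["edge_opaque"] = rd.edge_opaque
            r["broken"] = rd.broken
            r["illegible"] = rd.illegible
    if shape is not None and len(shape.values):
        for fid, srow in shape.values.iterrows():
            r = rows.setdefault(str(fid), {"fish_id": str(fid)})
            for c, v in srow.items():
                if pd.notna(v):
                    r[c] = v
    df = pd.DataFrame(list(rows.values()))
    df.to_csv(path, index=False)
    return df


def reconcile_readers(reading: OtolithReading, policy: QCPolicy) -> OtolithReading:
    """Apply the reader-reconciliation rule to one reading.

    Agreement of the two human readers within ``discordance_tolerance``
    accepts the first reader's count; otherwise a recorded consensus
    (the re-read) resolves the disagreement when the policy allows it;
    otherwise the reading stays without consensus and is later rejected
    as discordant.
    """
    human = reading.annuli_counts[:2]
    if len(human) >= 2:
        if abs(human[0] - human[1]) <= policy.discordance_tolerance:
            if reading.consensus_annuli is None:
                reading.consensus_annuli = human[0]
        elif not policy.second_read_resolves:
            reading.consensus_annuli = None
    elif len(human) == 1 and reading.consensus_annuli is None:
        reading.consensus_annuli = human[0]
    return reading


def qc_filter(readings: Sequence[OtolithReading],
              policy: Optional[QCPolicy] = None,
              ) -> tuple[list[OtolithReading], QCReport]:
    """Partition readings into retained vs broken vs unreadable/discordant.

    Pure bookkeeping: the report components always sum to the collected
    total, matching the downstream sample-size accounting.
    """
    policy = policy or QCPolicy()
    retained: list[OtolithReading] = []
    n_broken = 0
    n_bad = 0
    for rd in readings:
        if rd.broken:
            n_broken += 1
            continue
        rd = reconcile_readers(rd, policy)
        if rd.illegible or rd.consensus_annuli is None:
            n_bad += 1
            continue
        retained.append(rd)
    report = QCReport(collected=len(readings), broken=n_broken,
                      unreadable_or_discordant=n_bad, retained=len(retained))
    log.info("qc_filter: collected=%d broken=%d unreadable_or_discordant=%d retained=%d",
             report.collected, report.broken,
             report.unreadable_or_discordant, report.retained)
    return retained, report


def convert_xlsx_to_csv(xlsx_path, out_dir, sheet: Optional[str] = None) -> list[Path]:
    """Convert spreadsheet supplements to per-sheet CSVs.

    Utility only: the core pipeline never parses XLSX directly.  Requires
    the optional ``openpyxl`` dependency.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(xlsx_path, sheet_name=sheet, engine="openpyxl")
    if isinstance(sheets, pd.DataFrame):
        sheets = {sheet or Path(xlsx_path).stem: sheets}
    written = []
    for name, df in sheets.items():
        p = out_dir / f"{Path(xlsx_path).stem}_{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
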