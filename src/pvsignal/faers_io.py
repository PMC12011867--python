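"""Reading and writing FAERS-dialect ASCII quarterly extracts.

The public FAERS quarterly packages ship one ``$``-delimited text file per
table (DEMO, DRUG, REAC, OUTC, THER, INDI), a header line naming the columns,
plus a deletion list naming CASEIDs withdrawn by the FDA.  This module parses
those files into typed records and writes them back bit-exactly; everything
downstream of it consumes typed records only.

Upstream FAERS files contain no quoting; our writer escapes an embedded
``$`` as ``\\$`` (and a backslash as ``\\\\``) so that arbitrary free text
survives a write/read round trip.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

log = logging.getLogger(__name__)

DELIM = "$"
TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")
REQUIRED_TABLES = ("DEMO", "DRUG")
DELETED_PREFIX = "DELETED"

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "OT"})
AGE_UNITS = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
WEIGHT_UNITS = frozenset({"KG", "LBS", "GMS"})


class FaersFormatError(ValueError):
    """Fatal structural problem in a quarterly extract."""


@dataclass
class ParseWarnings:
    """Deterministic counter of recoverable parse problems."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, kind: str, n: int = 1) -> None:
        self.counts[kind] = self.counts.get(kind, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ParsedDate:
    """A possibly partial FAERS date.

    ``precision`` is one of ``day``/``month``/``year``/``missing``; ``value``
    is a calendar date only at day precision (partial dates are never coerced
    to a fabricated day).
    """

    value: Optional[date]
    precision: str
    raw: str = ""

    @property
    def is_full(self) -> bool:
        return self.precision == "day"


MISSING_DATE = ParsedDate(None, "missing")


def parse_date(raw: str, warnings: Optional[ParseWarnings] = None) -> ParsedDate:
    """Parse a FAERS date field (``YYYYMMDD``, ``YYYYMM``, ``YYYY`` or empty).

    Impossible or non-numeric values count a warning and return missing;
    no input ever raises.
    """
    raw = (raw or "").strip()
    if not raw:
        return MISSING_DATE
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        if warnings is not None:
            warnings.add("bad_date")
        return ParsedDate(None, "missing", raw)
    year = int(raw[:4])
    if len(raw) == 4:
        return ParsedDate(None, "year", raw)
    month = int(raw[4:6])
    if not 1 <= month <= 12:
        if warnings is not None:
            warnings.add("bad_date")
        return ParsedDate(None, "missing", raw)
    if len(raw) == 6:
        return ParsedDate(None, "month", raw)
    try:
        return ParsedDate(date(year, month, int(raw[6:8])), "day", raw)
    except ValueError:
        if warnings is not None:
            warnings.add("bad_date")
        return ParsedDate(None, "missing", raw)


def _parse_number(raw: str, warnings: ParseWarnings, kind: str) -> Optional[float]:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        warnings.add(kind)
        return None
    if value < 0:
        warnings.add(kind)
        return None
    return value


@dataclass(frozen=True)
class DemoRecord:
    primaryid: int
    caseid: int
    fda_dt: ParsedDate
    event_dt: ParsedDate = MISSING_DATE
    age_value: Optional[float] = None
    age_unit: Optional[str] = None
    weight_value: Optional[float] = None
    weight_unit: Optional[str] = None
    sex: Optional[str] = None
    country: Optional[str] = None
    occupation: Optional[str] = None


@dataclass(frozen=True)
class DrugRecord:
    primaryid: int
    drug_seq: int
    drugname: str
    role_cod: str
    indication_pt: Optional[str] = None


@dataclass(frozen=True)
class ReacRecord:
    primaryid: int
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    primaryid: int
    outcome_code: str


@dataclass(frozen=True)
class TherRecord:
    primaryid: int
    drug_seq: int
    start_dt: ParsedDate = MISSING_DATE


@dataclass
class RawQuarter:
    """One quarterly extract: raw keyed string rows per table plus the
    deletion list.  Unknown extra columns are preserved verbatim."""

    quarter_id: str
    demo_rows: list[dict[str, str]] = field(default_factory=list)
    drug_rows: list[dict[str, str]] = field(default_factory=list)
    reac_rows: list[dict[str, str]] = field(default_factory=list)
    outc_rows: list[dict[str, str]] = field(default_factory=list)
    ther_rows: list[dict[str, str]] = field(default_factory=list)
    indi_rows: list[dict[str, str]] = field(default_factory=list)
    deleted_caseids: list[int] = field(default_factory=list)

    def rows_for(self, table: str) -> list[dict[str, str]]:
        return getattr(self, f"{table.lower()}_rows")


# ---------------------------------------------------------------------------
# dialect: escaping, line parsing


def escape_field(text: str) -> str:
    return text.replace("\\", "\\\\").replace(DELIM, "\\" + DELIM)


def unescape_field(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text) and text[i + 1] in ("\\", DELIM):
            out.append(text[i + 1])
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _split_line(line: str) -> list[str]:
    """Split on unescaped ``$``."""
    fields: list[str] = []
    cur: list[str] = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "\\" and i + 1 < len(line):
            cur.append(ch)
            cur.append(line[i + 1])
            i += 2
        elif ch == DELIM:
            fields.append("".join(cur))
            cur = []
            i += 1
        else:
            cur.append(ch)
            i += 1
    fields.append("".join(cur))
    return [unescape_field(f) for f in fields]


def _read_text(path: str) -> str:
    with open(path, "rb") as fh:
        data = fh.read()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        log.warning("non-UTF-8 bytes in %s; falling back to latin-1", path)
        return data.decode("latin-1")


def _read_table(path: str) -> list[dict[str, str]]:
    text = _read_text(path)
    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty table file")
    header = [h.strip() for h in _split_line(lines[0])]
    if not header or any(not h for h in header):
        raise FaersFormatError(f"{path}, line 1: malformed header {header!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        values = _split_line(line)
        if len(values) != len(header):
            raise FaersFormatError(
                f"{path}, line {lineno}: expected {len(header)} fields, got {len(values)}"
            )
        rows.append(dict(zip(header, values)))
    return rows


def _table_path(path: str, table: str, quarter_id: str) -> str:
    return os.path.join(path, f"{table}{quarter_id}.txt")


def read_quarter(path: str, quarter_id: str) -> RawQuarter:
    """Read one quarterly directory into a :class:`RawQuarter`.

    DEMO and DRUG are required; other tables default to empty.  An absent
    deletion-list file yields an empty list with a logged warning.
    """
    quarter = RawQuarter(quarter_id=quarter_id)
    for table in TABLES:
        fpath = _table_path(path, table, quarter_id)
        if not os.path.exists(fpath):
            if table in REQUIRED_TABLES:
                raise FaersFormatError(f"required table file missing: {fpath}")
            continue
        setattr(quarter, f"{table.lower()}_rows", _read_table(fpath))
    del_path = os.path.join(path, f"{DELETED_PREFIX}{quarter_id}.txt")
    if os.path.exists(del_path):
        quarter.deleted_caseids = [
            int(line.strip())
            for line in _read_text(del_path).splitlines()
            if line.strip()
        ]
    else:
        log.warning("no deletion list for quarter %s; assuming none", quarter_id)
    return quarter


def write_quarter(quarter: RawQuarter, path: str) -> list[str]:
    """Write a quarter back to FAERS-dialect files; inverse of read_quarter.

    The deletion file is always written, even when empty, so a re-read never
    warns about an absent list on data we produced ourselves.
    """
    os.makedirs(path, exist_ok=True)
    written = []
    for table in TABLES:
        rows = quarter.rows_for(table)
        if not rows and table not in REQUIRED_TABLES:
            continue
        fpath = _table_path(path, table, quarter.quarter_id)
        header = list(rows[0].keys()) if rows else _default_header(table)
        with open(fpath, "w", encoding="utf-8") as fh:
            fh.write(DELIM.join(escape_field(h) for h in header) + "\n")
            for row in rows:
                fh.write(DELIM.join(escape_field(row.get(h, "")) for h in header) + "\n")
        written.append(fpath)
    del_path = os.path.join(path, f"{DELETED_PREFIX}{quarter.quarter_id}.txt")
    with open(del_path, "w", encoding="utf-8") as fh:
        for caseid in quarter.deleted_caseids:
            fh.write(f"{caseid}\n")
    written.append(del_path)
    return written


def _default_header(table: str) -> list[str]:
    return {
        "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                 "wt", "wt_cod", "sex", "occr_country", "occp_cod"],
        "DRUG": ["primaryid", "drug_seq", "drugname", "role_cod"],
        "REAC": ["primaryid", "pt"],
        "OUTC": ["primaryid", "outc_cod"],
        "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
        "INDI": ["primaryid", "indi_drug_seq", "indi_pt"],
    }[table]


# ---------------------------------------------------------------------------
# raw rows -> typed records


def demo_records(quarters: Iterable[RawQuarter],
                 warnings: Optional[ParseWarnings] = None) -> list[DemoRecord]:
    warnings = warnings if warnings is not None else ParseWarnings()
    records = []
    for quarter in quarters:
        for row in quarter.demo_rows:
            fda = parse_date(row.get("fda_dt", ""), warnings)
            event = parse_date(row.get("event_dt", ""), warnings)
            if not fda.is_full:
                warnings.add("demo_bad_fda_dt")
                continue
            if event.is_full and event.value > fda.value:
                warnings.add("event_after_receipt")
            unit = row.get("age_cod", "").strip().upper() or None
            wunit = row.get("wt_cod", "").strip().upper() or None
            records.append(DemoRecord(
                primaryid=int(row["primaryid"]),
                caseid=int(row["caseid"]),
                fda_dt=fda,
                event_dt=event,
                age_value=_parse_number(row.get("age", ""), warnings, "bad_age"),
                age_unit=unit if unit in AGE_UNITS else unit,
                weight_value=_parse_number(row.get("wt", ""), warnings, "bad_weight"),
                weight_unit=wunit,
                sex=row.get("sex", "").strip() or None,
                country=row.get("occr_country", "").strip() or None,
                occupation=row.get("occp_cod", "").strip() or None,
            ))
    return records


def drug_records(quarters: Iterable[RawQuarter],
                 warnings: Optional[ParseWarnings] = None) -> list[DrugRecord]:
    warnings = warnings if warnings is not None else ParseWarnings()
    # indication PTs live in INDI, keyed by (primaryid, drug_seq)
    indications: dict[tuple[int, int], str] = {}
    for quarter in quarters:
        for row in quarter.indi_rows:
            key = (int(row["primaryid"]), int(row.get("indi_drug_seq", 0) or 0))
            pt = row.get("indi_pt", "").strip()
            if pt:
                indications[key] = pt
    records = []
    for quarter in quarters:
        for row in quarter.drug_rows:
            role = row.get("role_cod", "").strip().upper()
            if role not in ROLE_CODES:
                warnings.add("bad_role_cod")
                continue
            primaryid = int(row["primaryid"])
            drug_seq = int(row.get("drug_seq", 0) or 0)
            records.append(DrugRecord(
                primaryid=primaryid,
                drug_seq=drug_seq,
                drugname=row.get("drugname", "").strip(),
                role_cod=role,
                indication_pt=indications.get((primaryid, drug_seq)),
            ))
    return records


def reac_records(quarters: Iterable[RawQuarter],
                 warnings: Optional[ParseWarnings] = None) -> list[ReacRecord]:
    warnings = warnings if warnings is not None else ParseWarnings()
    records = []
    for quarter in quarters:
        for row in quarter.reac_rows:
            pt = " ".join(row.get("pt", "").split())
            if not pt:
                warnings.add("empty_pt")
                continue
            records.append(ReacRecord(primaryid=int(row["primaryid"]), pt=pt))
    return records


def outc_records(quarters: Iterable[RawQuarter],
                 warnings: Optional[ParseWarnings] = None) -> list[OutcRecord]:
    warnings = warnings if warnings is not None else ParseWarnings()
    records = []
    for quarter in quarters:
        for row in quarter.outc_rows:
            code = row.get("outc_cod", "").strip().upper()
            if code and code not in OUTCOME_CODES:
                warnings.add("bad_outcome_code")
                continue
            if code:
                records.append(OutcRecord(primaryid=int(row["primaryid"]),
                                          outcome_code=code))
    return records


def ther_records(quarters: Iterable[RawQuarter],
                 warnings: Optional[ParseWarnings] = None) -> list[TherRecord]:
    warnings = warnings if warnings is not None else ParseWarnings()
    records = []
    for quarter in quarters:
        for row in quarter.ther_rows:
            records.append(TherRecord(
                primaryid=int(row["primaryid"]),
                drug_seq=int(row.get("dsg_drug_seq", 0) or 0),
                start_dt=parse_date(row.get("start_dt", ""), warnings),
            ))
    return records


def orphan_primaryids(quarters: Iterable[RawQuarter]) -> dict[str, int]:
    """Count primaryids in child tables that never appear in DEMO.

    Such rows cannot be deduplicated (CASEID and FDA_DT live only in DEMO);
    callers exclude them, and this count makes the exclusion auditable.
    """
    quarters = list(quarters)
    demo_ids = {int(r["primaryid"]) for q in quarters for r in q.demo_rows}
    counts = {}
    for table in ("DRUG", "REAC", "OUTC", "THER", "INDI"):
        n = sum(
            1
            for q in quarters
            for r in q.rows_for(table)
            if int(r["primaryid"]) not in demo_ids
        )
        if n:
            counts[table] = n
    return counts
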