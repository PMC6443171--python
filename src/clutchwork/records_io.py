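"""Domain types and CSV/JSON I/O for reproduction records.

Two kinds of record are handled:

* **Individual records** — the full reproductive history of one animal reared
  in isolation: birth (day 0 = deposition of the zygote it developed from),
  an ordered series of clutch events (day, embryo count), and a death day
  (or a censored flag if recording ended while it was alive).
* **Cohort logs** — the anonymized history of an interbreeding group: the
  initial group size, the multiset of observed death days, and unattributed
  clutch events in day order.

Days are 0-based integers (observations were daily). An animal whose death
day equals ``d`` is counted as *present* on day ``d`` — daily checks record
the last day an animal was seen alive — so ``alive(d)`` counts deaths
strictly before ``d``.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "ClutchEvent",
    "IndividualRecord",
    "CohortLog",
    "ValidationReport",
    "Violation",
    "FormatError",
    "ParseError",
    "RecordValidationError",
    "read_individual_records",
    "write_individual_records",
    "read_cohort_log",
    "write_cohort_log",
    "validate",
]


class FormatError(ValueError):
    """The file does not have the expected shape (e.g. a missing column)."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: Optional[int] = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class RecordValidationError(ValueError):
    """A parsed object breaks a domain invariant."""


@dataclass(frozen=True)
class ClutchEvent:
    """One egg-laying event: deposition day and embryo count.

    ``parent_id`` attributes the clutch to an individual (absent in cohort
    logs). ``estimated`` marks a laying date reconstructed post hoc from the
    developmental stage of the embryos rather than observed directly.
    """

    day: int
    size: int
    parent_id: Optional[str] = None
    estimated: bool = False


@dataclass
class IndividualRecord:
    """Reproductive history of one animal reared in isolation."""

    id: str
    death_day: Optional[int] = None
    censored: bool = False
    clutches: list[ClutchEvent] = field(default_factory=list)

    @property
    def total_embryos(self) -> int:
        return sum(c.size for c in self.clutches)

    @property
    def last_clutch_day(self) -> Optional[int]:
        return self.clutches[-1].day if self.clutches else None


@dataclass
class CohortLog:
    """Anonymized history of an interbreeding group.

    ``death_days`` holds one entry per *observed* death; animals still alive
    when recording ended are simply absent (``len(death_days) <= n0``).
    """

    n0: int
    death_days: list[int] = field(default_factory=list)
    clutches: list[ClutchEvent] = field(default_factory=list)
    label: str = ""

    def alive(self, day: int) -> int:
        """Number of animals present on ``day`` (deaths on ``day`` still count)."""
        return self.n0 - sum(1 for d in self.death_days if d < day)

    @property
    def total_embryos(self) -> int:
        return sum(c.size for c in self.clutches)


@dataclass(frozen=True)
class Violation:
    record_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, record_id: str, rule: str, message: str) -> None:
        self.violations.append(Violation(record_id, rule, message))


# ---------------------------------------------------------------------------
# individuals.csv
#
# Columns: id, death_day, clutch_day, clutch_size[, censored, estimated]
# One row per clutch; an animal with zero clutches gets a single row with
# empty clutch fields. Empty death_day means censored.

_INDIVIDUAL_COLUMNS = ("id", "death_day", "clutch_day", "clutch_size")


def _parse_int(value: str, what: str, row: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{what} is not an integer: {value!r}", row) from None


def read_individual_records(
    path: Union[str, Path],
    dialect: Optional[Mapping[str, str]] = None,
) -> list[IndividualRecord]:
    """Read per-individual reproduction records from CSV.

    ``dialect`` maps canonical column names (``id``, ``death_day``,
    ``clutch_day``, ``clutch_size``) to the headers actually present, for
    files with renamed columns. Rows are grouped by id and clutches sorted
    by day (stable), so row order in the file does not matter.
    """
    path = Path(path)
    colmap = dict(dialect or {})
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        headers = set(reader.fieldnames)
        resolved = {}
        for canon in _INDIVIDUAL_COLUMNS:
            actual = colmap.get(canon, canon)
            if actual not in headers:
                raise FormatError(f"{path}: missing required column {actual!r}")
            resolved[canon] = actual
        has_censored = colmap.get("censored", "censored") in headers
        has_estimated = colmap.get("estimated", "estimated") in headers

        by_id: dict[str, IndividualRecord] = {}
        for i, row in enumerate(reader, start=2):
            rid = (row[resolved["id"]] or "").strip()
            if not rid:
                raise ParseError("empty id", i)
            raw_death = (row[resolved["death_day"]] or "").strip()
            censored = raw_death == ""
            if has_censored:
                flag = (row[colmap.get("censored", "censored")] or "").strip().lower()
                censored = censored or flag in ("1", "true", "yes")
            death_day = None if raw_death == "" else _parse_int(raw_death, "death_day", i)
            rec = by_id.get(rid)
            if rec is None:
                rec = by_id[rid] = IndividualRecord(rid, death_day, censored)
            elif rec.death_day != death_day:
                raise ParseError(f"conflicting death_day for id {rid!r}", i)

            raw_day = (row[resolved["clutch_day"]] or "").strip()
            raw_size = (row[resolved["clutch_size"]] or "").strip()
            if raw_day == "" and raw_size == "":
                continue  # zero-clutch placeholder row
            if raw_day == "" or raw_size == "":
                raise ParseError("clutch_day and clutch_size must both be present", i)
            estimated = False
            if has_estimated:
                flag = (row[colmap.get("estimated", "estimated")] or "").strip().lower()
                estimated = flag in ("1", "true", "yes")
            rec.clutches.append(
                ClutchEvent(
                    day=_parse_int(raw_day, "clutch_day", i),
                    size=_parse_int(raw_size, "clutch_size", i),
                    parent_id=rid,
                    estimated=estimated,
                )
            )

    records = list(by_id.values())
    for rec in records:
        rec.clutches.sort(key=lambda c: c.day)  # stable
        days = [c.day for c in rec.clutches]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise RecordValidationError(
                f"id {rec.id!r}: clutch days not strictly increasing after sort: {days}"
            )
    return records


def write_individual_records(
    records: Sequence[IndividualRecord], path: Union[str, Path]
) -> None:
    """Write records in the canonical individuals.csv form (round-trips)."""
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_INDIVIDUAL_COLUMNS)
    for rec in records:
        death = "" if rec.censored or rec.death_day is None else rec.death_day
        if not rec.clutches:
            writer.writerow([rec.id, death, "", ""])
        for c in rec.clutches:
            writer.writerow([rec.id, death, c.day, c.size])
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# cohort.csv + sidecar JSON
#
# Event rows: event ("death" | "clutch"), day, size (empty for deaths).
# The sidecar <stem>.json holds {"n0": int, "label": str}.


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_cohort_log(path: Union[str, Path]) -> CohortLog:
    """Read a cohort event log (CSV) with its JSON sidecar header."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: missing sidecar header {sidecar.name}")
    header = json.loads(sidecar.read_text(encoding="utf-8"))
    if "n0" not in header:
        raise FormatError(f"{sidecar}: header must contain 'n0'")
    n0 = int(header["n0"])
    label = str(header.get("label", ""))

    deaths: list[int] = []
    clutches: list[ClutchEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"event", "day"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns event, day, size")
        for i, row in enumerate(reader, start=2):
            kind = (row["event"] or "").strip()
            day = _parse_int((row["day"] or "").strip(), "day", i)
            if kind == "death":
                deaths.append(day)
            elif kind == "clutch":
                size = _parse_int((row.get("size") or "").strip(), "size", i)
                clutches.append(ClutchEvent(day=day, size=size))
            else:
                raise ParseError(f"unknown event type {kind!r}", i)
    if len(deaths) > n0:
        raise RecordValidationError(
            f"{path}: {len(deaths)} deaths recorded for an initial cohort of {n0}"
        )
    deaths.sort()
    clutches.sort(key=lambda c: c.day)  # stable: same-day input order kept
    return CohortLog(n0=n0, death_days=deaths, clutches=clutches, label=label)


def write_cohort_log(log: CohortLog, path: Union[str, Path]) -> None:
    """Write a cohort log in canonical form (all events in day order)."""
    path = Path(path)
    events: list[tuple[int, int, str, str]] = []
    # deaths before clutches on the same day only for display stability;
    # ordering within a day carries no meaning for deaths.
    for d in sorted(log.death_days):
        events.append((d, 0, "death", ""))
    for c in log.clutches:
        events.append((c.day, 1, "clutch", str(c.size)))
    events.sort(key=lambda e: (e[0], e[1]))
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["event", "day", "size"])
    for day, _, kind, size in events:
        writer.writerow([kind, day, size])
    path.write_text(buf.getvalue(), encoding="utf-8")
    _sidecar_path(path).write_text(
        json.dumps({"n0": log.n0, "label": log.label}, indent=2) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# validation


def _validate_record(rec: IndividualRecord, report: ValidationReport) -> None:
    if rec.death_day is not None and rec.death_day < 0:
        report.add(rec.id, "death_day_nonnegative", f"death_day {rec.death_day} < 0")
    days = [c.day for c in rec.clutches]
    for a, b in zip(days, days[1:]):
        if b <= a:
            report.add(rec.id, "clutch_days_increasing", f"days {a} -> {b} not strictly increasing")
    for c in rec.clutches:
        if c.day < 0:
            report.add(rec.id, "clutch_day_nonnegative", f"clutch day {c.day} < 0")
        if c.size < 1:
            report.add(rec.id, "clutch_size_positive", f"clutch of {c.size} embryos is invalid")
        if rec.death_day is not None and not rec.censored and c.day > rec.death_day:
            report.add(
                rec.id,
                "clutch_before_death",
                f"clutch on day {c.day} after death on day {rec.death_day}",
            )


def _validate_log(log: CohortLog, report: ValidationReport) -> None:
    rid = log.label or "cohort"
    if log.n0 < 1:
        report.add(rid, "n0_positive", f"n0 = {log.n0}")
    if len(log.death_days) > log.n0:
        report.add(rid, "deaths_within_n0", f"{len(log.death_days)} deaths > n0 = {log.n0}")
    for d in log.death_days:
        if d < 0:
            report.add(rid, "death_day_nonnegative", f"death day {d} < 0")
    days = [c.day for c in log.clutches]
    if days != sorted(days):
        report.add(rid, "clutches_sorted", "clutch events not sorted by day")
    for c in log.clutches:
        if c.day < 0:
            report.add(rid, "clutch_day_nonnegative", f"clutch day {c.day} < 0")
        if c.size < 1:
            report.add(rid, "clutch_size_positive", f"clutch of {c.size} embryos is invalid")


def validate(
    obj: Union[IndividualRecord, CohortLog, Iterable[IndividualRecord]],
) -> ValidationReport:
    """Check every domain invariant; the report is the payload, never raised."""
    report = ValidationReport()
    if isinstance(obj, CohortLog):
        _validate_log(obj, report)
    elif isinstance(obj, IndividualRecord):
        _validate_record(obj, report)
    else:
        for rec in obj:
            _validate_record(rec, report)
    return report
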