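"""Movement-record ingest: parsing, validation, journey assembly.

The movement CSV dialect is comma-separated UTF-8 with header
``admission_id,location,entry_time,exit_time``, ISO-8601 timestamps, and
an empty string for an absent exit time.  Timestamps are timezone-naive
local hospital time; offset-bearing timestamps are rejected row by row so
a mixed-offset file cannot silently produce a mis-ordered journey.

Rows that fail validation are never silently dropped: every rejected row
is collected with its original row number and a reason, and ambiguous
orderings (two records of one admission with identical entry times but
different locations) are resolved deterministically and flagged.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import FormatError, InvalidParameterError

REQUIRED_COLUMNS = ("admission_id", "location", "entry_time", "exit_time")

#: label used by the ``other_bucket`` unmapped-location policy
OTHER_CATEGORY = "OTHER"


@dataclass(frozen=True)
class MovementEvent:
    """One timestamped stay of one admission in one location."""

    admission_id: str
    location: str
    entry_time: datetime
    exit_time: datetime | None = None


@dataclass(frozen=True)
class PatientJourney:
    """The ordered, compacted sequence of locations of one admission."""

    admission_id: str
    path: tuple[str, ...]


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based, counting the header as row 1
    reason: str
    raw: str


@dataclass
class ParseResult:
    events: list[MovementEvent]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


@dataclass
class JourneyResult:
    journeys: list[PatientJourney]
    #: admissions whose event order needed a deterministic tie-break
    ambiguous_admissions: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.journeys)

    def __len__(self):
        return len(self.journeys)


def _parse_ts(text: str) -> datetime | None:
    """Parse a timezone-naive ISO-8601 timestamp; None for empty."""
    text = text.strip()
    if not text:
        return None
    ts = datetime.fromisoformat(text)  # raises ValueError on junk
    if ts.tzinfo is not None:
        raise FormatError("timezone-aware timestamp")
    return ts


def read_movement_records(source: str | Path | IO[str]) -> ParseResult:
    """Parse a movement CSV into events plus a rejects report.

    Raises :class:`FormatError` if a required column is missing from the
    header.  An empty file yields an empty result with a warning.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_movement_records(fh)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        warnings.warn("movement file is empty", stacklevel=2)
        return ParseResult(events=[])
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    events: list[MovementEvent] = []
    rejects: list[RejectedRow] = []
    n_rows = 0
    for row_number, row in enumerate(reader, start=2):
        n_rows += 1
        raw = ",".join("" if row.get(c) is None else str(row.get(c)) for c in REQUIRED_COLUMNS)

        def reject(reason: str) -> None:
            rejects.append(RejectedRow(row_number, reason, raw))

        admission_id = (row.get("admission_id") or "").strip()
        location = (row.get("location") or "").strip()
        if not admission_id:
            reject("missing admission_id")
            continue
        if not location:
            reject("empty location")
            continue
        try:
            entry = _parse_ts(row.get("entry_time") or "")
        except (ValueError, FormatError) as exc:
            reject(f"unparseable entry_time ({exc})")
            continue
        if entry is None:
            reject("missing entry_time")
            continue
        try:
            exit_ = _parse_ts(row.get("exit_time") or "")
        except (ValueError, FormatError) as exc:
            reject(f"unparseable exit_time ({exc})")
            continue
        if exit_ is not None and not entry < exit_:
            reject("inverted interval")
            continue
        events.append(MovementEvent(admission_id, location, entry, exit_))

    if n_rows == 0:
        warnings.warn("movement file has a header but no rows", stacklevel=2)
    return ParseResult(events=events, rejects=rejects)


def write_movement_records(
    events: Iterable[MovementEvent], sink: str | Path | IO[str]
) -> None:
    """Write events in the movement CSV dialect."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            write_movement_records(events, fh)
        return
    writer = csv.writer(sink)
    writer.writerow(REQUIRED_COLUMNS)
    for ev in events:
        writer.writerow(
            [
                ev.admission_id,
                ev.location,
                ev.entry_time.isoformat(),
                "" if ev.exit_time is None else ev.exit_time.isoformat(),
            ]
        )


def compact_path(path: Sequence[str]) -> tuple[str, ...]:
    """Collapse consecutive duplicate locations; idempotent.

    A record of the same location twice in a row is a continued stay, not
    a transfer, so it contributes no edge.
    """
    out: list[str] = []
    for loc in path:
        if not out or out[-1] != loc:
            out.append(loc)
    return tuple(out)


def assemble_journeys(events: Iterable[MovementEvent]) -> JourneyResult:
    """Group events by admission, order them in time, compact repeats.

    Events lacking an exit time are kept — ordering uses the entry time.
    Ties on entry time are broken by exit time then lexicographic
    location; admissions needing such a tie-break are flagged as
    ambiguous, since simultaneous records cannot encode a true order.
    """
    by_admission: dict[str, list[MovementEvent]] = {}
    for ev in events:
        by_admission.setdefault(ev.admission_id, []).append(ev)

    journeys: list[PatientJourney] = []
    ambiguous: list[str] = []
    for admission_id in sorted(by_admission):
        evs = by_admission[admission_id]
        locs_at = {}
        for ev in evs:
            locs_at.setdefault(ev.entry_time, set()).add(ev.location)
        if any(len(ls) > 1 for ls in locs_at.values()):
            ambiguous.append(admission_id)
        evs.sort(
            key=lambda ev: (
                ev.entry_time,
                ev.exit_time or datetime.max,
                ev.location,
            )
        )
        path = compact_path([ev.location for ev in evs])
        journeys.append(PatientJourney(admission_id, path))
    return JourneyResult(journeys=journeys, ambiguous_admissions=ambiguous)


def read_category_map(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a ``location,category`` CSV into a mapping."""
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_category_map(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None or not {"location", "category"} <= set(reader.fieldnames):
        raise FormatError("category map must have columns: location, category")
    mapping: dict[str, str] = {}
    for row in reader:
        loc = (row.get("location") or "").strip()
        cat = (row.get("category") or "").strip()
        if not loc or not cat:
            raise FormatError("category map rows must have location and category")
        mapping[loc] = cat
    return mapping


def apply_category_map(
    journeys: Iterable[PatientJourney],
    mapping: dict[str, str],
    unmapped_policy: str = "error",
) -> list[PatientJourney]:
    """Replace locations by care categories and re-compact.

    A transfer between two wards of the same category is not a
    category-level transfer, so consecutive same-category entries are
    collapsed again after mapping.

    ``unmapped_policy`` is one of ``error`` (raise, naming the location),
    ``passthrough`` (keep the raw location id) or ``other_bucket`` (map to
    ``OTHER``).
    """
    if unmapped_policy not in ("error", "passthrough", "other_bucket"):
        raise InvalidParameterError(f"unknown unmapped policy {unmapped_policy!r}")
    out = []
    for j in journeys:
        mapped = []
        for loc in j.path:
            if loc in mapping:
                mapped.append(mapping[loc])
            elif unmapped_policy == "passthrough":
                mapped.append(loc)
            elif unmapped_policy == "other_bucket":
                mapped.append(OTHER_CATEGORY)
            else:
                raise FormatError(f"location {loc!r} has no category mapping")
        out.append(PatientJourney(j.admission_id, compact_path(mapped)))
    return out
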