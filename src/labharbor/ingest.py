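"""Parsers for the two raw input shapes the pipeline accepts.

The first is the "untidy" EHR export: a delimited file with exactly four
columns — patient name/MRN, collection date, collection time, and a
single free-text cell holding an entire lab panel ("Sodium 140 mmol/L;
Potassium 4.0 mmol/L; ...").  The second is a tabular data-warehouse
(EDW) export with one result per row, whose column names vary by site
and are supplied as a column map.

Both parsers produce the same atom: a :class:`RawObservation`, one lab
result with source-row provenance.  Tokens or rows that cannot be parsed
are never dropped silently — they are routed to a reject list, so that
``observations + rejects`` always accounts for every candidate record.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import re
from dataclasses import dataclass
from labharbor.dictionary import NUMBER_RE, parse_mdy_date, parse_hm_time
from labharbor.errors import ConfigError, FormatError

__all__ = [
    "RawEhrRow",
    "RawObservation",
    "RejectedToken",
    "PanelGrammar",
    "ColumnMap",
    "parse_ehr_export",
    "explode_panels",
    "parse_edw_export",
    "parse_any_date",
    "parse_any_time",
]


def parse_any_date(raw: str) -> _dt.date:
    """Parse M/D/Y or ISO Y-M-D.  Two-digit years are ambiguous at a
    PHI boundary and are rejected.  Raises ValueError."""
    value = raw.strip()
    if re.match(r"^\d{4}-\d{1,2}-\d{1,2}$", value):
        y, m, d = value.split("-")
        return _dt.date(int(y), int(m), int(d))
    return parse_mdy_date(value)


def parse_any_time(raw: str) -> _dt.time | None:
    """Parse HH:MM (seconds, if present, are truncated).  Empty input
    means the draw was untimed and yields None.  Raises ValueError."""
    value = raw.strip()
    if not value:
        return None
    m = re.match(r"^(\d{1,2}):(\d{2})(?::\d{2})?$", value)
    if not m:
        raise ValueError(f"not an HH:MM time: {raw!r}")
    return parse_hm_time(f"{m.group(1)}:{m.group(2)}")


@dataclass(frozen=True)
class RawEhrRow:
    """One line of the untidy 4-column export, untouched."""

    patient_key: str
    collection_date: str
    collection_time: str
    panel_text: str
    source_row: int = 1  # 1-based line number in the source file


@dataclass(frozen=True)
class RawObservation:
    """One lab result as extracted from a raw export."""

    patient_key: str
    collection_date: _dt.date
    collection_time: _dt.time | None
    source_test_name: str
    raw_value: str
    raw_unit: str = ""
    source_row: int = 1

    def __post_init__(self) -> None:
        if not self.source_test_name:
            raise ValueError("source_test_name must be nonempty")
        if self.source_row < 1:
            raise ValueError("source_row must be >= 1")


@dataclass(frozen=True)
class RejectedToken:
    """A token or row the parser could not interpret, with provenance."""

    source_row: int
    text: str
    reason: str


@dataclass(frozen=True)
class PanelGrammar:
    """How to split a panel cell into individual results.

    Results are separated by ``separator``; each result is
    ``TESTNAME VALUE [UNIT]`` where the unit is a single trailing token.
    A trailing token that itself looks like a value (a decimal numeral,
    or a recognised non-numeric result word such as "refused") is taken
    as the value of a unit-less result.  Test names may contain spaces
    and punctuation.  Sites whose exports use a different intra-cell
    syntax override this object.
    """

    separator: str = ";"
    nonnumeric_values: frozenset[str] = frozenset({"refused", "canceled", "cancelled"})

    def _is_value_token(self, tok: str) -> bool:
        return bool(NUMBER_RE.match(tok)) or tok.casefold() in self.nonnumeric_values

    def parse_token(self, token: str) -> tuple[str, str, str] | None:
        """Split one result token into (name, value, unit).

        Returns None when the token does not fit the grammar.
        """
        words = token.split()
        if len(words) < 2:
            return None
        if self._is_value_token(words[-1]):
            return " ".join(words[:-1]), words[-1], ""
        if len(words) >= 3 and self._is_value_token(words[-2]):
            return " ".join(words[:-2]), words[-2], words[-1]
        return None


def parse_ehr_export(
    stream: str | io.TextIOBase,
    delimiter: str = ",",
    has_header: bool = True,
) -> list[RawEhrRow]:
    """Read an untidy 4-column EHR export.

    Every data line must have exactly 4 columns; a line with any other
    width raises :class:`FormatError` naming the offending line — a
    malformed export should fail loudly, not half-parse.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter=delimiter)
    rows: list[RawEhrRow] = []
    for lineno, row in enumerate(reader, start=1):
        if not any(cell.strip() for cell in row):
            continue
        if has_header and lineno == 1:
            continue
        if len(row) != 4:
            raise FormatError(
                f"line {lineno}: expected 4 columns "
                f"(patient, date, time, results), got {len(row)}"
            )
        rows.append(RawEhrRow(row[0], row[1], row[2], row[3], source_row=lineno))
    return rows


def explode_panels(
    row: RawEhrRow, grammar: PanelGrammar | None = None
) -> tuple[list[RawObservation], list[RejectedToken]]:
    """Explode one panel cell into individual observations.

    Order within the cell is preserved.  Unrecognised tokens, and rows
    whose date or time cannot be parsed, go to the reject list rather
    than being dropped.
    """
    grammar = grammar or PanelGrammar()
    try:
        date = parse_any_date(row.collection_date)
    except ValueError:
        return [], [RejectedToken(row.source_row, row.collection_date, "invalid_date")]
    try:
        time = parse_any_time(row.collection_time)
    except ValueError:
        return [], [RejectedToken(row.source_row, row.collection_time, "invalid_time")]

    observations: list[RawObservation] = []
    rejects: list[RejectedToken] = []
    for token in row.panel_text.split(grammar.separator):
        token = token.strip()
        if not token:
            continue
        parsed = grammar.parse_token(token)
        if parsed is None:
            rejects.append(RejectedToken(row.source_row, token, "unparseable_token"))
            continue
        name, value, unit = parsed
        observations.append(
            RawObservation(
                patient_key=row.patient_key,
                collection_date=date,
                collection_time=time,
                source_test_name=name,
                raw_value=value,
                raw_unit=unit,
                source_row=row.source_row,
            )
        )
    return observations, rejects


@dataclass(frozen=True)
class ColumnMap:
    """Names of the EDW export columns holding each required item.

    ``time`` and ``unit`` may be None for exports that lack them.
    """

    mrn: str = "MRN"
    date: str = "DATE"
    time: str | None = "TIME"
    test: str = "TEST_NAME"
    value: str = "VALUE"
    unit: str | None = "UNIT"


def parse_edw_export(
    stream: str | io.TextIOBase,
    colmap: ColumnMap | None = None,
    delimiter: str = ",",
) -> tuple[list[RawObservation], list[RejectedToken]]:
    """Read a tabular EDW export (one result per row).

    Raises :class:`ConfigError` when the column map references a column
    absent from the file header.  Rows with an empty test name or an
    unparseable date are rejected with provenance.
    """
    colmap = colmap or ColumnMap()
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        return [], []
    idx: dict[str, int] = {}
    for attr in ("mrn", "date", "time", "test", "value", "unit"):
        col = getattr(colmap, attr)
        if col is None:
            continue
        if col not in header:
            raise ConfigError(f"column map references missing column {col!r}")
        idx[attr] = header.index(col)

    observations: list[RawObservation] = []
    rejects: list[RejectedToken] = []
    for lineno, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue

        def cell(attr: str) -> str:
            i = idx.get(attr)
            return row[i].strip() if i is not None and i < len(row) else ""

        test = cell("test")
        if not test:
            rejects.append(RejectedToken(lineno, "", "missing_test_name"))
            continue
        try:
            date = parse_any_date(cell("date"))
        except ValueError:
            rejects.append(RejectedToken(lineno, cell("date"), "invalid_date"))
            continue
        try:
            time = parse_any_time(cell("time"))
        except ValueError:
            rejects.append(RejectedToken(lineno, cell("time"), "invalid_time"))
            continue
        observations.append(
            RawObservation(
                patient_key=cell("mrn"),
                collection_date=date,
                collection_time=time,
                source_test_name=test,
                raw_value=cell("value"),
                raw_unit=cell("unit"),
                source_row=lineno,
            )
        )
    return observations, rejects
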