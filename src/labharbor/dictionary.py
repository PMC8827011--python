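"""The REDCap data dictionary: registry schema, CSV round-trip, and
field-level value validation.

A REDCap project is defined entirely by its data dictionary (DD): a CSV
in which each row declares one field — its variable name, the form
(instrument) it lives on, its type, and a text-validation rule.  The DD
is what makes multi-site aggregation trivial: every site uploads the same
DD, so every site's export has the same columns, codes and formats.

This module models the DD, reads and writes the standard REDCap DD-CSV
dialect, and implements the per-cell validation REDCap applies at import
time (a value that fails validation fails to import).  The packaged
default dictionary defines a repeating ``labs`` instrument capturing 35
clinical laboratory types plus one shared collection date and time per
instance, and the two non-repeating instruments the survival stage reads
(``subject_status`` and ``patient_characteristics``).
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from labharbor.errors import IntegrityError, SchemaError

__all__ = [
    "FieldDef",
    "DataDictionary",
    "ValidationResult",
    "LabType",
    "LAB_TYPES",
    "LAB_PANELS",
    "default_mcc_dictionary",
    "read_dd_csv",
    "write_dd_csv",
    "validate_value",
    "parse_mdy_date",
    "format_mdy_date",
    "parse_hm_time",
]

# Decimal numerals exactly: optional sign, digits with optional point.
# Scientific notation is deliberately excluded — REDCap "number"
# validation does not accept it.
NUMBER_RE = re.compile(r"^[+-]?(?:\d+(?:\.\d*)?|\.\d+)$")

TIME_HM_RE = re.compile(r"^(\d{1,2}):(\d{2})$")

FIELD_TYPES = ("text", "notes", "dropdown", "radio", "yesno", "calc")
VALIDATIONS = ("none", "number", "date_mdy", "time_hm")


@dataclass(frozen=True)
class FieldDef:
    """One row of the data dictionary: a single registry field."""

    variable_name: str
    form_name: str
    field_type: str = "text"
    validation: str = "none"
    label: str = ""
    choices: tuple[tuple[str, str], ...] = ()
    required: bool = False
    #: cells from DD-CSV columns this model does not interpret; preserved
    #: opaquely so read -> write round-trips foreign dictionaries.
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.variable_name or " " in self.variable_name:
            raise SchemaError(
                f"invalid variable name {self.variable_name!r} "
                "(must be nonempty, no spaces)"
            )
        if self.variable_name != self.variable_name.lower():
            raise SchemaError(f"variable name {self.variable_name!r} must be lowercase")
        if self.field_type not in FIELD_TYPES:
            raise SchemaError(f"unknown field type {self.field_type!r}")
        if self.validation not in VALIDATIONS:
            raise SchemaError(f"unknown validation {self.validation!r}")
        if self.validation == "number" and self.field_type != "text":
            raise SchemaError(
                f"{self.variable_name}: number validation requires a text field"
            )
        needs_choices = self.field_type in ("dropdown", "radio")
        if needs_choices != bool(self.choices):
            raise SchemaError(
                f"{self.variable_name}: choices must be nonempty iff the "
                "field is a dropdown or radio"
            )


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of checking one raw value against one field's rule."""

    ok: bool
    field: str
    raw_value: str
    message: str = ""

    def __post_init__(self) -> None:
        if not self.ok and not self.message:
            raise ValueError("failed validation must carry a message")


@dataclass
class DataDictionary:
    """An ordered collection of field definitions plus the set of
    repeating instruments."""

    fields: list[FieldDef] = field(default_factory=list)
    repeating_forms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.fields:
            if f.variable_name in seen:
                raise IntegrityError(f"duplicate variable name {f.variable_name!r}")
            seen.add(f.variable_name)
        self._by_name = {f.variable_name: f for f in self.fields}

    def field_def(self, name: str) -> FieldDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"no field named {name!r} in dictionary") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def form_fields(self, form: str) -> list[FieldDef]:
        return [f for f in self.fields if f.form_name == form]

    @property
    def lab_fields(self) -> list[FieldDef]:
        """Number-validated value fields on the repeating labs form."""
        return [
            f
            for f in self.form_fields("labs")
            if f.validation == "number" and f.field_type == "text"
        ]

    @property
    def lab_field_names(self) -> list[str]:
        return [f.variable_name for f in self.lab_fields]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataDictionary):
            return NotImplemented
        return (
            self.fields == other.fields
            and self.repeating_forms == other.repeating_forms
        )


# ---------------------------------------------------------------------------
# The packaged registry dictionary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabType:
    """Static description of one registry lab type."""

    code: str
    label: str
    unit: str
    panel: str


# The 35 laboratory types captured by the repeating labs instrument, in
# registry order: electrolytes/renal/glucose, general chemistries, liver
# function tests, then hematological studies.  The derived
# neutrophil-to-lymphocyte ratio is intentionally NOT stored — it is
# arithmetic on neut/lymp and is computed at analysis time.
LAB_TYPES: tuple[LabType, ...] = (
    LabType("na", "Sodium", "mmol/L", "electrolytes_renal_glucose"),
    LabType("k", "Potassium", "mmol/L", "electrolytes_renal_glucose"),
    LabType("cl", "Chloride", "mmol/L", "electrolytes_renal_glucose"),
    LabType("co2", "Carbon dioxide", "mmol/L", "electrolytes_renal_glucose"),
    LabType("bun", "Blood urea nitrogen", "mg/dL", "electrolytes_renal_glucose"),
    LabType("cre", "Creatinine", "mg/dL", "electrolytes_renal_glucose"),
    LabType(
        "gfr",
        "Estimated glomerular filtration rate",
        "mL/min/1.73m2",
        "electrolytes_renal_glucose",
    ),
    LabType("glu", "Blood glucose", "mg/dL", "electrolytes_renal_glucose"),
    LabType("anion", "Anion gap", "mmol/L", "electrolytes_renal_glucose"),
    LabType("alb", "Albumin", "g/dL", "general_chemistries"),
    LabType("tbili", "Total bilirubin", "mg/dL", "general_chemistries"),
    LabType("ca", "Calcium", "mg/dL", "general_chemistries"),
    LabType("tp", "Total protein", "g/dL", "general_chemistries"),
    LabType("sgpt", "Alanine aminotransferase", "U/L", "liver_function"),
    LabType("sgot", "Aspartate aminotransferase", "U/L", "liver_function"),
    LabType("alkp", "Alkaline phosphatase", "U/L", "liver_function"),
    LabType("glob", "Globulin", "g/dL", "liver_function"),
    LabType("wbc", "White blood cells", "K/uL", "hematological"),
    LabType("rbc", "Red blood cells", "M/uL", "hematological"),
    LabType("hgb", "Hemoglobin", "g/dL", "hematological"),
    LabType("hct", "Hematocrit", "%", "hematological"),
    LabType("mcv", "Mean corpuscular volume", "fL", "hematological"),
    LabType("mch", "Mean corpuscular hemoglobin", "pg", "hematological"),
    LabType("mchc", "Mean corpuscular hemoglobin conc.", "g/dL", "hematological"),
    LabType("plt", "Platelet count", "K/uL", "hematological"),
    LabType("mpv", "Mean platelet volume", "fL", "hematological"),
    LabType("rdw", "Red cell distribution width", "%", "hematological"),
    LabType("neut", "Percent neutrophils", "%", "hematological"),
    LabType("anc", "Absolute neutrophil count", "K/uL", "hematological"),
    LabType("lymp", "Percent lymphocytes", "%", "hematological"),
    LabType("alc", "Absolute lymphocyte count", "K/uL", "hematological"),
    LabType("mon", "Percent monocytes", "%", "hematological"),
    LabType("amc", "Absolute monocyte count", "K/uL", "hematological"),
    LabType("eosp", "Percent eosinophils", "%", "hematological"),
    LabType("aec", "Absolute eosinophil count", "K/uL", "hematological"),
)

LAB_UNITS: Mapping[str, str] = {t.code: t.unit for t in LAB_TYPES}

#: panel -> lab codes, in presentation order.
LAB_PANELS: dict[str, tuple[str, ...]] = {}
for _t in LAB_TYPES:
    LAB_PANELS.setdefault(_t.panel, ())
    LAB_PANELS[_t.panel] = LAB_PANELS[_t.panel] + (_t.code,)

#: Columns of the repeating labs instrument shared by every instance:
#: one collection event = one date + one time + any subset of lab values.
LAB_DATE_FIELD = "lab_date"
LAB_TIME_FIELD = "lab_time"


def default_mcc_dictionary() -> DataDictionary:
    """The packaged registry data dictionary.

    Defines the repeating ``labs`` instrument with exactly 35
    number-validated lab value fields plus shared collection date
    (M/D/Y) and time (HH:MM) fields, and the non-repeating
    ``subject_status`` and ``patient_characteristics`` instruments used
    by the survival stage.
    """
    fields: list[FieldDef] = [
        FieldDef("record_id", "patient_characteristics", "text", "none", "Record ID"),
        FieldDef(
            "diagnosis_date",
            "patient_characteristics",
            "text",
            "date_mdy",
            "Date of diagnosis",
        ),
        FieldDef(
            "death_date", "subject_status", "text", "date_mdy", "Date of death"
        ),
        FieldDef(
            "last_followup_date",
            "subject_status",
            "text",
            "date_mdy",
            "Date of last follow-up",
        ),
        FieldDef(LAB_DATE_FIELD, "labs", "text", "date_mdy", "Collection date"),
        FieldDef(LAB_TIME_FIELD, "labs", "text", "time_hm", "Collection time"),
    ]
    for t in LAB_TYPES:
        fields.append(
            FieldDef(t.code, "labs", "text", "number", f"{t.label} ({t.unit})")
        )
    return DataDictionary(fields=fields, repeating_forms=frozenset({"labs"}))


# ---------------------------------------------------------------------------
# Value validation
# ---------------------------------------------------------------------------


def parse_mdy_date(raw: str) -> _dt.date:
    """Parse a month/day/four-digit-year date, rejecting impossible
    calendar dates.  Raises ValueError."""
    parts = raw.strip().split("/")
    if len(parts) != 3:
        raise ValueError(f"not an M/D/Y date: {raw!r}")
    m, d, y = parts
    if len(y) != 4:
        raise ValueError(f"year must have 4 digits: {raw!r}")
    if not (m.isdigit() and d.isdigit() and y.isdigit()):
        raise ValueError(f"not an M/D/Y date: {raw!r}")
    return _dt.date(int(y), int(m), int(d))


def format_mdy_date(d: _dt.date) -> str:
    return f"{d.month:02d}/{d.day:02d}/{d.year:04d}"


def parse_hm_time(raw: str) -> _dt.time:
    """Parse an HH:MM clock time (24 h).  Raises ValueError."""
    m = TIME_HM_RE.match(raw.strip())
    if not m:
        raise ValueError(f"not an HH:MM time: {raw!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if not (0 <= hh <= 23 and 0 <= mm <= 59):
        raise ValueError(f"clock time out of range: {raw!r}")
    return _dt.time(hh, mm)


def validate_value(fdef: FieldDef, raw: str) -> ValidationResult:
    """Check one raw value against a field's validation rule.

    Mirrors the check REDCap applies at import: a cell that fails here
    would be flagged by the import tool and block the upload.  Failures
    are returned as results, never raised.  Values are stripped of
    surrounding whitespace before checking (EHR exports pad cells).
    """
    value = raw.strip()

    def fail(msg: str) -> ValidationResult:
        return ValidationResult(False, fdef.variable_name, raw, msg)

    def ok() -> ValidationResult:
        return ValidationResult(True, fdef.variable_name, raw)

    if fdef.field_type in ("dropdown", "radio"):
        codes = {c for c, _ in fdef.choices}
        if value in codes:
            return ok()
        return fail(f"value not among the field's coded choices: {value!r}")
    if fdef.field_type == "yesno":
        if value in ("0", "1"):
            return ok()
        return fail(f"yes/no field requires 0 or 1, got {value!r}")

    if fdef.validation == "number":
        if NUMBER_RE.match(value):
            return ok()
        return fail(f"not a decimal number: {value!r}")
    if fdef.validation == "date_mdy":
        try:
            parse_mdy_date(value)
        except ValueError as exc:
            return fail(str(exc))
        return ok()
    if fdef.validation == "time_hm":
        try:
            parse_hm_time(value)
        except ValueError as exc:
            return fail(str(exc))
        return ok()
    return ok()


# ---------------------------------------------------------------------------
# DD-CSV round trip
# ---------------------------------------------------------------------------

# Standard REDCap data-dictionary header.
DD_COLUMNS = (
    "Variable / Field Name",
    "Form Name",
    "Section Header",
    "Field Type",
    "Field Label",
    "Choices, Calculations, OR Slider Labels",
    "Field Note",
    "Text Validation Type OR Show Slider Number",
    "Text Validation Min",
    "Text Validation Max",
    "Identifier?",
    "Branching Logic (Show field only if...)",
    "Required Field?",
    "Custom Alignment",
    "Question Number (surveys only)",
    "Matrix Group Name",
    "Matrix Ranking?",
    "Field Annotation",
)

_MANDATORY_COLUMNS = (
    "Variable / Field Name",
    "Form Name",
    "Field Type",
    "Field Label",
    "Text Validation Type OR Show Slider Number",
)

# internal validation token <-> REDCap validation-type string
_VALIDATION_OUT = {"none": "", "number": "number", "date_mdy": "date_mdy", "time_hm": "time"}
_VALIDATION_IN = {v: k for k, v in _VALIDATION_OUT.items()}


def _choices_to_csv(choices: Iterable[tuple[str, str]]) -> str:
    return " | ".join(f"{code}, {label}" for code, label in choices)


def _choices_from_csv(raw: str) -> tuple[tuple[str, str], ...]:
    out = []
    for chunk in raw.split("|"):
        chunk = chunk.strip()
        if not chunk:
            continue
        code, _, label = chunk.partition(",")
        out.append((code.strip(), label.strip()))
    return tuple(out)


def write_dd_csv(dd: DataDictionary) -> str:
    """Render a dictionary in the REDCap DD-CSV dialect.

    Column order is fixed; output is deterministic, so
    write -> read -> write is byte-identical.
    """
    extra_cols: list[str] = []
    for f in dd.fields:
        for col, _ in f.extra:
            if col not in extra_cols:
                extra_cols.append(col)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(DD_COLUMNS) + extra_cols)
    for f in dd.fields:
        row = {
            "Variable / Field Name": f.variable_name,
            "Form Name": f.form_name,
            "Field Type": f.field_type,
            "Field Label": f.label,
            "Choices, Calculations, OR Slider Labels": _choices_to_csv(f.choices),
            "Text Validation Type OR Show Slider Number": _VALIDATION_OUT[f.validation],
            "Required Field?": "y" if f.required else "",
        }
        row.update(dict(f.extra))
        writer.writerow([row.get(c, "") for c in list(DD_COLUMNS) + extra_cols])
    return buf.getvalue()


def read_dd_csv(
    stream: str | io.TextIOBase,
    repeating_forms: Iterable[str] | None = None,
) -> DataDictionary:
    """Parse a REDCap DD-CSV.

    The DD-CSV itself does not record which instruments repeat (REDCap
    stores that in project settings); by default any form named ``labs``
    is marked repeating, matching the packaged registry.  Pass
    ``repeating_forms`` to override.

    Raises :class:`SchemaError` on a missing mandatory header column and
    :class:`IntegrityError` on duplicate variable names.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("empty data-dictionary CSV") from None
    for col in _MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(f"data dictionary is missing column {col!r}")
    known = set(DD_COLUMNS)
    idx = {c: i for i, c in enumerate(header)}

    fields: list[FieldDef] = []
    seen: set[str] = set()
    for row in reader:
        if not any(cell.strip() for cell in row):
            continue
        row = row + [""] * (len(header) - len(row))

        def cell(col: str) -> str:
            i = idx.get(col)
            return row[i] if i is not None else ""

        name = cell("Variable / Field Name").strip()
        if name in seen:
            raise IntegrityError(f"duplicate variable name {name!r} in dictionary")
        seen.add(name)
        raw_validation = cell("Text Validation Type OR Show Slider Number").strip()
        if raw_validation not in _VALIDATION_IN:
            raise SchemaError(
                f"field {name!r}: unsupported validation type {raw_validation!r}"
            )
        extra = tuple(
            (c, row[idx[c]]) for c in header if c not in known and row[idx[c]] != ""
        )
        fields.append(
            FieldDef(
                variable_name=name,
                form_name=cell("Form Name").strip(),
                field_type=cell("Field Type").strip() or "text",
                validation=_VALIDATION_IN[raw_validation],
                label=cell("Field Label"),
                choices=_choices_from_csv(
                    cell("Choices, Calculations, OR Slider Labels")
                ),
                required=cell("Required Field?").strip().lower() == "y",
                extra=extra,
            )
        )
    if repeating_forms is None:
        forms = {f.form_name for f in fields}
        repeating = frozenset({"labs"} & forms)
    else:
        repeating = frozenset(repeating_forms)
    return DataDictionary(fields=fields, repeating_forms=repeating)
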