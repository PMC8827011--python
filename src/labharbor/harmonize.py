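"""The pipeline core: remap source test names to registry fields,
enforce dictionary units, clean non-importable values, de-identify,
assign repeat instances, and emit validated REDCap-importable tables.

Design rules this module enforces throughout:

* **Nothing is dropped silently.**  Every raw observation either ends up
  as a value in the import table or as an itemized entry in an
  :class:`ExclusionReport`; the two counts always sum to the input.
* **Matching is exact, not fuzzy.**  Source test names match the lookup
  table case-insensitively after whitespace collapsing, and units match
  the dictionary's allowed set — a near-miss is surfaced as an
  exclusion, never guessed at.  Fuzzy matching is unsafe for clinical
  data.
* **PHI stays on one side.**  MRNs/patient names live only in the
  crosswalk; everything emitted downstream carries registry record_ids,
  and exclusion exports carry source-row provenance instead of keys.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from labharbor import dictionary as dd_mod
from labharbor.dictionary import (
    DataDictionary,
    LAB_DATE_FIELD,
    LAB_TIME_FIELD,
    LAB_TYPES,
    format_mdy_date,
    validate_value,
)
from labharbor.errors import (
    DeidentificationError,
    IntegrityError,
    SchemaError,
)
from labharbor.ingest import (
    RawObservation,
    RejectedToken,
    parse_any_date,
    parse_any_time,
)

__all__ = [
    "LookupEntry",
    "LookupTable",
    "Crosswalk",
    "LabObservation",
    "Exclusion",
    "ExclusionReport",
    "ImportTable",
    "ImportCellError",
    "ErrorReport",
    "default_lookup",
    "DEFAULT_LOINC_MAP",
    "normalize_name",
    "remap_tests",
    "normalize_values",
    "deidentify",
    "assign_instances",
    "to_redcap_long",
    "validate_import",
    "export_import_csv",
    "aggregate_sites",
    "annotate_loinc",
    "run_pipeline",
    "PipelineResult",
    "format_value",
]

REPEAT_INSTRUMENT = "labs"

EXCLUSION_REASONS = (
    "unmapped_test",
    "nonimportable_value",
    "unit_mismatch",
    "invalid_date",
    "unknown_patient",
)


def normalize_name(name: str) -> str:
    """Collapse internal whitespace and case-fold — the equivalence used
    for test-name matching."""
    return " ".join(name.split()).casefold()


def _normalize_unit(unit: str) -> str:
    return unit.strip().casefold()


def format_value(v: float) -> str:
    """Canonical decimal rendering of a lab value (no exponent, no
    trailing zeros), shared by every stage that writes values so that
    round trips are byte-stable."""
    return np.format_float_positional(float(v), trim="-")


# ---------------------------------------------------------------------------
# Lookup table: source test name -> registry field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LookupEntry:
    field_code: str
    allowed_units: frozenset[str]
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


class LookupTable:
    """Key-value table remapping source lab subtypes (the many EHR
    spellings of one test) onto registry field codes, with the units the
    dictionary accepts for each.

    An empty string in ``allowed_units`` means results exported without
    a unit are accepted for that source name; by default a missing unit
    is an exclusion.
    """

    def __init__(self, entries: Mapping[str, LookupEntry]):
        # keys are stored normalized; originals kept for rendering
        self._entries: dict[str, LookupEntry] = {}
        self._originals: dict[str, list[str]] = {}
        for name, entry in entries.items():
            norm = normalize_name(name)
            if norm in self._entries and self._entries[norm] != entry:
                raise IntegrityError(
                    f"conflicting lookup entries for source name {name!r}"
                )
            self._entries[norm] = entry
            self._originals.setdefault(entry.field_code, [])
            if name not in self._originals[entry.field_code]:
                self._originals[entry.field_code].append(name)

    def get(self, source_name: str) -> LookupEntry | None:
        return self._entries.get(normalize_name(source_name))

    def source_names(self, field_code: str) -> list[str]:
        """Original-case source spellings that map to a field."""
        return list(self._originals.get(field_code, []))

    @property
    def field_codes(self) -> set[str]:
        return {e.field_code for e in self._entries.values()}

    def __len__(self) -> int:
        return len(self._entries)

    def validate_against(self, dd: DataDictionary) -> None:
        lab_fields = set(dd.lab_field_names)
        for norm, entry in self._entries.items():
            if entry.field_code not in lab_fields:
                raise SchemaError(
                    f"lookup maps {norm!r} to unknown field {entry.field_code!r}"
                )
            if not entry.allowed_units:
                raise SchemaError(f"lookup entry {norm!r} has no allowed units")

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["source_name", "field_code", "allowed_units", "scale_factor"])
        for code in sorted(self._originals):
            for name in self._originals[code]:
                entry = self._entries[normalize_name(name)]
                w.writerow(
                    [
                        name,
                        entry.field_code,
                        ";".join(sorted(entry.allowed_units)),
                        format_value(entry.scale_factor),
                    ]
                )
        return buf.getvalue()

    @classmethod
    def from_csv(cls, stream: str | io.TextIOBase) -> "LookupTable":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        reader = csv.DictReader(stream)
        required = {"source_name", "field_code", "allowed_units"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise SchemaError(f"lookup CSV missing columns: {missing}")
        entries: dict[str, LookupEntry] = {}
        for row in reader:
            entries[row["source_name"]] = LookupEntry(
                field_code=row["field_code"].strip(),
                allowed_units=frozenset(
                    _normalize_unit(u) for u in row["allowed_units"].split(";") if True
                ),
                scale_factor=float(row.get("scale_factor") or 1.0),
            )
        return cls(entries)


#: A handful of widely used display synonyms for the packaged demo table.
_SYNONYMS: dict[str, tuple[str, ...]] = {
    "na": ("NA", "Sodium, serum"),
    "k": (
        # the registry's worked example: the many spellings one
        # electrolyte acquires across feeds
        "Potassium-External",
        "Potassium(POC)",
        "Potassium, whole-bld",
        "Potassium-Level-External",
        "Potassium, venous",
        "Potassium-whole-bld/plasma",
    ),
    "cl": ("CL", "Chloride, serum"),
    "co2": ("CO2", "Carbon Dioxide, Total"),
    "bun": ("BUN", "Urea Nitrogen"),
    "cre": ("Creatinine, serum", "CRE"),
    "gfr": ("eGFR", "GFR (estimated)"),
    "glu": ("Glucose", "GLU", "Glucose, fasting"),
    "anion": ("Anion Gap",),
    "alb": ("ALB",),
    "tbili": ("Bilirubin, Total", "TBILI"),
    "ca": ("CA", "Calcium, serum"),
    "tp": ("Protein, Total", "TP"),
    "sgpt": ("ALT", "ALT (SGPT)"),
    "sgot": ("AST", "AST (SGOT)"),
    "alkp": ("ALP", "Alk Phos"),
    "glob": ("GLOB",),
    "wbc": ("WBC", "White Blood Cell Count"),
    "rbc": ("RBC", "Red Blood Cell Count"),
    "hgb": ("HGB", "Hgb"),
    "hct": ("HCT", "Hct"),
    "mcv": ("MCV",),
    "mch": ("MCH",),
    "mchc": ("MCHC",),
    "plt": ("PLT", "Platelets"),
    "mpv": ("MPV",),
    "rdw": ("RDW",),
    "neut": ("Neutrophils %", "NEUT%"),
    "anc": ("ANC", "Neutrophils, Absolute"),
    "lymp": ("Lymphocytes %", "LYMP%"),
    "alc": ("ALC", "Lymphocytes, Absolute"),
    "mon": ("Monocytes %", "MON%"),
    "amc": ("AMC", "Monocytes, Absolute"),
    "eosp": ("Eosinophils %", "EOS%"),
    "aec": ("AEC", "Eosinophils, Absolute"),
}


def default_lookup(dd: DataDictionary | None = None) -> LookupTable:
    """The packaged demonstration lookup table.

    For each registry lab field it enumerates the canonical label plus
    the subtype spellings a bulk EHR pull typically produces
    ("-External", "(POC)", warehouse short codes, ...).  It is a demo
    fixture meant to be replaced or extended by each site; real feeds
    will need entries added for their own spellings.
    """
    dd = dd or dd_mod.default_mcc_dictionary()
    labels = {t.code: t.label for t in LAB_TYPES}
    units = {t.code: t.unit for t in LAB_TYPES}
    entries: dict[str, LookupEntry] = {}
    for code in dd.lab_field_names:
        label = labels[code]
        allowed = frozenset({_normalize_unit(units[code])})
        variants = [
            label,
            f"{label}-External",
            f"{label}(POC)",
            f"{label}-Level-External",
        ]
        syn = _SYNONYMS.get(code, ())
        if isinstance(syn, str):  # guard against a bare string
            syn = (syn,)
        variants.extend(syn)
        for v in variants:
            entries[v] = LookupEntry(field_code=code, allowed_units=allowed)
    return LookupTable(entries)


# ---------------------------------------------------------------------------
# Crosswalk (PHI side)
# ---------------------------------------------------------------------------


class Crosswalk:
    """MRN/patient-name -> record_id map.

    This is the only object in the pipeline that holds patient
    identifiers.  It must be injective (two patients may never share a
    record_id) and is stored apart from all shareable outputs.
    """

    def __init__(self, entries: Mapping[str, str], site_prefix: str = ""):
        rev: dict[str, str] = {}
        for key, rid in entries.items():
            if rid in rev:
                raise IntegrityError(
                    f"record_id {rid!r} assigned to more than one patient key"
                )
            rev[rid] = key
        self.entries = dict(entries)
        self.site_prefix = site_prefix

    def record_id(self, patient_key: str) -> str | None:
        return self.entries.get(patient_key)

    def patient_key(self, record_id: str) -> str | None:
        for key, rid in self.entries.items():
            if rid == record_id:
                return key
        return None

    @property
    def patient_keys(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["patient_key", "record_id"])
        for key, rid in self.entries.items():
            w.writerow([key, rid])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, stream: str | io.TextIOBase, site_prefix: str = "") -> "Crosswalk":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        reader = csv.DictReader(stream)
        if reader.fieldnames is None or not {"patient_key", "record_id"} <= set(
            reader.fieldnames
        ):
            raise SchemaError("crosswalk CSV requires patient_key and record_id columns")
        return cls(
            {row["patient_key"]: row["record_id"] for row in reader},
            site_prefix=site_prefix,
        )


# ---------------------------------------------------------------------------
# Observation states and the exclusion report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MappedObservation:
    """A raw observation whose test name resolved to a registry field."""

    raw: RawObservation
    field_code: str
    entry: LookupEntry


@dataclass(frozen=True)
class CleanObservation:
    """A value that passed number and unit checks, still identified."""

    patient_key: str
    field_code: str
    value: float
    unit: str
    collection_date: _dt.date
    collection_time: _dt.time | None
    source_row: int


@dataclass(frozen=True)
class LabObservation:
    """One harmonized, de-identified lab result."""

    record_id: str
    field_code: str
    value: float
    unit: str
    collection_date: _dt.date
    collection_time: _dt.time | None = None
    instance: int | None = None
    source_row: int = 1


@dataclass(frozen=True)
class Exclusion:
    observation: RawObservation
    reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


class ExclusionReport:
    """Itemized record of everything the pipeline refused to import."""

    def __init__(self, excluded: Iterable[Exclusion] = ()):
        self.excluded: list[Exclusion] = list(excluded)

    def add(self, obs: RawObservation, reason: str, detail: str = "") -> None:
        self.excluded.append(Exclusion(obs, reason, detail))

    def extend(self, other: "ExclusionReport") -> None:
        self.excluded.extend(other.excluded)

    @property
    def counts(self) -> Counter:
        return Counter(e.reason for e in self.excluded)

    def __len__(self) -> int:
        return len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        """Shareable tabular form.  Deliberately carries source-row
        provenance instead of patient keys so it can live beside the
        import file without leaking PHI."""
        rows = [
            {
                "source_row": e.observation.source_row,
                "source_test_name": e.observation.source_test_name,
                "raw_value": e.observation.raw_value,
                "raw_unit": e.observation.raw_unit,
                "collection_date": format_mdy_date(e.observation.collection_date),
                "reason": e.reason,
                "detail": e.detail,
            }
            for e in self.excluded
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "source_row",
                "source_test_name",
                "raw_value",
                "raw_unit",
                "collection_date",
                "reason",
                "detail",
            ],
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)


# ---------------------------------------------------------------------------
# Stage 1: test-name remapping
# ---------------------------------------------------------------------------


def remap_tests(
    observations: Sequence[RawObservation], lut: LookupTable
) -> tuple[list[MappedObservation], ExclusionReport]:
    """Tag each observation with its registry field code.

    Matching is case-insensitive after whitespace collapsing and exact
    otherwise; unmapped names are itemized, never guessed.
    """
    mapped: list[MappedObservation] = []
    report = ExclusionReport()
    for obs in observations:
        entry = lut.get(obs.source_test_name)
        if entry is None:
            report.add(obs, "unmapped_test", f"no lookup entry for test name")
        else:
            mapped.append(MappedObservation(obs, entry.field_code, entry))
    return mapped, report


# ---------------------------------------------------------------------------
# Stage 2: value and unit normalization
# ---------------------------------------------------------------------------


def normalize_values(
    mapped: Sequence[MappedObservation],
    dd: DataDictionary,
) -> tuple[list[CleanObservation], ExclusionReport]:
    """Enforce the dictionary's number validation and allowed units.

    Non-numeric result tokens ("refused", "canceled", comparator values
    like "<0.01", stray text) fail number validation and are excluded as
    ``nonimportable_value``.  A unit outside the allowed set for the
    source name — including a missing unit unless the lookup explicitly
    allows one — is a ``unit_mismatch``.  Surviving values are scaled by
    the entry's scale factor and stamped with the field's registry unit.
    """
    registry_units = dict(dd_mod.LAB_UNITS)
    clean: list[CleanObservation] = []
    report = ExclusionReport()
    for m in mapped:
        obs = m.raw
        fdef = dd.field_def(m.field_code)
        result = validate_value(fdef, obs.raw_value)
        if not result.ok:
            report.add(obs, "nonimportable_value", result.message)
            continue
        if _normalize_unit(obs.raw_unit) not in m.entry.allowed_units:
            report.add(
                obs,
                "unit_mismatch",
                f"unit {obs.raw_unit!r} not among allowed units",
            )
            continue
        clean.append(
            CleanObservation(
                patient_key=obs.patient_key,
                field_code=m.field_code,
                value=float(obs.raw_value) * m.entry.scale_factor,
                unit=registry_units.get(m.field_code, obs.raw_unit),
                collection_date=obs.collection_date,
                collection_time=obs.collection_time,
                source_row=obs.source_row,
            )
        )
    return clean, report


# ---------------------------------------------------------------------------
# Stage 3: de-identification
# ---------------------------------------------------------------------------


def deidentify(
    observations: Sequence[CleanObservation],
    xwalk: Crosswalk,
    strict: bool = True,
) -> tuple[list[LabObservation], ExclusionReport]:
    """Replace patient keys with registry record_ids.

    In strict mode an unknown patient key raises
    :class:`DeidentificationError` whose message carries only the source
    row, never the key.  With ``strict=False`` unknowns are itemized as
    ``unknown_patient`` exclusions instead.
    """
    out: list[LabObservation] = []
    report = ExclusionReport()
    for obs in observations:
        rid = xwalk.record_id(obs.patient_key)
        if rid is None:
            if strict:
                raise DeidentificationError(
                    f"source row {obs.source_row}: patient key not in crosswalk"
                )
            raw = RawObservation(
                patient_key=obs.patient_key,
                collection_date=obs.collection_date,
                collection_time=obs.collection_time,
                source_test_name=obs.field_code,
                raw_value=format_value(obs.value),
                raw_unit=obs.unit,
                source_row=obs.source_row,
            )
            report.add(raw, "unknown_patient", f"source row {obs.source_row}")
            continue
        out.append(
            LabObservation(
                record_id=rid,
                field_code=obs.field_code,
                value=obs.value,
                unit=obs.unit,
                collection_date=obs.collection_date,
                collection_time=obs.collection_time,
                source_row=obs.source_row,
            )
        )
    return out, report


# ---------------------------------------------------------------------------
# Stage 4: repeat-instance assignment
# ---------------------------------------------------------------------------


def _time_key(t: _dt.time | None) -> tuple:
    # untimed draws sort before any timed draw on the same date
    return (0,) if t is None else (1, t.hour, t.minute)


def assign_instances(observations: Sequence[LabObservation]) -> list[LabObservation]:
    """Assign each observation its repeating-instrument instance.

    One instance = one collection event (record_id + date + time): all
    labs drawn together share an instance, and repeat draws on the same
    day get consecutive instances in time order.  When the same field
    appears twice at one event (two results in a single exported cell),
    the later-source-ordered result opens a follow-on instance so both
    values are representable.  Instances are numbered 1..k per record in
    chronological order, independent of input order.
    """
    by_record: dict[str, list[tuple[int, LabObservation]]] = {}
    for i, obs in enumerate(observations):
        by_record.setdefault(obs.record_id, []).append((i, obs))

    out: list[tuple[int, LabObservation]] = []
    for rid, items in by_record.items():
        # deterministic processing order: source position breaks ties
        items.sort(key=lambda p: (p[1].source_row, p[0]))
        occurrence: Counter = Counter()
        keyed: list[tuple[tuple, int, LabObservation]] = []
        for pos, obs in items:
            event = (obs.collection_date, _time_key(obs.collection_time))
            occ = occurrence[(event, obs.field_code)]
            occurrence[(event, obs.field_code)] += 1
            keyed.append(((event[0], event[1], occ), pos, obs))
        # events ranked chronologically; duplicate-field occurrences
        # become follow-on events at the same timestamp
        events = sorted({k for k, _, _ in keyed}, key=lambda k: (k[0], k[1], k[2]))
        rank = {e: n + 1 for n, e in enumerate(events)}
        for k, pos, obs in keyed:
            out.append((pos, replace(obs, instance=rank[k])))

    out.sort(key=lambda p: p[0])
    return [obs for _, obs in out]


# ---------------------------------------------------------------------------
# Stage 5: the REDCap-ready import table
# ---------------------------------------------------------------------------

IMPORT_FIXED_COLUMNS = (
    "record_id",
    "redcap_repeat_instrument",
    "redcap_repeat_instance",
    LAB_DATE_FIELD,
    LAB_TIME_FIELD,
)


class ImportTable:
    """A REDCap-importable long table: one row per (record_id, instance)
    of the repeating labs instrument, all cells rendered as text exactly
    as they will appear in the import CSV."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def n_values(self) -> int:
        """Count of filled lab-value cells."""
        lab_cols = [c for c in self.columns if c not in IMPORT_FIXED_COLUMNS]
        if not lab_cols or self.df.empty:
            return 0
        return int((self.df[lab_cols] != "").to_numpy().sum())

    def equals(self, other: "ImportTable") -> bool:
        """Equality up to column order."""
        if set(self.columns) != set(other.columns):
            return False
        cols = sorted(self.columns)
        return self.df[cols].equals(other.df[cols])

    def to_csv(self) -> str:
        return self.df.to_csv(index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, stream: str | io.TextIOBase) -> "ImportTable":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        df = pd.read_csv(stream, dtype=str, keep_default_na=False)
        return cls(df)

    def to_observations(self, dd: DataDictionary) -> list[LabObservation]:
        """Invert the long layout back into per-result observations —
        the form the survival stage and re-harmonization consume."""
        units = dict(dd_mod.LAB_UNITS)
        lab_cols = [c for c in dd.lab_field_names if c in self.columns]
        out: list[LabObservation] = []
        for i, row in self.df.iterrows():
            date = parse_any_date(row[LAB_DATE_FIELD])
            time = parse_any_time(row.get(LAB_TIME_FIELD, ""))
            for code in lab_cols:
                cell = row[code]
                if cell == "":
                    continue
                out.append(
                    LabObservation(
                        record_id=row["record_id"],
                        field_code=code,
                        value=float(cell),
                        unit=units.get(code, ""),
                        collection_date=date,
                        collection_time=time,
                        instance=int(row["redcap_repeat_instance"]),
                        source_row=i + 1,
                    )
                )
        return out


def to_redcap_long(
    observations: Sequence[LabObservation], dd: DataDictionary
) -> ImportTable:
    """Pivot observations into the REDCap import layout.

    One row per (record_id, instance) with the repeat-instrument
    columns, the event's shared date/time, and one column per dictionary
    lab field (blank when not measured at that event).  Requires
    instances to be assigned.  Two different values colliding on the
    same (record, instance, field) cannot be represented and raise
    :class:`IntegrityError`.
    """
    lab_cols = dd.lab_field_names
    columns = list(IMPORT_FIXED_COLUMNS) + lab_cols
    rows: dict[tuple[str, int], dict[str, str]] = {}
    for obs in observations:
        if obs.instance is None:
            raise IntegrityError(
                "observations must have instances assigned before pivoting"
            )
        if obs.field_code not in lab_cols:
            raise SchemaError(f"unknown lab field {obs.field_code!r}")
        key = (obs.record_id, obs.instance)
        row = rows.setdefault(
            key,
            {
                "record_id": obs.record_id,
                "redcap_repeat_instrument": REPEAT_INSTRUMENT,
                "redcap_repeat_instance": str(obs.instance),
                LAB_DATE_FIELD: format_mdy_date(obs.collection_date),
                LAB_TIME_FIELD: (
                    ""
                    if obs.collection_time is None
                    else f"{obs.collection_time.hour:02d}:{obs.collection_time.minute:02d}"
                ),
            },
        )
        rendered = format_value(obs.value)
        existing = row.get(obs.field_code, "")
        if existing and existing != rendered:
            raise IntegrityError(
                f"record {obs.record_id} instance {obs.instance}: two values "
                f"for field {obs.field_code!r} at the same event"
            )
        row[obs.field_code] = rendered

    ordered = sorted(rows, key=lambda k: (k[0], k[1]))
    data = [[rows[k].get(c, "") for c in columns] for k in ordered]
    return ImportTable(pd.DataFrame(data, columns=columns, dtype=str))


# ---------------------------------------------------------------------------
# Stage 6: final import validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImportCellError:
    row: int  # 0-based data row in the table
    column: str
    raw_value: str
    message: str


class ErrorReport:
    """What the REDCap import tool would flag: every nonconforming cell
    with its location and a resolution hint.  A nonempty report blocks
    export unless explicitly forced."""

    def __init__(self, errors: Iterable[ImportCellError] = ()):
        self.errors: list[ImportCellError] = list(errors)

    @property
    def empty(self) -> bool:
        return not self.errors

    def __len__(self) -> int:
        return len(self.errors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": e.row,
                    "column": e.column,
                    "raw_value": e.raw_value,
                    "message": e.message,
                }
                for e in self.errors
            ],
            columns=["row", "column", "raw_value", "message"],
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)


def validate_import(tbl: ImportTable, dd: DataDictionary) -> ErrorReport:
    """Check every cell of an import table against the dictionary.

    This is the pre-flight equivalent of REDCap's import screen: a
    malformed date, a non-numeric lab value, or a bad instance number is
    reported by (row, column) so it can be corrected before upload.
    """
    errors: list[ImportCellError] = []
    lab_fields = set(dd.lab_field_names)
    for i, row in tbl.df.iterrows():
        if row.get("record_id", "") == "":
            errors.append(ImportCellError(i, "record_id", "", "record_id is empty"))
        inst = row.get("redcap_repeat_instance", "")
        if not (inst.isdigit() and int(inst) >= 1):
            errors.append(
                ImportCellError(
                    i,
                    "redcap_repeat_instance",
                    inst,
                    "repeat instance must be a positive integer",
                )
            )
        for col in tbl.columns:
            if col in ("record_id", "redcap_repeat_instrument", "redcap_repeat_instance"):
                continue
            cell = row[col]
            if col in lab_fields and cell == "":
                continue  # unmeasured lab at this event
            if col == LAB_TIME_FIELD and cell == "":
                continue  # untimed draw
            if col not in dd:
                continue  # foreign column: not this dictionary's concern
            result = validate_value(dd.field_def(col), cell)
            if not result.ok:
                errors.append(ImportCellError(i, col, cell, result.message))
    return ErrorReport(errors)


# ---------------------------------------------------------------------------
# Multi-site aggregation and LOINC annotation
# ---------------------------------------------------------------------------


def aggregate_sites(tables: Sequence[ImportTable]) -> ImportTable:
    """Combine per-site import tables into one multisite table.

    Because every site uses the same dictionary, aggregation is plain
    row-wise concatenation — but the headers must agree exactly and
    record_id sets must be disjoint (the site prefix guarantees this
    when used)."""
    if not tables:
        return ImportTable(pd.DataFrame(columns=list(IMPORT_FIXED_COLUMNS)))
    ref = tables[0].columns
    for t in tables[1:]:
        if t.columns != ref:
            diff = set(t.columns) ^ set(ref)
            name = sorted(diff)[0] if diff else "(column order)"
            raise SchemaError(f"site tables disagree on column {name!r}")
    seen: dict[str, int] = {}
    for site_no, t in enumerate(tables):
        for rid in t.df["record_id"].unique():
            if rid in seen and seen[rid] != site_no:
                raise IntegrityError(
                    f"record_id {rid!r} appears in more than one site table"
                )
            seen[rid] = site_no
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return ImportTable(df)


def export_import_csv(
    tbl: ImportTable,
    dd: DataDictionary,
    path,
    force: bool = False,
) -> ErrorReport:
    """Write an import CSV only if it validates.

    Mirrors the registry discipline that data with errors must not reach
    the import tool: a nonempty validation report raises
    :class:`IntegrityError` unless ``force`` is set.  Returns the report
    either way.
    """
    from pathlib import Path

    report = validate_import(tbl, dd)
    if not report.empty and not force:
        raise IntegrityError(
            f"{len(report)} validation errors; refusing to write import file"
        )
    Path(path).write_text(tbl.to_csv())
    return report


#: One standard LOINC code per registry lab field, for interoperability
#: annotation after import.  These are common serum/blood codes chosen
#: for the demo configuration; registries adopting the package should
#: review and edit the map for their own assays.
DEFAULT_LOINC_MAP: dict[str, str] = {
    "na": "2951-2",
    "k": "2823-3",
    "cl": "2075-0",
    "co2": "2028-9",
    "bun": "3094-0",
    "cre": "2160-0",
    "gfr": "33914-3",
    "glu": "2345-7",
    "anion": "33037-3",
    "alb": "1751-7",
    "tbili": "1975-2",
    "ca": "17861-6",
    "tp": "2885-2",
    "sgpt": "1742-6",
    "sgot": "1920-8",
    "alkp": "6768-6",
    "glob": "10834-0",
    "wbc": "6690-2",
    "rbc": "789-8",
    "hgb": "718-7",
    "hct": "4544-3",
    "mcv": "787-2",
    "mch": "785-6",
    "mchc": "786-4",
    "plt": "777-3",
    "mpv": "32623-1",
    "rdw": "788-0",
    "neut": "770-8",
    "anc": "751-8",
    "lymp": "736-9",
    "alc": "731-0",
    "mon": "5905-5",
    "amc": "742-7",
    "eosp": "713-8",
    "aec": "711-2",
}


def annotate_loinc(
    dd: DataDictionary,
    loinc_map: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Emit the field -> LOINC annotation table: exactly one code per
    covered lab field, in dictionary order.

    Annotation is a post-import interoperability step; it never alters
    the data.  A field assigned two codes raises
    :class:`IntegrityError`; a code assigned to a field the dictionary
    does not define raises :class:`SchemaError`.
    """
    if loinc_map is None:
        loinc_map = DEFAULT_LOINC_MAP
    pairs = list(loinc_map.items()) if isinstance(loinc_map, Mapping) else list(loinc_map)
    lab_fields = set(dd.lab_field_names)
    assigned: dict[str, str] = {}
    for code_field, loinc in pairs:
        if code_field not in lab_fields:
            raise SchemaError(f"LOINC map covers unknown lab field {code_field!r}")
        if code_field in assigned:
            raise IntegrityError(f"field {code_field!r} assigned more than one LOINC code")
        assigned[code_field] = loinc
    order = [c for c in dd.lab_field_names if c in assigned]
    return pd.DataFrame(
        {"field_code": order, "loinc_code": [assigned[c] for c in order]}
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    import_table: ImportTable
    exclusions: ExclusionReport
    n_raw: int

    @property
    def n_imported(self) -> int:
        return self.import_table.n_values

    @property
    def conserved(self) -> bool:
        """|raw| == |imported values| + |itemized exclusions|."""
        return self.n_raw == self.n_imported + len(self.exclusions)


def run_pipeline(
    observations: Sequence[RawObservation],
    lut: LookupTable,
    xwalk: Crosswalk,
    dd: DataDictionary,
    strict: bool = True,
) -> PipelineResult:
    """Run remap -> normalize -> de-identify -> instance assignment ->
    pivot, accumulating one exclusion report across stages."""
    report = ExclusionReport()
    mapped, r1 = remap_tests(observations, lut)
    report.extend(r1)
    clean, r2 = normalize_values(mapped, dd)
    report.extend(r2)
    deid, r3 = deidentify(clean, xwalk, strict=strict)
    report.extend(r3)
    table = to_redcap_long(assign_instances(deid), dd)
    return PipelineResult(import_table=table, exclusions=report, n_raw=len(observations))
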