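"""Ground-truth cohort generator and messy-input renderers.

Every downstream stage is testable without any real patient data: this
module simulates a registry cohort with known lab values and a known
survival structure, then renders it into the raw shapes the pipeline
consumes — the untidy 4-column EHR export (whole panels in one cell,
subtype spellings varying per draw, "refused"/"canceled" tokens and
off-dictionary units planted at known rates) and the tabular EDW export.
Each planted corruption is recorded in a sidecar manifest so the
pipeline's exclusion accounting can be checked item-for-item.

The survival structure is an exponential proportional-hazards model:
subject i's event time is exponential with rate
``baseline_hazard * exp(sum_f beta_f * (x_if - mean_f))`` where x_if is
the subject's baseline value for lab f, with independent exponential
censoring whose per-subject rate is tuned so every subject is censored
with probability ``censor_rate`` exactly.  Lab values are drawn from
per-field reference-range normals — plausibility scaffolding for
testing, not clinical claims.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from labharbor import harmonize as hz
from labharbor.dictionary import (
    DataDictionary,
    LAB_TYPES,
    default_mcc_dictionary,
    format_mdy_date,
)
from labharbor.harmonize import (
    Crosswalk,
    ImportTable,
    LabObservation,
    LookupTable,
    assign_instances,
    default_lookup,
    format_value,
    to_redcap_long,
)
from labharbor.survival import (
    PatientCharacteristics,
    SubjectStatus,
)

__all__ = [
    "RefRange",
    "REFERENCE_RANGES",
    "CorruptionRates",
    "SimulationConfig",
    "GroundTruth",
    "PlantedCorruption",
    "CellCorruption",
    "simulate_cohort",
    "simulate_survival_days",
    "render_untidy",
    "render_edw",
    "inject_errors",
    "manifest_to_json",
]


@dataclass(frozen=True)
class RefRange:
    """Sampling distribution for one lab: Normal(mean, sd), reported to
    ``decimals`` places, floored at zero."""

    mean: float
    sd: float
    decimals: int


#: Adult reference-interval midpoints with spreads wide enough to give
#: the Cox screen covariate variation.  Units follow the dictionary.
REFERENCE_RANGES: dict[str, RefRange] = {
    "na": RefRange(140, 3, 0),
    "k": RefRange(4.2, 0.4, 1),
    "cl": RefRange(103, 3, 0),
    "co2": RefRange(25, 2, 0),
    "bun": RefRange(16, 5, 0),
    "cre": RefRange(1.0, 0.3, 2),
    "gfr": RefRange(85, 15, 0),
    "glu": RefRange(100, 20, 0),
    "anion": RefRange(10, 2, 0),
    "alb": RefRange(4.2, 0.4, 1),
    "tbili": RefRange(0.7, 0.3, 1),
    "ca": RefRange(9.4, 0.5, 1),
    "tp": RefRange(7.0, 0.5, 1),
    "sgpt": RefRange(30, 12, 0),
    "sgot": RefRange(28, 10, 0),
    "alkp": RefRange(80, 25, 0),
    "glob": RefRange(2.8, 0.4, 1),
    "wbc": RefRange(7.0, 2.0, 1),
    "rbc": RefRange(4.8, 0.5, 2),
    "hgb": RefRange(13.5, 1.5, 1),
    "hct": RefRange(41, 4, 1),
    "mcv": RefRange(90, 5, 1),
    "mch": RefRange(30, 2, 1),
    "mchc": RefRange(33.5, 1.0, 1),
    "plt": RefRange(250, 60, 0),
    "mpv": RefRange(10.5, 1.0, 1),
    "rdw": RefRange(13.5, 1.2, 1),
    "neut": RefRange(60, 10, 1),
    "anc": RefRange(4.2, 1.5, 2),
    "lymp": RefRange(30, 8, 1),
    "alc": RefRange(2.1, 0.8, 2),
    "mon": RefRange(8, 2, 1),
    "amc": RefRange(0.5, 0.15, 2),
    "eosp": RefRange(3, 1.5, 1),
    "aec": RefRange(0.15, 0.1, 2),
}

_UNITS = {t.code: t.unit for t in LAB_TYPES}

#: Plausible-but-wrong units used when planting unit variants, one per
#: canonical unit, chosen so none case-folds to the canonical spelling.
OFF_DD_UNITS: dict[str, str] = {
    "mmol/L": "mEq/dL",
    "mg/dL": "mg/L",
    "g/dL": "g/L",
    "U/L": "IU/mL",
    "%": "fraction",
    "K/uL": "10^3/mm3",
    "M/uL": "10^6/mm3",
    "fL": "um3",
    "pg": "pcg",
    "mL/min/1.73m2": "mL/min",
}


@dataclass(frozen=True)
class CorruptionRates:
    """Per-value probabilities of the corruptions a real export shows."""

    refused: float = 0.01
    canceled: float = 0.01
    unit_variant: float = 0.01
    duplicate_draw: float = 0.05  # per-subject probability of a same-day repeat

    def __post_init__(self) -> None:
        for name in ("refused", "canceled", "unit_variant", "duplicate_draw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must be in [0, 1]")
        if self.refused + self.canceled + self.unit_variant > 1.0:
            raise ValueError("per-value corruption rates must sum to <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 300
    seed: int = 0
    #: mean number of extra (non-baseline) draws per subject
    extra_draws_mean: float = 2.0
    #: log hazard ratios per unit of each named lab; unnamed labs are null
    true_log_hr: Mapping[str, float] = field(default_factory=dict)
    #: events per day at the reference covariate profile (median ~2 y)
    baseline_hazard: float = 1.0 / 730.0
    censor_rate: float = 0.3
    corruption: CorruptionRates = field(default_factory=CorruptionRates)
    site_prefix: str = ""

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        for code in self.true_log_hr:
            if code not in REFERENCE_RANGES:
                raise ValueError(f"true_log_hr names unknown lab {code!r}")


@dataclass(frozen=True)
class PlantedCorruption:
    """One corruption planted by the renderer, keyed so the pipeline's
    exclusion report can be matched against it."""

    record_id: str
    field_code: str
    collection_date: _dt.date
    collection_time: _dt.time | None
    kind: str  # "refused" | "canceled" | "unit_variant"
    original_value: float

    @property
    def expected_reason(self) -> str:
        return {
            "refused": "nonimportable_value",
            "canceled": "nonimportable_value",
            "unit_variant": "unit_mismatch",
        }[self.kind]


@dataclass
class GroundTruth:
    """A fully known registry cohort."""

    observations: list[LabObservation]
    status: list[SubjectStatus]
    chars: list[PatientCharacteristics]
    crosswalk: Crosswalk

    def import_table(self, dd: DataDictionary | None = None) -> ImportTable:
        """The REDCap import table a perfect pipeline would produce."""
        dd = dd or default_mcc_dictionary()
        return to_redcap_long(assign_instances(self.observations), dd)


def simulate_survival_days(
    rng: np.random.Generator,
    linpred: np.ndarray,
    baseline_hazard: float,
    censor_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with per-subject hazard
    ``baseline_hazard * exp(linpred)`` and independent exponential
    censoring tuned so P(censored) = ``censor_rate`` for every subject.

    Returns (time_days, event) with times rounded up to whole days.
    """
    lam = baseline_hazard * np.exp(np.asarray(linpred, dtype=float))
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        # for competing exponentials, P(censor) = mu / (lam + mu)
        mu = lam * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / mu)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    days = np.maximum(np.ceil(time), 1.0)
    return days.astype(int), event


def _draw_panel(rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for code, ref in REFERENCE_RANGES.items():
        v = rng.normal(ref.mean, ref.sd)
        v = max(round(v, ref.decimals), 0.0)
        out[code] = float(v)
    return out


def simulate_cohort(cfg: SimulationConfig) -> GroundTruth:
    """Generate a reproducible ground-truth cohort.

    Each subject gets a diagnosis date, a baseline blood draw near
    diagnosis (within the default baseline window), a Poisson number of
    additional draws, an event/censoring time driven by the configured
    log hazard ratios applied to the subject's *baseline* values
    (centered at the reference means), and — at the configured rate — a
    same-day repeat draw to exercise the repeating-instrument logic.
    """
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_subjects)))
    prefix = f"{cfg.site_prefix}-" if cfg.site_prefix else ""

    record_ids = [f"{prefix}{i + 1:0{width}d}" for i in range(cfg.n_subjects)]
    mrn_numbers: list[int] = []
    seen_mrns: set[int] = set()
    while len(mrn_numbers) < cfg.n_subjects:
        n = int(rng.integers(10_000_000, 100_000_000))
        if n not in seen_mrns:
            seen_mrns.add(n)
            mrn_numbers.append(n)
    crosswalk = Crosswalk(
        {f"MRN{n}": rid for n, rid in zip(mrn_numbers, record_ids)},
        site_prefix=cfg.site_prefix,
    )

    epoch = _dt.date(2016, 1, 1)
    observations: list[LabObservation] = []
    status: list[SubjectStatus] = []
    chars: list[PatientCharacteristics] = []

    # baseline values drive the hazard; draw them first per subject
    baselines = [_draw_panel(rng) for _ in range(cfg.n_subjects)]
    linpred = np.zeros(cfg.n_subjects)
    for code, beta in cfg.true_log_hr.items():
        ref = REFERENCE_RANGES[code]
        xs = np.array([b[code] for b in baselines])
        linpred += beta * (xs - ref.mean)
    time_days, events = simulate_survival_days(
        rng, linpred, cfg.baseline_hazard, cfg.censor_rate
    )

    source_row = 0
    for i, rid in enumerate(record_ids):
        dx = epoch + _dt.timedelta(days=int(rng.integers(0, 1461)))
        chars.append(PatientCharacteristics(record_id=rid, diagnosis_date=dx))
        end = dx + _dt.timedelta(days=int(time_days[i]))
        status.append(
            SubjectStatus(
                record_id=rid,
                last_followup_date=end,
                death_date=end if events[i] else None,
            )
        )

        # collection events: baseline draw near dx plus extras
        draw_offsets = [int(rng.integers(-30, 6))]
        n_extra = int(rng.poisson(cfg.extra_draws_mean))
        for _ in range(n_extra):
            draw_offsets.append(int(rng.integers(-90, 121)))
        offsets = sorted(set(draw_offsets))
        # the draw the baseline-selection rule (nearest diagnosis within
        # the default window, earlier on ties) will pick carries the
        # hazard-driving panel, so analysis sees the true covariate
        eligible = [o for o in offsets if -90 <= o <= 30]
        baseline_offset = min(eligible, key=lambda o: (abs(o), o))
        draws: list[tuple[_dt.date, _dt.time, dict[str, float]]] = []
        for off in offsets:
            date = dx + _dt.timedelta(days=off)
            hh = int(rng.integers(6, 12))
            mm = int(rng.integers(0, 60))
            panel = baselines[i] if off == baseline_offset else _draw_panel(rng)
            draws.append((date, _dt.time(hh, mm), panel))
        if rng.random() < cfg.corruption.duplicate_draw:
            # same-day repeat: second draw later the same day
            date, t0, _ = draws[0]
            hh = min(t0.hour + int(rng.integers(2, 8)), 23)
            draws.append((date, _dt.time(hh, t0.minute), _draw_panel(rng)))

        for date, time, panel in draws:
            for code, value in panel.items():
                source_row += 1
                observations.append(
                    LabObservation(
                        record_id=rid,
                        field_code=code,
                        value=value,
                        unit=_UNITS[code],
                        collection_date=date,
                        collection_time=time,
                        source_row=source_row,
                    )
                )

    observations = assign_instances(observations)
    return GroundTruth(
        observations=observations, status=status, chars=chars, crosswalk=crosswalk
    )


# ---------------------------------------------------------------------------
# Renderers: ground truth -> messy inputs
# ---------------------------------------------------------------------------


def _corrupt_value(
    rng: np.random.Generator, rates: CorruptionRates
) -> str | None:
    """Decide the fate of one rendered value: None = clean, else the
    corruption kind."""
    u = rng.random()
    if u < rates.refused:
        return "refused"
    if u < rates.refused + rates.canceled:
        return "canceled"
    if u < rates.refused + rates.canceled + rates.unit_variant:
        return "unit_variant"
    return None


def render_untidy(
    truth: GroundTruth,
    lut: LookupTable | None = None,
    rates: CorruptionRates | None = None,
    seed: int = 0,
    separator: str = "; ",
) -> tuple[str, list[PlantedCorruption]]:
    """Render ground truth as the untidy 4-column EHR export.

    Each collection event becomes one line whose last cell holds the
    whole panel; each lab is written under a source spelling drawn at
    random from the lookup table's subtypes for that field, so the
    remapping stage has real work to do.  Corruptions are planted at the
    configured per-value rates and returned as a manifest.

    With all rates zero the render is lossless:
    ``pipeline(render_untidy(T))`` reproduces ``T.import_table()``.
    """
    lut = lut or default_lookup()
    rates = rates or CorruptionRates(0, 0, 0, 0)
    rng = np.random.default_rng(seed)
    key_of = {rid: key for key, rid in truth.crosswalk.entries.items()}

    events: dict[tuple[str, _dt.date, _dt.time | None], list[LabObservation]] = {}
    for obs in truth.observations:
        events.setdefault(
            (obs.record_id, obs.collection_date, obs.collection_time), []
        ).append(obs)

    manifest: list[PlantedCorruption] = []
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["Patient Name (MRN)", "Collection Date", "Collection Time", "Lab Results"])
    for (rid, date, time), group in sorted(
        events.items(),
        key=lambda kv: (kv[0][0], kv[0][1], (0,) if kv[0][2] is None else (1, kv[0][2].hour, kv[0][2].minute)),
    ):
        tokens = []
        for obs in sorted(group, key=lambda o: o.source_row):
            names = lut.source_names(obs.field_code) or [obs.field_code]
            name = names[int(rng.integers(0, len(names)))]
            value = format_value(obs.value)
            unit = _UNITS[obs.field_code]
            kind = _corrupt_value(rng, rates)
            if kind in ("refused", "canceled"):
                value = kind
            elif kind == "unit_variant":
                unit = OFF_DD_UNITS[unit]
            if kind is not None:
                manifest.append(
                    PlantedCorruption(
                        record_id=rid,
                        field_code=obs.field_code,
                        collection_date=date,
                        collection_time=time,
                        kind=kind,
                        original_value=obs.value,
                    )
                )
            tokens.append(f"{name} {value} {unit}")
        w.writerow(
            [
                key_of[rid],
                format_mdy_date(date),
                "" if time is None else f"{time.hour:02d}:{time.minute:02d}",
                separator.join(tokens),
            ]
        )
    return buf.getvalue(), manifest


def render_edw(
    truth: GroundTruth,
    lut: LookupTable | None = None,
    seed: int = 0,
) -> str:
    """Render ground truth as a clean tabular EDW export (one result per
    row, default column names matching :class:`labharbor.ingest.ColumnMap`)."""
    lut = lut or default_lookup()
    rng = np.random.default_rng(seed)
    key_of = {rid: key for key, rid in truth.crosswalk.entries.items()}
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["MRN", "DATE", "TIME", "TEST_NAME", "VALUE", "UNIT"])
    for obs in truth.observations:
        names = lut.source_names(obs.field_code) or [obs.field_code]
        name = names[int(rng.integers(0, len(names)))]
        t = obs.collection_time
        w.writerow(
            [
                key_of[obs.record_id],
                format_mdy_date(obs.collection_date),
                "" if t is None else f"{t.hour:02d}:{t.minute:02d}",
                name,
                format_value(obs.value),
                _UNITS[obs.field_code],
            ]
        )
    return buf.getvalue()


def manifest_to_json(manifest: Sequence[PlantedCorruption]) -> str:
    return json.dumps(
        [
            {
                "record_id": m.record_id,
                "field_code": m.field_code,
                "collection_date": m.collection_date.isoformat(),
                "collection_time": (
                    None
                    if m.collection_time is None
                    else m.collection_time.strftime("%H:%M")
                ),
                "kind": m.kind,
                "original_value": m.original_value,
                "expected_reason": m.expected_reason,
            }
            for m in manifest
        ],
        indent=2,
    )


# ---------------------------------------------------------------------------
# Cell-level error injection (emulates manual typo/date errors)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellCorruption:
    row: int
    column: str
    original: str
    corrupted: str
    kind: str  # "digit" | "date" | "swap"

    @property
    def import_invalid(self) -> bool:
        """Whether a dictionary validation pass will flag the cell.
        Digit typos and value transpositions remain valid numbers —
        only comparison against an independent dataset can catch them."""
        return self.kind == "date"


def _digit_typo(rng: np.random.Generator, value: str) -> str:
    digits = [i for i, ch in enumerate(value) if ch.isdigit()]
    i = digits[int(rng.integers(0, len(digits)))]
    old = value[i]
    choices = [d for d in "0123456789" if d != old]
    new = choices[int(rng.integers(0, len(choices)))]
    return value[:i] + new + value[i + 1 :]


def _malform_date(rng: np.random.Generator) -> str:
    month = int(rng.integers(13, 20))
    day = int(rng.integers(32, 46))
    year = int(rng.integers(2016, 2021))
    return f"{month}/{day}/{year}"


def inject_errors(
    table: ImportTable,
    k: int,
    seed: int = 0,
    kinds: Sequence[str] = ("digit", "date", "swap"),
) -> tuple[ImportTable, list[CellCorruption]]:
    """Perturb exactly ``k`` cells of an import table, uniformly at
    random without replacement, returning the corrupted copy and a
    manifest of every change.

    Kinds: ``digit`` replaces one digit of a lab value (a manual typo —
    still a valid number), ``date`` malforms a collection date into an
    impossible M/D/Y string (caught by import validation), ``swap``
    replaces a lab value with a different row's value from the same
    column (a transposition error).  Restrict ``kinds`` to target one
    error class.  Raises ValueError when ``k`` exceeds the number of
    eligible cells.
    """
    bad = set(kinds) - {"digit", "date", "swap"}
    if bad:
        raise ValueError(f"unknown corruption kinds: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    lab_cols = [c for c in table.columns if c not in hz.IMPORT_FIXED_COLUMNS]

    value_kinds = [kd for kd in kinds if kd in ("digit", "swap")]
    cells: list[tuple[int, str]] = []
    if value_kinds:
        for col in lab_cols:
            for i in df.index[df[col] != ""]:
                cells.append((int(i), col))
    if "date" in kinds:
        for i in df.index:
            cells.append((int(i), hz.LAB_DATE_FIELD))
    if k > len(cells):
        raise ValueError(f"k={k} exceeds the {len(cells)} eligible cells")

    chosen = rng.choice(len(cells), size=k, replace=False) if k else []
    manifest: list[CellCorruption] = []
    for idx in chosen:
        row, col = cells[int(idx)]
        original = df.at[row, col]
        if col == hz.LAB_DATE_FIELD:
            kind = "date"
            corrupted = _malform_date(rng)
        else:
            kind = value_kinds[int(rng.integers(0, len(value_kinds)))]
            if kind == "swap":
                others = [
                    v for v in df[col][df[col] != ""].unique() if v != original
                ]
                if others:
                    corrupted = others[int(rng.integers(0, len(others)))]
                else:
                    kind = "digit"
                    corrupted = _digit_typo(rng, original)
            else:
                corrupted = _digit_typo(rng, original)
        df.at[row, col] = corrupted
        manifest.append(CellCorruption(row, col, original, corrupted, kind))
    return ImportTable(df), manifest
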