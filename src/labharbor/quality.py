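"""Data-quality assessment: manual-vs-automated agreement and
abstraction throughput.

The registry's quality check compares values captured by trained human
abstractors against the same values produced by the automated pipeline,
keyed on (record, lab, collection date/time).  Every key is compared —
no sampling — and every disagreement is itemized so it can be
adjudicated against the source EHR.  Throughput is simply values
abstracted per minute of measured abstraction time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from labharbor.harmonize import LabObservation

__all__ = [
    "Discrepancy",
    "AgreementReport",
    "ThroughputReport",
    "compare_datasets",
    "throughput_report",
]


@dataclass(frozen=True)
class Discrepancy:
    record_id: str
    field_code: str
    collection_date: _dt.date
    collection_time: _dt.time | None
    manual_value: float | None
    automated_value: float | None
    kind: str  # "value_mismatch" | "missing_in_manual" | "missing_in_automated"


@dataclass
class AgreementReport:
    n_compared: int
    n_agree: int
    discrepancies: list[Discrepancy] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.discrepancies) != self.n_compared - self.n_agree:
            raise ValueError("discrepancy count must equal n_compared - n_agree")

    @property
    def agreement_pct(self) -> float:
        """Percent of compared keys that agree (100.0 for an empty
        comparison)."""
        if self.n_compared == 0:
            return 100.0
        return 100.0 * self.n_agree / self.n_compared

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "record_id": d.record_id,
                    "field_code": d.field_code,
                    "collection_date": d.collection_date.isoformat(),
                    "collection_time": (
                        "" if d.collection_time is None else d.collection_time.strftime("%H:%M")
                    ),
                    "manual_value": d.manual_value,
                    "automated_value": d.automated_value,
                    "kind": d.kind,
                }
                for d in self.discrepancies
            ],
            columns=[
                "record_id",
                "field_code",
                "collection_date",
                "collection_time",
                "manual_value",
                "automated_value",
                "kind",
            ],
        )

    def summary(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_agree": self.n_agree,
            "agreement_pct": round(self.agreement_pct, 1),
            "n_discrepancies": len(self.discrepancies),
        }


def _key(obs: LabObservation) -> tuple:
    t = obs.collection_time
    return (
        obs.record_id,
        obs.field_code,
        obs.collection_date,
        None if t is None else (t.hour, t.minute),
    )


def compare_datasets(
    manual: Sequence[LabObservation],
    automated: Sequence[LabObservation],
    tolerance: float = 0.0,
) -> AgreementReport:
    """Compare two harmonized datasets value-by-value.

    Values are matched on (record_id, field_code, date, time) and
    compared numerically — "5.0" and "5.00" agree.  ``tolerance`` is
    relative (0 = exact).  Keys present in only one dataset count as
    discrepancies of kind ``missing_in_*``, and are included in the
    denominator: an absent value is a disagreement, not a free pass.
    """
    man = {_key(o): o for o in manual}
    aut = {_key(o): o for o in automated}
    keys = sorted(set(man) | set(aut), key=lambda k: (k[0], k[1], k[2], k[3] or (-1, -1)))

    n_agree = 0
    discrepancies: list[Discrepancy] = []
    for k in keys:
        m, a = man.get(k), aut.get(k)
        rid, code, date, tkey = k
        time = None if tkey is None else _dt.time(*tkey)
        if m is None:
            discrepancies.append(
                Discrepancy(rid, code, date, time, None, a.value, "missing_in_manual")
            )
            continue
        if a is None:
            discrepancies.append(
                Discrepancy(rid, code, date, time, m.value, None, "missing_in_automated")
            )
            continue
        diff = abs(m.value - a.value)
        limit = tolerance * max(abs(m.value), abs(a.value))
        if diff <= limit or diff == 0.0:
            n_agree += 1
        else:
            discrepancies.append(
                Discrepancy(rid, code, date, time, m.value, a.value, "value_mismatch")
            )
    return AgreementReport(
        n_compared=len(keys), n_agree=n_agree, discrepancies=discrepancies
    )


@dataclass(frozen=True)
class ThroughputReport:
    n_values: int
    total_minutes: float

    @property
    def values_per_minute(self) -> float:
        """Abstraction rate, rounded to 1 decimal as reported."""
        return round(self.n_values / self.total_minutes, 1)


def throughput_report(n_values: int, total_minutes: float) -> ThroughputReport:
    """Abstraction throughput from measured totals (e.g. REDCap
    start/stop timestamps).  ``total_minutes`` must be positive."""
    if total_minutes <= 0:
        raise ValueError("total_minutes must be positive")
    if n_values < 0:
        raise ValueError("n_values must be nonnegative")
    return ThroughputReport(n_values=n_values, total_minutes=total_minutes)
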