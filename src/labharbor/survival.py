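"""Baseline-labs overall-survival screen.

Given harmonized lab observations plus the registry's subject-status and
patient-characteristics instruments, this module

1. derives overall survival (OS): time in whole days from the date of
   diagnosis to death, censored at the last follow-up visit when no
   death occurred;
2. selects, per subject and per lab, a single *baseline* value — the
   draw nearest the diagnosis date within a configurable window
   (default 90 days before to 30 days after); and
3. fits one univariable Cox proportional-hazards model per lab and
   renders the results as a hazard-ratio table grouped by lab panel.

The Cox partial likelihood is maximized by Newton iteration with the
Efron correction for tied event times; the hazard ratio is exp(b̂), the
95% CI is exp(b̂ ± 1.96·SE) with SE from the observed information, and
the p-value is a two-sided Wald test.  Labs are modeled untransformed,
per unit, and — the screen being exploratory — no multiplicity
correction is applied by default.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from labharbor.dictionary import LAB_PANELS, LAB_TYPES, format_mdy_date
from labharbor.errors import DataError, DegenerateFitError
from labharbor.harmonize import LabObservation
from labharbor.ingest import parse_any_date

__all__ = [
    "SubjectStatus",
    "PatientCharacteristics",
    "SurvivalRecord",
    "CoxResult",
    "derive_os",
    "baseline_labs",
    "fit_univariable_cox",
    "cox_newton",
    "baselabs_os_table",
    "results_to_csv",
    "render_table",
    "read_status_csv",
    "read_characteristics_csv",
    "write_status_csv",
    "write_characteristics_csv",
]

logger = logging.getLogger(__name__)

PANEL_LABELS = {
    "electrolytes_renal_glucose": "Electrolytes/renal/glucose",
    "general_chemistries": "General chemistries",
    "liver_function": "Liver function tests",
    "hematological": "Hematological studies",
}

_LABELS = {t.code: t.label for t in LAB_TYPES}


@dataclass(frozen=True)
class SubjectStatus:
    record_id: str
    last_followup_date: _dt.date
    death_date: _dt.date | None = None


@dataclass(frozen=True)
class PatientCharacteristics:
    record_id: str
    diagnosis_date: _dt.date | None


@dataclass(frozen=True)
class SurvivalRecord:
    record_id: str
    time_days: int
    event: bool

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("survival time must be nonnegative")


@dataclass(frozen=True)
class CoxResult:
    """One row of the univariable screen."""

    field_code: str
    n_used: int
    n_events: int
    coef: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    panel: str = ""
    flag: str | None = None  # e.g. "monotone_likelihood", "not_converged"


# ---------------------------------------------------------------------------
# Overall survival
# ---------------------------------------------------------------------------


def derive_os(
    status: Sequence[SubjectStatus],
    chars: Sequence[PatientCharacteristics],
) -> list[SurvivalRecord]:
    """Derive per-subject OS from the two registry instruments.

    Event subjects contribute death − diagnosis; censored subjects
    contribute last-follow-up − diagnosis, in whole days.  Subjects with
    no diagnosis date are excluded with a logged reason; a death before
    diagnosis is a data error naming the record.
    """
    dx_by_id = {c.record_id: c.diagnosis_date for c in chars}
    out: list[SurvivalRecord] = []
    for s in status:
        if s.record_id not in dx_by_id:
            logger.warning(
                "record %s: no patient-characteristics row; excluded from OS",
                s.record_id,
            )
            continue
        dx = dx_by_id[s.record_id]
        if dx is None:
            logger.warning(
                "record %s: missing diagnosis date; excluded from OS", s.record_id
            )
            continue
        if s.death_date is not None:
            if s.death_date < dx:
                raise DataError(
                    f"record {s.record_id}: death date precedes diagnosis date"
                )
            time = (s.death_date - dx).days
            event = True
        else:
            if s.last_followup_date < dx:
                raise DataError(
                    f"record {s.record_id}: last follow-up precedes diagnosis date"
                )
            time = (s.last_followup_date - dx).days
            event = False
        out.append(SurvivalRecord(s.record_id, time, event))
    return out


# ---------------------------------------------------------------------------
# Baseline lab selection
# ---------------------------------------------------------------------------


def baseline_labs(
    observations: Sequence[LabObservation],
    chars: Sequence[PatientCharacteristics],
    window: tuple[int, int] = (-90, 30),
) -> dict[tuple[str, str], float]:
    """Pick one baseline value per (subject, lab).

    Eligible draws fall within ``window`` days of the diagnosis date
    (negative = before).  Among eligible draws the one nearest the
    diagnosis wins; a tie in distance goes to the earlier draw, then to
    the earlier clock time.  Subjects with no eligible draw for a lab
    are simply absent from the map (complete-case per lab).
    """
    lo, hi = window
    dx_by_id = {c.record_id: c.diagnosis_date for c in chars}
    best: dict[tuple[str, str], tuple[tuple, float]] = {}
    for obs in observations:
        dx = dx_by_id.get(obs.record_id)
        if dx is None:
            continue
        delta = (obs.collection_date - dx).days
        if not (lo <= delta <= hi):
            continue
        t = obs.collection_time
        tkey = (0, 0) if t is None else (t.hour, t.minute)
        key = (obs.record_id, obs.field_code)
        rankkey = (abs(delta), delta, tkey, obs.source_row)
        if key not in best or rankkey < best[key][0]:
            best[key] = (rankkey, obs.value)
    return {key: value for key, (_, value) in best.items()}


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties), Newton maximization
# ---------------------------------------------------------------------------


def _efron_quantities(
    beta: float,
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and observed information for a
    single covariate under the Efron tie correction."""
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order], x[order]
    eta = beta * xv
    # guard against overflow in exp for extreme beta during line search
    w = np.exp(np.clip(eta, -700, 700))
    wx = w * xv
    wxx = w * xv * xv
    # suffix (risk-set) sums: subjects with time >= t_j
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1])[::-1]
    s2 = np.cumsum(wxx[::-1])[::-1]

    loglik = 0.0
    grad = 0.0
    info = 0.0
    n = len(t)
    j = 0
    while j < n:
        k = j
        while k < n and t[k] == t[j]:
            k += 1
        d_idx = [i for i in range(j, k) if e[i]]
        d = len(d_idx)
        if d:
            sum_eta = float(eta[d_idx].sum())
            sum_x = float(xv[d_idx].sum())
            w_d = float(w[d_idx].sum())
            wx_d = float(wx[d_idx].sum())
            wxx_d = float(wxx[d_idx].sum())
            r0, r1, r2 = float(s0[j]), float(s1[j]), float(s2[j])
            loglik += sum_eta
            for l in range(d):
                f = l / d
                phi0 = r0 - f * w_d
                phi1 = r1 - f * wx_d
                phi2 = r2 - f * wxx_d
                loglik -= np.log(phi0)
                grad_term = phi1 / phi0
                grad += -grad_term
                info += phi2 / phi0 - grad_term**2
            grad += sum_x
        j = k
    return loglik, grad, info


def cox_newton(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
    beta_cap: float = 20.0,
) -> tuple[float, float, bool, str | None]:
    """Maximize the single-covariate Cox partial likelihood.

    Returns ``(beta, se, converged, flag)``.  The covariate is centered
    internally (the estimate is location invariant) for numerical
    stability.  Monotone likelihoods — perfect separation of event
    order by the covariate — drive |beta| past ``beta_cap`` and are
    flagged rather than returned as if trustworthy.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("covariate is constant; hazard ratio undefined")
    if int(event.sum()) < 1:
        raise DegenerateFitError("no events; partial likelihood is flat")
    xc = x - x.mean()

    beta = 0.0
    loglik, grad, info = _efron_quantities(beta, time, event, xc)
    flag: str | None = None
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            flag = "singular_information"
            break
        step = grad / info
        # step-halving line search: partial likelihood is concave but
        # huge first steps can overshoot into overflow territory
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_quantities(new_beta, time, event, xc)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_quantities(new_beta, time, event, xc)
            halvings += 1
        delta = abs(new_beta - beta)
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > beta_cap:
            flag = "monotone_likelihood"
            break
        if delta < tol:
            converged = True
            break
    else:
        flag = "not_converged"
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    return float(beta), se, converged, flag


def fit_univariable_cox(
    values: Mapping[str, float],
    surv: Sequence[SurvivalRecord],
    field_code: str = "x",
) -> CoxResult:
    """Fit one univariable Cox model of a lab against OS.

    ``values`` maps record_id to the subject's baseline covariate value;
    only subjects present in both inputs are used (complete case).
    Raises :class:`DegenerateFitError` when the covariate is constant or
    there are no usable events; a non-converged or monotone fit is
    returned flagged, never silently.
    """
    used = [(s, values[s.record_id]) for s in surv if s.record_id in values]
    if len(used) < 2:
        raise DegenerateFitError(
            f"{field_code}: fewer than 2 subjects with covariate and survival data"
        )
    time = np.array([s.time_days for s, _ in used], dtype=float)
    event = np.array([s.event for s, _ in used], dtype=bool)
    x = np.array([v for _, v in used], dtype=float)

    beta, se, converged, flag = cox_newton(time, event, x)
    z = beta / se if se > 0 and np.isfinite(se) else float("nan")
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    return CoxResult(
        field_code=field_code,
        n_used=len(used),
        n_events=int(event.sum()),
        coef=beta,
        se=se,
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=p,
        flag=flag if not converged or flag else None,
    )


# ---------------------------------------------------------------------------
# The full screen
# ---------------------------------------------------------------------------


def baselabs_os_table(
    observations: Sequence[LabObservation],
    status: Sequence[SubjectStatus],
    chars: Sequence[PatientCharacteristics],
    window: tuple[int, int] = (-90, 30),
    min_subjects: int = 10,
) -> list[CoxResult]:
    """Run the univariable screen for every lab with enough data.

    One result per lab field, grouped and ordered by panel
    (electrolytes/renal/glucose first, sodium first within it).  Labs
    with fewer than ``min_subjects`` usable subjects, fewer than 2
    events, or a constant covariate are skipped.  Raw p-values only —
    the screen is hypothesis-generating.
    """
    surv = derive_os(status, chars)
    if not any(s.event for s in surv):
        warnings.warn("cohort has zero death events; survival screen is empty")
        return []
    baseline = baseline_labs(observations, chars, window=window)

    results: list[CoxResult] = []
    for panel, codes in LAB_PANELS.items():
        for code in codes:
            values = {
                rid: v for (rid, fc), v in baseline.items() if fc == code
            }
            usable = [s for s in surv if s.record_id in values]
            if len(usable) < min_subjects:
                continue
            if sum(s.event for s in usable) < 2:
                continue
            try:
                res = fit_univariable_cox(values, surv, field_code=code)
            except DegenerateFitError:
                continue
            results.append(
                CoxResult(**{**res.__dict__, "panel": panel})
            )
    return results


def results_to_csv(results: Sequence[CoxResult]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(
        [
            "panel",
            "field_code",
            "n_used",
            "n_events",
            "hazard_ratio",
            "ci_low",
            "ci_high",
            "p_value",
            "flag",
        ]
    )
    for r in results:
        w.writerow(
            [
                r.panel,
                r.field_code,
                r.n_used,
                r.n_events,
                f"{r.hazard_ratio:.4f}",
                f"{r.ci_low:.4g}",
                f"{r.ci_high:.4g}",
                f"{r.p_value:.4g}",
                r.flag or "",
            ]
        )
    return buf.getvalue()


def render_table(results: Sequence[CoxResult]) -> str:
    """Plain-text hazard-ratio table in registry presentation order."""
    lines = [
        f"{'Laboratory test':<48}{'Hazard ratio (95% CI)':<28}{'P value':>8}",
        "-" * 84,
    ]
    for panel in LAB_PANELS:
        rows = [r for r in results if r.panel == panel]
        if not rows:
            continue
        lines.append(PANEL_LABELS[panel])
        for r in rows:
            label = f"{_LABELS.get(r.field_code, r.field_code)} ({r.field_code})"
            hr = f"{r.hazard_ratio:.4f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
            flag = f"  [{r.flag}]" if r.flag else ""
            lines.append(f"  {label:<46}{hr:<28}{r.p_value:>8.3g}{flag}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Instrument CSV readers
# ---------------------------------------------------------------------------


def read_status_csv(stream: str | io.TextIOBase) -> list[SubjectStatus]:
    """Read the subject-status instrument (record_id,
    last_followup_date, death_date; dates M/D/Y or ISO, death may be
    blank)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for row in csv.DictReader(stream):
        death = row.get("death_date", "").strip()
        out.append(
            SubjectStatus(
                record_id=row["record_id"],
                last_followup_date=parse_any_date(row["last_followup_date"]),
                death_date=parse_any_date(death) if death else None,
            )
        )
    return out


def read_characteristics_csv(stream: str | io.TextIOBase) -> list[PatientCharacteristics]:
    """Read the patient-characteristics instrument (record_id,
    diagnosis_date; a blank diagnosis date is kept and excluded later
    with a logged reason)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for row in csv.DictReader(stream):
        dx = row.get("diagnosis_date", "").strip()
        out.append(
            PatientCharacteristics(
                record_id=row["record_id"],
                diagnosis_date=parse_any_date(dx) if dx else None,
            )
        )
    return out


def write_status_csv(status: Sequence[SubjectStatus]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["record_id", "last_followup_date", "death_date"])
    for s in status:
        w.writerow(
            [
                s.record_id,
                format_mdy_date(s.last_followup_date),
                format_mdy_date(s.death_date) if s.death_date else "",
            ]
        )
    return buf.getvalue()


def write_characteristics_csv(chars: Sequence[PatientCharacteristics]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["record_id", "diagnosis_date"])
    for c in chars:
        w.writerow(
            [c.record_id, format_mdy_date(c.diagnosis_date) if c.diagnosis_date else ""]
        )
    return buf.getvalue()
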