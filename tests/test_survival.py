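"""Overall-survival derivation, baseline selection, and the Cox fit —
checked against a brute-force partial-likelihood oracle and an
independent survival library."""

import datetime as dt

import numpy as np
import pytest

from labharbor import survival as sv
from labharbor import synthetic as syn
from labharbor.errors import DataError, DegenerateFitError
from labharbor.harmonize import LabObservation

D = dt.date


# ---------------------------------------------------------------------------
# Independent oracle: maximize the (no-ties) Cox partial likelihood on a
# grid.  Written against the textbook definition, not the package code.
# ---------------------------------------------------------------------------


def partial_loglik(beta, time, event, x):
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def grid_maximizer(time, event, x, lo=-5.0, hi=5.0):
    """Two-stage exhaustive grid search (coarse 1e-3, then 1e-6 around
    the coarse optimum).  The partial likelihood is concave in beta, so
    refining around the coarse argmax loses nothing."""
    grid = np.arange(lo, hi, 1e-3)
    vals = [partial_loglik(b, time, event, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-6)
    vals = [partial_loglik(b, time, event, x) for b in fine]
    return float(fine[int(np.argmax(vals))])


def tiny_dataset(rng, n):
    """A no-ties survival dataset with n <= 8 subjects."""
    time = rng.permutation(np.arange(1, n + 1)).astype(float)
    event = rng.random(n) < 0.8
    if not event.any():
        event[0] = True
    x = rng.normal(size=n)
    return time, event, x


class TestCoxAgainstGridOracle:
    def test_spec_case_alternating_binary_covariate(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([True] * 4)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        beta, se, converged, flag = sv.cox_newton(time, event, x)
        assert converged and flag is None
        assert beta == pytest.approx(grid_maximizer(time, event, x), abs=1e-5)

    @pytest.mark.parametrize("seed", range(12))
    def test_newton_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        time, event, x = tiny_dataset(rng, int(rng.integers(4, 9)))
        if np.ptp(x[event]) == 0:
            x[np.argmax(event)] += 1.0
        beta, _, converged, _ = sv.cox_newton(time, event, x)
        oracle = grid_maximizer(time, event, x)
        if abs(oracle) > 4.9:
            return  # maximizer outside the oracle's search box; not comparable
        assert beta == pytest.approx(oracle, abs=1e-5)


class TestCoxProperties:
    def fit(self, time, event, x):
        return sv.cox_newton(np.asarray(time, float), np.asarray(event, bool),
                             np.asarray(x, float))

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        days, ev = syn.simulate_survival_days(rng, 0.5 * x, 1 / 365, 0.2)
        b1, se1, _, _ = self.fit(days, ev, x)
        b2, se2, _, _ = self.fit(days, ev, x + 17.3)
        assert b1 == pytest.approx(b2, abs=1e-8)
        assert se1 == pytest.approx(se2, abs=1e-8)

    def test_constant_covariate_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            self.fit([1, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])

    def test_monotone_likelihood_is_flagged_not_silent(self):
        # covariate perfectly ordered with event times: beta diverges
        time = np.arange(1.0, 9.0)
        event = np.ones(8, dtype=bool)
        x = np.arange(8.0)
        beta, _, converged, flag = sv.cox_newton(time, event, x)
        assert flag == "monotone_likelihood" and not converged

    def test_agrees_with_independent_library(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(size=60)
            days, ev = syn.simulate_survival_days(rng, 0.4 * x, 1 / 365, 0.3)
            beta, _, _, _ = self.fit(days, ev, x)
            y = np.array(list(zip(ev, days.astype(float))),
                         dtype=[("e", bool), ("t", float)])
            ref = CoxPHSurvivalAnalysis(ties="efron", tol=1e-12, n_iter=200)
            ref.fit(x.reshape(-1, 1), y)
            assert beta == pytest.approx(float(ref.coef_[0]), abs=1e-6)


class TestDeriveOs:
    def test_death_yields_event_with_day_count(self):
        surv = sv.derive_os(
            [sv.SubjectStatus("0001", D(2020, 12, 31), death_date=D(2020, 12, 31))],
            [sv.PatientCharacteristics("0001", D(2020, 1, 1))],
        )
        assert surv == [sv.SurvivalRecord("0001", 365, True)]

    def test_alive_subject_is_censored_at_last_followup(self):
        surv = sv.derive_os(
            [sv.SubjectStatus("0001", D(2021, 6, 30))],
            [sv.PatientCharacteristics("0001", D(2020, 1, 1))],
        )
        assert surv == [sv.SurvivalRecord("0001", 546, False)]

    def test_death_before_diagnosis_names_the_record(self):
        with pytest.raises(DataError, match="0001"):
            sv.derive_os(
                [sv.SubjectStatus("0001", D(2019, 1, 1), death_date=D(2019, 1, 1))],
                [sv.PatientCharacteristics("0001", D(2020, 1, 1))],
            )

    def test_missing_diagnosis_date_excludes_with_log(self, caplog):
        surv = sv.derive_os(
            [sv.SubjectStatus("0001", D(2021, 1, 1))],
            [sv.PatientCharacteristics("0001", None)],
        )
        assert surv == []

    def test_extending_censored_followup_never_adds_events(self):
        chars = [sv.PatientCharacteristics("0001", D(2020, 1, 1))]
        early = sv.derive_os([sv.SubjectStatus("0001", D(2020, 6, 1))], chars)
        late = sv.derive_os([sv.SubjectStatus("0001", D(2022, 6, 1))], chars)
        assert sum(s.event for s in early) == sum(s.event for s in late) == 0
        assert late[0].time_days > early[0].time_days


def obs(code="cre", value=1.0, date=D(2020, 1, 1), time=None, rid="0001", row=1):
    return LabObservation(rid, code, value, "mg/dL", date, time, source_row=row)


class TestBaselineLabs:
    CHARS = [sv.PatientCharacteristics("0001", D(2020, 3, 1))]

    def test_nearest_draw_wins(self):
        picked = sv.baseline_labs(
            [obs(value=1.0, date=D(2020, 2, 20), row=1),   # dx - 10
             obs(value=2.0, date=D(2020, 3, 21), row=2)],  # dx + 20
            self.CHARS,
        )
        assert picked[("0001", "cre")] == 1.0

    def test_distance_tie_goes_to_earlier_draw(self):
        picked = sv.baseline_labs(
            [obs(value=2.0, date=D(2020, 3, 6), row=1),    # dx + 5
             obs(value=1.0, date=D(2020, 2, 25), row=2)],  # dx - 5
            self.CHARS,
        )
        assert picked[("0001", "cre")] == 1.0

    def test_out_of_window_subject_is_absent(self):
        picked = sv.baseline_labs(
            [obs(date=D(2020, 9, 17))], self.CHARS  # dx + 200
        )
        assert picked == {}

    def test_window_is_configurable(self):
        picked = sv.baseline_labs(
            [obs(date=D(2020, 9, 17))], self.CHARS, window=(-90, 250)
        )
        assert ("0001", "cre") in picked


class TestBaselabsOsTable:
    def test_results_ordered_by_panel_sodium_first(self, small_truth):
        results = sv.baselabs_os_table(
            small_truth.observations, small_truth.status, small_truth.chars
        )
        assert results[0].field_code == "na"
        assert results[0].panel == "electrolytes_renal_glucose"
        panels = [r.panel for r in results]
        # grouped: each panel appears as one contiguous block
        seen, order = set(), []
        for p in panels:
            if p not in seen:
                seen.add(p)
                order.append(p)
        assert order == [p for p in sv.LAB_PANELS if p in seen]

    def test_zero_events_warns_and_returns_empty(self, small_truth):
        status = [
            sv.SubjectStatus(s.record_id, s.last_followup_date, None)
            for s in small_truth.status
        ]
        with pytest.warns(UserWarning, match="zero death events"):
            results = sv.baselabs_os_table(
                small_truth.observations, status, small_truth.chars
            )
        assert results == []

    def test_ci_always_brackets_the_hazard_ratio(self, small_truth):
        results = sv.baselabs_os_table(
            small_truth.observations, small_truth.status, small_truth.chars
        )
        assert results
        for r in results:
            assert r.ci_low <= r.hazard_ratio <= r.ci_high
            assert 0 <= r.p_value <= 1

    def test_render_mentions_every_fitted_lab(self, small_truth):
        results = sv.baselabs_os_table(
            small_truth.observations, small_truth.status, small_truth.chars
        )
        text = sv.render_table(results)
        for r in results:
            assert f"({r.field_code})" in text


class TestInstrumentCsv:
    def test_status_round_trip(self, small_truth):
        text = sv.write_status_csv(small_truth.status)
        assert sv.read_status_csv(text) == small_truth.status

    def test_characteristics_round_trip(self, small_truth):
        text = sv.write_characteristics_csv(small_truth.chars)
        assert sv.read_characteristics_csv(text) == small_truth.chars
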