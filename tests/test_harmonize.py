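"""Harmonization core: remapping, cleaning, de-identification, repeat
instances, the REDCap import layout, aggregation and LOINC annotation."""

import datetime as dt

import pytest

from labharbor import harmonize as hz
from labharbor import synthetic as syn
from labharbor.errors import (
    DeidentificationError,
    IntegrityError,
    SchemaError,
)
from labharbor.ingest import RawObservation

from conftest import pipeline_from_untidy

D = dt.date
T = dt.time

POTASSIUM_SUBTYPES = [
    "Potassium",
    "Potassium-External",
    "Potassium(POC)",
    "Potassium, whole-bld",
    "Potassium-Level-External",
    "Potassium, venous",
    "Potassium-whole-bld/plasma",
]


def raw(name="Potassium", value="4.0", unit="mmol/L", key="MRN1", row=2,
        date=D(2020, 5, 1), time=T(8, 0)):
    return RawObservation(
        patient_key=key,
        collection_date=date,
        collection_time=time,
        source_test_name=name,
        raw_value=value,
        raw_unit=unit,
        source_row=row,
    )


class TestRemapTests:
    @pytest.mark.parametrize("subtype", POTASSIUM_SUBTYPES)
    def test_every_potassium_subtype_maps_to_k(self, lut, subtype):
        mapped, report = hz.remap_tests([raw(name=subtype)], lut)
        assert len(report) == 0
        assert mapped[0].field_code == "k"

    def test_matching_is_case_insensitive(self, lut):
        mapped, _ = hz.remap_tests([raw(name="POTASSIUM")], lut)
        assert mapped[0].field_code == "k"

    def test_whitespace_is_collapsed_before_matching(self, lut):
        mapped, _ = hz.remap_tests([raw(name="  Potassium,   whole-bld ")], lut)
        assert mapped[0].field_code == "k"

    def test_unknown_test_is_itemized_never_guessed(self, lut):
        mapped, report = hz.remap_tests([raw(name="Zinc-RBC")], lut)
        assert mapped == []
        assert report.counts == {"unmapped_test": 1}


class TestNormalizeValues:
    def run_one(self, lut, dd, **kw):
        mapped, _ = hz.remap_tests([raw(**kw)], lut)
        return hz.normalize_values(mapped, dd)

    @pytest.mark.parametrize("token", ["refused", "canceled", "REFUSED", "<0.01", "n/a"])
    def test_nonimportable_tokens_are_excluded(self, lut, dd, token):
        clean, report = self.run_one(lut, dd, value=token)
        assert clean == [] and report.counts == {"nonimportable_value": 1}

    def test_unit_outside_dictionary_is_excluded(self, lut, dd):
        clean, report = self.run_one(lut, dd, unit="mg/dL")
        assert clean == [] and report.counts == {"unit_mismatch": 1}

    def test_missing_unit_is_excluded_by_default(self, lut, dd):
        clean, report = self.run_one(lut, dd, unit="")
        assert report.counts == {"unit_mismatch": 1}

    def test_clean_value_survives_with_registry_unit(self, lut, dd):
        clean, report = self.run_one(lut, dd, value="4.0", unit="mmol/L")
        assert len(report) == 0
        assert clean[0].value == 4.0 and clean[0].unit == "mmol/L"

    def test_unit_comparison_ignores_case(self, lut, dd):
        clean, _ = self.run_one(lut, dd, unit="MMOL/L")
        assert len(clean) == 1

    def test_scale_factor_converts_explicitly(self, dd):
        lut = hz.LookupTable(
            {"Potassium mEq": hz.LookupEntry("k", frozenset({"meq/l"}), 1.0),
             "Calcium mmol": hz.LookupEntry("ca", frozenset({"mmol/l"}), 4.008)}
        )
        mapped, _ = hz.remap_tests([raw(name="Calcium mmol", value="2.5", unit="mmol/L")], lut)
        clean, _ = hz.normalize_values(mapped, dd)
        assert clean[0].value == pytest.approx(10.02)


class TestDeidentify:
    XW = hz.Crosswalk({"MRN1": "0001", "MRN2": "0002"})

    def clean(self, key="MRN1", row=2):
        return hz.CleanObservation(key, "k", 4.0, "mmol/L", D(2020, 5, 1), T(8, 0), row)

    def test_known_key_gets_its_record_id(self):
        out, report = hz.deidentify([self.clean()], self.XW)
        assert out[0].record_id == "0001" and len(report) == 0

    def test_same_key_always_same_record(self):
        out, _ = hz.deidentify([self.clean(), self.clean(row=3)], self.XW)
        assert out[0].record_id == out[1].record_id

    def test_strict_unknown_key_raises_without_leaking_the_key(self):
        with pytest.raises(DeidentificationError) as err:
            hz.deidentify([self.clean(key="MRN999", row=7)], self.XW)
        assert "MRN999" not in str(err.value)
        assert "row 7" in str(err.value)

    def test_lenient_unknown_key_is_itemized(self):
        out, report = hz.deidentify([self.clean(key="MRN999")], self.XW, strict=False)
        assert out == [] and report.counts == {"unknown_patient": 1}

    def test_crosswalk_must_be_injective(self):
        with pytest.raises(IntegrityError):
            hz.Crosswalk({"MRN1": "0001", "MRN2": "0001"})


def lab(rid="0001", code="k", value=4.0, date=D(2020, 5, 1), time=T(8, 0), row=2):
    return hz.LabObservation(rid, code, value, "mmol/L", date, time, source_row=row)


class TestAssignInstances:
    def test_two_same_day_draws_get_consecutive_instances(self):
        out = hz.assign_instances(
            [lab(time=T(8, 0), row=2), lab(time=T(14, 0), row=3)]
        )
        assert [o.instance for o in out] == [1, 2]

    def test_single_draw_is_instance_one(self):
        assert hz.assign_instances([lab()])[0].instance == 1

    def test_labs_sharing_an_event_share_an_instance(self):
        out = hz.assign_instances([lab(code="k", row=2), lab(code="na", row=2)])
        assert out[0].instance == out[1].instance == 1

    def test_input_order_does_not_change_assignment(self):
        a = [lab(time=T(8, 0), row=2), lab(time=T(14, 0), row=3), lab(code="na", row=2)]
        fwd = {(o.field_code, o.collection_time): o.instance
               for o in hz.assign_instances(a)}
        rev = {(o.field_code, o.collection_time): o.instance
               for o in hz.assign_instances(a[::-1])}
        assert fwd == rev

    def test_untimed_draw_sorts_before_timed_same_day(self):
        out = hz.assign_instances([lab(time=T(0, 0), row=3), lab(time=None, row=2)])
        by_time = {o.collection_time: o.instance for o in out}
        assert by_time[None] == 1 and by_time[T(0, 0)] == 2

    def test_duplicate_field_at_one_event_opens_new_instance(self):
        out = hz.assign_instances(
            [lab(value=4.0, row=2), lab(value=4.4, row=3)]  # same field/date/time
        )
        assert sorted(o.instance for o in out) == [1, 2]
        # the later source row gets the later instance
        later = max(out, key=lambda o: o.source_row)
        assert later.instance == 2


class TestToRedcapLong:
    def test_one_event_fills_one_row(self, dd):
        obs = hz.assign_instances([lab(code="k", value=4.0), lab(code="na", value=140.0)])
        tbl = hz.to_redcap_long(obs, dd)
        assert tbl.n_rows == 1
        row = tbl.df.iloc[0]
        assert row["k"] == "4" and row["na"] == "140"
        assert row["redcap_repeat_instrument"] == "labs"
        assert row["lab_date"] == "05/01/2020" and row["lab_time"] == "08:00"

    def test_column_header_is_fixed_plus_35_lab_fields(self, dd):
        tbl = hz.to_redcap_long([], dd)
        assert tbl.columns[:5] == [
            "record_id",
            "redcap_repeat_instrument",
            "redcap_repeat_instance",
            "lab_date",
            "lab_time",
        ]
        assert len(tbl.columns) == 5 + 35

    def test_empty_observations_yield_header_only_table(self, dd):
        tbl = hz.to_redcap_long([], dd)
        assert tbl.n_rows == 0 and tbl.to_csv().count("\n") == 1

    def test_unassigned_instances_are_refused(self, dd):
        with pytest.raises(IntegrityError):
            hz.to_redcap_long([lab()], dd)

    def test_conflicting_values_at_same_slot_are_an_error(self, dd):
        a = hz.LabObservation("0001", "k", 4.0, "mmol/L", D(2020, 5, 1), T(8, 0),
                              instance=1, source_row=2)
        b = hz.LabObservation("0001", "k", 4.4, "mmol/L", D(2020, 5, 1), T(8, 0),
                              instance=1, source_row=2)
        with pytest.raises(IntegrityError):
            hz.to_redcap_long([a, b], dd)


class TestValidateImport:
    def test_malformed_date_is_flagged_at_its_cell(self, dd, small_truth):
        tbl = small_truth.import_table(dd)
        df = tbl.df.copy()
        df.at[0, "lab_date"] = "2020-14-01"
        report = hz.validate_import(hz.ImportTable(df), dd)
        assert len(report) == 1
        err = report.errors[0]
        assert (err.row, err.column) == (0, "lab_date")

    def test_clean_pipeline_output_validates(self, dd, small_truth):
        assert hz.validate_import(small_truth.import_table(dd), dd).empty

    def test_nonempty_report_blocks_export_without_force(self, dd, small_truth, tmp_path):
        tbl = small_truth.import_table(dd)
        df = tbl.df.copy()
        df.at[0, "k"] = "refused"
        bad = hz.ImportTable(df)
        target = tmp_path / "import.csv"
        with pytest.raises(IntegrityError):
            hz.export_import_csv(bad, dd, target)
        assert not target.exists()
        hz.export_import_csv(bad, dd, target, force=True)
        assert target.exists()


class TestAggregateSites:
    def site(self, dd, prefix, n, seed):
        cfg = syn.SimulationConfig(
            n_subjects=n, seed=seed, site_prefix=prefix,
            corruption=syn.CorruptionRates(0, 0, 0, 0),
        )
        return syn.simulate_cohort(cfg).import_table(dd)

    def test_row_counts_are_conserved(self, dd):
        a = self.site(dd, "A", 4, 1)
        b = self.site(dd, "B", 5, 2)
        combined = hz.aggregate_sites([a, b])
        assert combined.n_rows == a.n_rows + b.n_rows

    def test_colliding_record_ids_are_an_error(self, dd):
        a = self.site(dd, "", 3, 1)
        b = self.site(dd, "", 3, 2)  # same un-prefixed ids
        with pytest.raises(IntegrityError, match="record_id"):
            hz.aggregate_sites([a, b])

    def test_single_table_aggregates_to_itself(self, dd):
        a = self.site(dd, "A", 3, 1)
        assert hz.aggregate_sites([a]).equals(a)

    def test_header_mismatch_names_the_divergent_column(self, dd):
        a = self.site(dd, "A", 3, 1)
        b = self.site(dd, "B", 3, 2)
        df = b.df.rename(columns={"k": "potassium"})
        with pytest.raises(SchemaError, match="k|potassium"):
            hz.aggregate_sites([a, hz.ImportTable(df)])


class TestAnnotateLoinc:
    def test_default_map_covers_every_lab_field_once(self, dd):
        tbl = hz.annotate_loinc(dd)
        assert len(tbl) == 35
        assert tbl["field_code"].is_unique
        assert (tbl["loinc_code"] != "").all()

    def test_duplicate_assignment_is_an_error(self, dd):
        with pytest.raises(IntegrityError):
            hz.annotate_loinc(dd, [("k", "2823-3"), ("k", "6298-4")])

    def test_unknown_field_is_a_schema_error(self, dd):
        with pytest.raises(SchemaError):
            hz.annotate_loinc(dd, {"nlr": "1988-5"})

    def test_empty_map_yields_empty_table(self, dd):
        assert len(hz.annotate_loinc(dd, {})) == 0


class TestLookupTableCsv:
    def test_round_trip_preserves_entries(self, lut):
        again = hz.LookupTable.from_csv(lut.to_csv())
        assert len(again) == len(lut)
        assert again.get("Potassium, venous") == lut.get("Potassium, venous")

    def test_validates_against_dictionary(self, dd, lut):
        lut.validate_against(dd)  # packaged table must be coherent
        bad = hz.LookupTable({"Foo": hz.LookupEntry("nope", frozenset({"x"}))})
        with pytest.raises(SchemaError):
            bad.validate_against(dd)


class TestPipelineProperties:
    def test_record_conservation_end_to_end(self, dd, lut, small_truth):
        rates = syn.CorruptionRates(0.03, 0.02, 0.03, 0)
        text, manifest = syn.render_untidy(small_truth, lut, rates=rates, seed=5)
        result, rejects = pipeline_from_untidy(text, lut, small_truth.crosswalk, dd)
        assert rejects == []
        assert result.conserved
        assert len(result.exclusions) == len(manifest)

    def test_harmonizing_harmonized_output_is_a_noop(self, dd, small_truth):
        tbl = small_truth.import_table(dd)
        again = hz.to_redcap_long(
            hz.assign_instances(tbl.to_observations(dd)), dd
        )
        assert again.equals(tbl)

    def test_import_table_csv_round_trip(self, dd, small_truth):
        tbl = small_truth.import_table(dd)
        assert hz.ImportTable.from_csv(tbl.to_csv()).equals(tbl)
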