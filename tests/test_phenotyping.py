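"""Unit and property tests of the EMR phenotyping rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import labs_frame, scripts
from statintol.config import RulesConfig, ValidationError
from statintol.phenotyping import (
    classify_patient,
    compute_coverage,
    count_switches,
    detect_discontinuations,
    dose_equivalent,
    flag_ck,
)


@pytest.mark.parametrize(
    "drug,dose,expected",
    [
        ("simvastatin", 40, 40.0),
        ("atorvastatin", 20, 40.0),
        ("rosuvastatin", 10, 40.0),
        ("pravastatin", 80, 40.0),
        ("pitavastatin", 4, 40.0),
    ],
)
def test_dose_equivalent_potency_ladder(rules, drug, dose, expected):
    assert dose_equivalent(drug, dose, rules) == pytest.approx(expected)


def test_dose_equivalent_unknown_drug_named(rules):
    with pytest.raises(ValidationError, match="cerivastatin"):
        dose_equivalent("cerivastatin", 10, rules)


class TestCoverage:
    def test_single_script_fraction(self):
        rx = scripts([("p", "simvastatin", 40, "2000-01-01", 90)])
        frac, years = compute_coverage(rx, ("2000-01-01", "2000-04-10"))
        assert frac == pytest.approx(0.90)

    def test_overlapping_scripts_not_double_counted(self):
        rx = scripts(
            [
                ("p", "simvastatin", 40, "2000-01-01", 30),
                ("p", "simvastatin", 40, "2000-01-01", 30),
            ]
        )
        frac, _ = compute_coverage(rx, ("2000-01-01", "2000-03-01"))
        assert frac == pytest.approx(30 / 60)

    def test_tiling_scripts_full_coverage(self):
        rx = scripts(
            [("p", "simvastatin", 40, f"2000-0{m}-01", 40) for m in (1, 2, 3)]
        )
        frac, _ = compute_coverage(rx, ("2000-01-01", "2000-03-01"))
        assert frac == pytest.approx(1.0)

    def test_empty_prescriptions_is_zero(self):
        frac, years = compute_coverage(scripts([]), ("2000-01-01", "2001-01-01"))
        assert frac == 0.0
        assert years == pytest.approx(1.0, abs=0.01)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        starts=st.lists(st.integers(0, 300), min_size=1, max_size=8),
        lengths=st.lists(st.integers(1, 90), min_size=8, max_size=8),
        split=st.integers(0, 7),
    )
    def test_coverage_invariant_under_script_splitting(self, starts, lengths, split):
        base = pd.Timestamp("2000-01-01")
        rows = [
            ("p", "simvastatin", 40, base + pd.Timedelta(days=s), d)
            for s, d in zip(starts, lengths[: len(starts)])
        ]
        window = (base, base + pd.Timedelta(days=400))
        frac0, _ = compute_coverage(scripts(rows), window)
        i = split % len(rows)
        pid, drug, dose, s, d = rows[i]
        if d > 1:
            cut = d // 2
            rows[i] = (pid, drug, dose, s, cut)
            rows.append((pid, drug, dose, s + pd.Timedelta(days=cut), d - cut))
        frac1, _ = compute_coverage(scripts(rows), window)
        assert frac1 == pytest.approx(frac0)
        assert 0.0 <= frac1 <= 1.0


class TestSwitches:
    def test_patent_shift_to_atorvastatin_not_counted(self, rules):
        rx = scripts(
            [
                ("p", "simvastatin", 40, "2011-01-01", 56),
                ("p", "simvastatin", 40, "2011-03-01", 56),
                ("p", "atorvastatin", 20, "2013-01-01", 56),
            ]
        )
        assert count_switches(rx, rules) == (0, 2)

    def test_pre_patent_atorvastatin_switch_counts(self, rules):
        rx = scripts(
            [
                ("p", "simvastatin", 40, "2005-01-01", 56),
                ("p", "atorvastatin", 20, "2005-03-01", 56),
            ]
        )
        assert count_switches(rx, rules) == (1, 2)

    def test_back_and_forth_counts_twice(self, rules):
        rx = scripts(
            [
                ("p", "simvastatin", 40, "2000-01-01", 56),
                ("p", "pravastatin", 40, "2000-03-01", 56),
                ("p", "simvastatin", 40, "2000-05-01", 56),
            ]
        )
        assert count_switches(rx, rules) == (2, 2)

    def test_single_drug_no_switches(self, rules):
        rx = scripts([("p", "simvastatin", 40, f"200{y}-01-01", 56) for y in range(3)])
        assert count_switches(rx, rules) == (0, 1)

    def test_invariant_under_same_drug_duplication(self, rules):
        rows = [
            ("p", "simvastatin", 40, "2000-01-01", 56),
            ("p", "pravastatin", 40, "2000-03-01", 56),
        ]
        n0, _ = count_switches(scripts(rows), rules)
        rows.insert(1, ("p", "simvastatin", 40, "2000-01-15", 56))
        n1, _ = count_switches(scripts(rows), rules)
        assert n0 == n1 == 1


class TestDiscontinuations:
    def test_gap_beyond_threshold_is_event(self, rules):
        rx = scripts([("p", "rosuvastatin", 5, "2010-01-01", 56)])
        ev = detect_discontinuations(rx, "2010-09-14", rules)  # 200 days after end
        assert len(ev) == 1
        assert ev.iloc[0]["drug"] == "rosuvastatin"
        assert ev.iloc[0]["daily_dose_mg"] == 5

    def test_continuous_refills_no_event(self, rules):
        rx = scripts(
            [("p", "simvastatin", 40, f"2010-0{m}-01", 56) for m in range(1, 8)]
        )
        ev = detect_discontinuations(rx, "2010-08-15", rules)
        assert len(ev) == 0

    def test_boundary_gap_exactly_threshold_no_event(self, rules):
        rx = scripts([("p", "simvastatin", 40, "2010-01-01", 56)])
        end = pd.Timestamp("2010-01-01") + pd.Timedelta(days=56 + 90)
        assert len(detect_discontinuations(rx, end, rules)) == 0
        assert len(detect_discontinuations(rx, end + pd.Timedelta(days=1), rules)) == 1

    def test_restart_within_gap_suppresses_event(self, rules):
        rx = scripts(
            [
                ("p", "simvastatin", 40, "2010-01-01", 56),
                ("p", "simvastatin", 40, "2010-04-01", 56),  # 34 days after end
            ]
        )
        ev = detect_discontinuations(rx, "2010-06-01", rules)
        assert len(ev) == 0


class TestCKFlags:
    def test_myopathy_candidate_at_4x_uln(self, rules):
        labs = labs_frame([("p", "2010-06-01", "CK", 5 * 320)])
        f = flag_ck(labs, "2010-01-01", "M", rules)
        assert f.any_on_statin_above_uln is True
        assert f.any_on_statin_ge_4x_uln is True

    def test_all_normal(self, rules):
        labs = labs_frame(
            [("p", "2010-06-01", "CK", 150), ("p", "2011-06-01", "CK", 250)]
        )
        f = flag_ck(labs, "2010-01-01", "M", rules)
        assert f.all_on_statin_normal is True
        assert f.any_on_statin_above_uln is False

    def test_pre_therapy_elevation_ignored(self, rules):
        labs = labs_frame(
            [("p", "2009-06-01", "CK", 900), ("p", "2010-06-01", "CK", 150)]
        )
        f = flag_ck(labs, "2010-01-01", "M", rules)
        assert f.any_on_statin_above_uln is False

    def test_no_on_statin_ck_is_undetermined(self, rules):
        labs = labs_frame([("p", "2009-06-01", "CK", 150)])
        f = flag_ck(labs, "2010-01-01", "F", rules)
        assert f.any_on_statin_above_uln is None
        assert f.all_on_statin_normal is None

    def test_sex_specific_uln(self, rules):
        labs = labs_frame([("p", "2010-06-01", "CK", 250)])
        assert flag_ck(labs, "2010-01-01", "F", rules).any_on_statin_above_uln is True
        assert flag_ck(labs, "2010-01-01", "M", rules).any_on_statin_above_uln is False


class TestClassifyPatient:
    def test_long_adherent_normal_ck_is_tolerant_both(self, rules):
        # simvastatin 40 for 6 years at ~95% coverage, no switches, CK normal
        base = pd.Timestamp("2000-01-01")
        rows = [
            ("p", "simvastatin", 40, base + pd.Timedelta(days=59 * i), 56)
            for i in range(38)
        ]
        labs = labs_frame([("p", "2002-01-01", "CK", 120), ("p", "2004-01-01", "CK", 90)])
        end = rows[-1][3] + pd.Timedelta(days=56 + 10)
        a = classify_patient(scripts(rows), labs, "M", rules, end)
        assert a.gsi == "control" and a.ldi == "control"
        assert a.flags["coverage"] > 0.9 and a.flags["years_on_therapy"] >= 5

    def test_elevated_ck_with_switches_then_stop_is_gsi(self, rules):
        rows = [
            ("p", "simvastatin", 40, "2000-01-01", 56),
            ("p", "pravastatin", 80, "2000-04-01", 56),
            ("p", "fluvastatin", 80, "2000-07-01", 56),
        ]
        labs = labs_frame([("p", "2000-05-01", "CK", 1.5 * 320)])
        a = classify_patient(scripts(rows), labs, "M", rules, "2001-06-01")
        assert a.gsi == "case"
        assert a.ldi == "unclassified"  # no lowest-dose discontinuation

    def test_lowest_dose_discontinuation_is_ldi_not_gsi(self, rules):
        rows = [
            ("p", "rosuvastatin", 5, "2000-01-01", 56),
            ("p", "rosuvastatin", 5, "2000-02-26", 56),
            ("p", "atorvastatin", 10, "2001-01-01", 56),
            ("p", "atorvastatin", 10, "2001-02-26", 56),
        ]
        labs = labs_frame([("p", "2000-06-01", "CK", 100)])
        a = classify_patient(scripts(rows), labs, "F", rules, "2002-01-01")
        assert a.ldi == "case"
        assert a.gsi == "unclassified"  # CK never elevated

    def test_single_prescription_excluded(self, rules):
        rows = [("p", "simvastatin", 40, "2000-01-01", 56)]
        a = classify_patient(scripts(rows), labs_frame([]), "M", rules, "2001-01-01")
        assert a.gsi == "excluded" and a.ldi == "excluded"


class TestCohortProperties:
    def test_round_trip_against_planted_truth(self, small_bundle, small_assignments):
        m = small_assignments.merge(small_bundle.truth, on="patient_id")
        assert (m["gsi"] == m["gsi_truth"]).all()
        assert (m["ldi"] == m["ldi_truth"]).all()

    def test_st1_subset_of_st2(self, small_assignments):
        st1 = set(small_assignments.loc[small_assignments["gsi"] == "control", "patient_id"])
        st2 = set(small_assignments.loc[small_assignments["ldi"] == "control", "patient_id"])
        assert st1 <= st2
        assert len(st2) > len(st1)  # some controls carry an incidental CK elevation

    def test_never_case_and_control_of_same_phenotype(self, small_assignments):
        assert set(small_assignments["gsi"]) <= {"case", "control", "unclassified", "excluded"}
        assert not small_assignments.duplicated("patient_id").any()

    def test_classification_is_pure(self, small_bundle, small_assignments, rules):
        from statintol.phenotyping import classify_cohort

        again = classify_cohort(
            small_bundle.prescriptions,
            small_bundle.labs,
            small_bundle.patients,
            rules,
            small_bundle.records_end,
        )
        pd.testing.assert_frame_equal(small_assignments, again)


class TestAnalysisTable:
    def test_unclassified_dropped_and_counts(self, small_bundle, small_assignments):
        from statintol.phenotyping import build_analysis_table

        tbl = build_analysis_table(
            small_assignments, small_bundle.genotypes, small_bundle.patients, "gsi"
        )
        n_classified = small_assignments["gsi"].isin(["case", "control"]).sum()
        assert len(tbl) == n_classified
        truth = small_bundle.truth
        assert tbl["outcome"].sum() == (truth["gsi_truth"] == "case").sum()
        assert set(tbl["genotype_dom"]) <= {0, 1}

    def test_missing_genotype_dropped(self, small_bundle, small_assignments):
        from statintol.phenotyping import build_analysis_table

        tbl_full = build_analysis_table(
            small_assignments, small_bundle.genotypes, small_bundle.patients, "ldi"
        )
        tbl = build_analysis_table(
            small_assignments, small_bundle.genotypes.iloc[1:], small_bundle.patients, "ldi"
        )
        dropped_id = small_bundle.genotypes.iloc[0]["patient_id"]
        was_classified = small_assignments.set_index("patient_id").loc[dropped_id, "ldi"] in (
            "case",
            "control",
        )
        assert len(tbl) == len(tbl_full) - int(was_classified)

    def test_duplicate_patient_errors(self, small_bundle, small_assignments):
        from statintol.phenotyping import build_analysis_table

        dup = pd.concat([small_assignments, small_assignments.iloc[:1]])
        with pytest.raises(ValidationError, match="duplicated"):
            build_analysis_table(dup, small_bundle.genotypes, small_bundle.patients, "gsi")
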