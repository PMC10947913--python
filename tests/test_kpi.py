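from __future__ import annotations

import math
from datetime import date, timedelta

import pandas as pd
import pytest

from conftest import AS_OF
from hfdash.hierarchy import build_evidence
from hfdash.kpi import (KpiConfig, KpiReport, aggregate_kpis,
                        compute_gdmt_use, compute_patient_flags,
                        flag_high_risk_meds, flag_high_risk_patient,
                        kpi_report_frame)
from hfdash.model import (AdmissionRecord, EncounterRecord, MedicationRecord)
from hfdash.phenotyping import phenotype_cohort
from hfdash.selection import ClassificationConfig
from hfdash.simulate import preset, generate

KCFG = KpiConfig()


def med(drug: str, dose: float = 10.0) -> MedicationRecord:
    return MedicationRecord("P1", drug, dose, "mg", date(2022, 1, 1), None)


def adm(days_ago: int, hf: bool = True) -> AdmissionRecord:
    return AdmissionRecord("P1", AS_OF - timedelta(days=days_ago), hf)


def enc(days_ago: int, specialty: str = "cardiology") -> EncounterRecord:
    return EncounterRecord("P1", AS_OF - timedelta(days=days_ago), specialty)


class TestHighRiskPatient:
    def test_two_admissions_plus_cardiology(self):
        assert flag_high_risk_patient([adm(30), adm(200)], [enc(50)], AS_OF, KCFG)

    def test_admissions_without_cardiology_insufficient(self):
        assert not flag_high_risk_patient([adm(30), adm(60), adm(90)], [], AS_OF, KCFG)

    def test_one_admission_insufficient(self):
        assert not flag_high_risk_patient([adm(30)], [enc(50)], AS_OF, KCFG)

    def test_only_hf_admissions_in_past_year_count(self):
        old = [adm(400), adm(30)]
        non_hf = [adm(30, hf=False), adm(60, hf=False)]
        assert not flag_high_risk_patient(old, [enc(10)], AS_OF, KCFG)
        assert not flag_high_risk_patient(non_hf, [enc(10)], AS_OF, KCFG)

    def test_non_cardiology_specialty_does_not_count(self):
        assert not flag_high_risk_patient([adm(30), adm(60)],
                                          [enc(10, "podiatry")], AS_OF, KCFG)


class TestHighRiskMeds:
    @pytest.mark.parametrize("drug,phenotype,expected", [
        ("diltiazem", "HFpEF", False),   # reduced-EF-only drug
        ("diltiazem", "HFrEF", True),
        ("verapamil", "HFmrEF", False),
        ("pioglitazone", "HFmrEF", True),  # any-subtype drug
        ("pioglitazone", "HFpEF", True),
        ("naproxen", "HFrEF", True),
        ("lisinopril", "HFrEF", False),
    ])
    def test_table_rows(self, drug, phenotype, expected):
        flagged, matched = flag_high_risk_meds([med(drug)], phenotype, AS_OF, KCFG)
        assert flagged is expected
        assert (drug in matched) is expected

    def test_inactive_medication_ignored(self):
        ended = MedicationRecord("P1", "diltiazem", 10.0, "mg",
                                 date(2021, 1, 1), date(2021, 6, 1))
        assert flag_high_risk_meds([ended], "HFrEF", AS_OF, KCFG) == (False, [])


class TestGdmtUse:
    def test_at_target(self):
        on, target = compute_gdmt_use([med("metoprolol succinate", 200)],
                                      "HFrEF", AS_OF, KCFG)
        assert on["beta_blocker"] and target["beta_blocker"]

    def test_below_target(self):
        on, target = compute_gdmt_use([med("carvedilol", 12.5)], "HFrEF", AS_OF, KCFG)
        assert on["beta_blocker"] and not target["beta_blocker"]

    def test_no_gdmt(self):
        on, target = compute_gdmt_use([], "HFrEF", AS_OF, KCFG)
        assert not any(on.values()) and not any(target.values())

    def test_only_applicable_classes_for_preserved_ef(self):
        on, _ = compute_gdmt_use([med("dapagliflozin", 10)], "HFpEF", AS_OF, KCFG)
        assert set(on) == {"sglt2_inhibitor"}
        assert on["sglt2_inhibitor"]

    def test_unparseable_dose_counts_on_therapy_not_at_target(self):
        on, target = compute_gdmt_use([med("carvedilol", math.nan)],
                                      "HFrEF", AS_OF, KCFG)
        assert on["beta_blocker"] and not target["beta_blocker"]


def _flags_for(params):
    cohort, _ = generate(params)
    cfg = ClassificationConfig(as_of_date=params.as_of_date)
    results = phenotype_cohort(cohort, build_evidence(cohort), cfg, "v2")
    return compute_patient_flags(cohort, results, cfg.as_of_date, KCFG)


class TestAggregation:
    def test_facility_totals_from_providers(self):
        flags = pd.DataFrame([
            {"patient_id": "P1", "provider_id": "D1", "facility_id": "F1",
             "network_id": "N1", "phenotype": "HFrEF", "gdmt_mra": True},
            {"patient_id": "P2", "provider_id": "D1", "facility_id": "F1",
             "network_id": "N1", "phenotype": "HFrEF", "gdmt_mra": False},
            {"patient_id": "P3", "provider_id": "D2", "facility_id": "F1",
             "network_id": "N1", "phenotype": "HFrEF", "gdmt_mra": True},
        ])
        reports = {(r.level, r.unit_id): r for r in aggregate_kpis(flags, KCFG)}
        facility = reports[("facility", "F1")]
        assert (facility.numerator, facility.denominator) == (2, 3)
        assert facility.percentage == pytest.approx(200 / 3)

    def test_empty_cohort_national_row_undefined(self):
        empty = pd.DataFrame(columns=["patient_id", "provider_id", "facility_id",
                                      "network_id", "phenotype", "high_risk"])
        reports = aggregate_kpis(empty, KCFG)
        national = [r for r in reports if r.level == "national"]
        assert national and national[0].denominator == 0
        assert national[0].percentage is None and national[0].color == "none"

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_across_levels(self, seed):
        flags = _flags_for(preset("paper_like", n_patients=60, seed=seed))
        reports = aggregate_kpis(flags, KCFG)
        by_kpi: dict[str, dict[str, list[KpiReport]]] = {}
        for r in reports:
            by_kpi.setdefault(r.kpi, {}).setdefault(r.level, []).append(r)
        for kpi, levels in by_kpi.items():
            nat = levels["national"][0]
            for level in ("provider", "facility", "network"):
                assert sum(r.numerator for r in levels[level]) == nat.numerator
                assert sum(r.denominator for r in levels[level]) == nat.denominator

    def test_percentages_bounded_and_counts_sane(self):
        flags = _flags_for(preset("paper_like", n_patients=80, seed=9))
        for r in aggregate_kpis(flags, KCFG):
            assert 0 <= r.numerator <= r.denominator
            if r.percentage is not None:
                assert 0 <= r.percentage <= 100


class TestColors:
    @pytest.mark.parametrize("pct,expected", [
        (100.0, "green"), (80.0, "green"), (79.9, "yellow"), (60.0, "yellow"),
        (59.9, "red"), (0.0, "red"),
    ])
    def test_higher_is_better_thresholds(self, pct, expected):
        assert KCFG.color("gdmt_mra", pct) == expected

    @pytest.mark.parametrize("pct,expected", [
        (0.0, "green"), (20.0, "green"), (30.0, "yellow"), (70.0, "red"),
    ])
    def test_lower_is_better_mirrored(self, pct, expected):
        assert KCFG.color("high_risk_meds", pct) == expected

    def test_undefined_score_has_no_color(self):
        assert KCFG.color("gdmt_mra", None) == "none"


def test_report_frame_shape():
    flags = _flags_for(preset("clean", n_patients=20, seed=2))
    frame = kpi_report_frame(aggregate_kpis(flags, KCFG))
    assert list(frame.columns) == ["level", "unit_id", "kpi", "numerator",
                                   "denominator", "pct", "color"]
    assert (frame["level"] == "national").sum() == len(frame["kpi"].unique())
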