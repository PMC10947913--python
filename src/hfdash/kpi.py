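"""Key performance indicators over the phenotyped cohort.

Four families of quality measures are computed per included patient and
rolled up to provider, facility, network and national levels:

* ``high_risk`` — at least 2 HF admissions in the past year AND at
  least one cardiology-specialty encounter in the past year;
* ``gdmt_<class>`` / ``gdmt_target_<class>`` — on therapy / at target
  dose for each guideline-directed medication class applicable to the
  patient's phenotype;
* ``high_risk_meds`` — on a medication considered harmful in heart
  failure: an any-subtype list (oral NSAIDs, the DPP-4 inhibitors
  alogliptin and saxagliptin, the thiazolidinediones pioglitazone and
  rosiglitazone) plus a reduced-EF-only list (cilostazol, the
  antiarrhythmics disopyramide, dronedarone, flecainide, propafenone,
  and the calcium-channel blockers diltiazem, verapamil, nifedipine).

GDMT class membership and target doses are guideline-derived editable
defaults shipped with the package, not fixed rules. Scores are colored
green/yellow/red from configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from .model import AdmissionRecord, Cohort, EncounterRecord, MedicationRecord
from .phenotyping import PhenotypeResult
from .selection import years_before

__all__ = [
    "GdmtClass",
    "KpiConfig",
    "KpiReport",
    "flag_high_risk_patient",
    "flag_high_risk_meds",
    "compute_gdmt_use",
    "compute_patient_flags",
    "aggregate_kpis",
    "kpi_report_frame",
]

LEVELS = ("provider", "facility", "network", "national")


@dataclass(frozen=True)
class GdmtClass:
    """One guideline-directed medication class with per-drug daily target doses."""

    name: str
    phenotypes: tuple[str, ...]
    target_doses: dict[str, float] = field(hash=False)

    def members(self) -> set[str]:
        return {d.lower() for d in self.target_doses}


def _default_gdmt() -> tuple[GdmtClass, ...]:
    # Guideline-derived defaults (editable config, not fixed rules).
    return (
        GdmtClass("beta_blocker", ("HFrEF",), {
            "metoprolol succinate": 200, "carvedilol": 50, "bisoprolol": 10}),
        GdmtClass("raas_inhibitor", ("HFrEF",), {
            "lisinopril": 40, "losartan": 150, "valsartan": 320,
            "sacubitril/valsartan": 194}),
        GdmtClass("mra", ("HFrEF",), {"spironolactone": 50, "eplerenone": 50}),
        GdmtClass("sglt2_inhibitor", ("HFrEF", "HFmrEF", "HFpEF"), {
            "dapagliflozin": 10, "empagliflozin": 10}),
    )


_ANY_HF_HIGH_RISK = (
    "ibuprofen", "naproxen", "indomethacin", "diclofenac", "meloxicam",
    "alogliptin", "saxagliptin", "pioglitazone", "rosiglitazone",
)
_HFREF_HIGH_RISK = (
    "cilostazol", "disopyramide", "dronedarone", "flecainide", "propafenone",
    "diltiazem", "verapamil", "nifedipine",
)


@dataclass(frozen=True)
class KpiConfig:
    gdmt_classes: tuple[GdmtClass, ...] = field(default_factory=_default_gdmt)
    high_risk_meds_any_hf: tuple[str, ...] = _ANY_HF_HIGH_RISK
    high_risk_meds_hfref: tuple[str, ...] = _HFREF_HIGH_RISK
    high_risk_admission_count: int = 2
    cardiology_specialty_labels: tuple[str, ...] = ("cardiology",)
    # pct >= green_min -> green; >= yellow_min -> yellow; else red
    color_thresholds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"default": (80.0, 60.0)}, hash=False)
    # for these KPIs a LOW percentage is good; thresholds are mirrored
    lower_is_better: tuple[str, ...] = ("high_risk", "high_risk_meds")

    def __post_init__(self) -> None:
        for kpi, (green, yellow) in self.color_thresholds.items():
            if green <= yellow:
                raise ValueError(f"{kpi}: green_min must exceed yellow_min")

    def color(self, kpi: str, percentage: float | None) -> str:
        if percentage is None:
            return "none"
        green_min, yellow_min = self.color_thresholds.get(
            kpi, self.color_thresholds["default"])
        pct = 100 - percentage if kpi in self.lower_is_better else percentage
        if pct >= green_min:
            return "green"
        if pct >= yellow_min:
            return "yellow"
        return "red"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KpiConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "gdmt_classes" in data:
            kwargs["gdmt_classes"] = tuple(
                GdmtClass(c["name"], tuple(c["phenotypes"]),
                          {k.lower(): float(v) for k, v in c["target_doses"].items()})
                for c in data["gdmt_classes"])
        for key in ("high_risk_meds_any_hf", "high_risk_meds_hfref",
                    "cardiology_specialty_labels", "lower_is_better"):
            if key in data:
                kwargs[key] = tuple(s.lower() for s in data[key])
        if "high_risk_admission_count" in data:
            kwargs["high_risk_admission_count"] = int(data["high_risk_admission_count"])
        if "color_thresholds" in data:
            kwargs["color_thresholds"] = {
                k: (float(v[0]), float(v[1])) for k, v in data["color_thresholds"].items()}
        return cls(**kwargs)


def flag_high_risk_patient(admissions: list[AdmissionRecord],
                           encounters: list[EncounterRecord],
                           as_of_date: date,
                           cfg: KpiConfig) -> bool:
    """>= 2 HF admissions in the past year AND cardiology care in the past year."""
    window_start = years_before(as_of_date, 1)
    n_hf_adm = sum(1 for a in admissions
                   if a.primary_dx_is_hf and window_start <= a.admit_date <= as_of_date)
    cardio = any(window_start <= e.encounter_date <= as_of_date
                 and e.specialty.lower() in {s.lower() for s in cfg.cardiology_specialty_labels}
                 for e in encounters)
    return n_hf_adm >= cfg.high_risk_admission_count and cardio


def _active_drugs(medications: list[MedicationRecord], day: date) -> list[MedicationRecord]:
    return [m for m in medications if m.active_on(day)]


def flag_high_risk_meds(medications: list[MedicationRecord],
                        phenotype: str,
                        as_of_date: date,
                        cfg: KpiConfig) -> tuple[bool, list[str]]:
    """Any active medication on the harmful list for this patient's phenotype."""
    any_hf = {d.lower() for d in cfg.high_risk_meds_any_hf}
    hfref_only = {d.lower() for d in cfg.high_risk_meds_hfref}
    matched = []
    for m in _active_drugs(medications, as_of_date):
        name = m.drug_name.lower()
        if name in any_hf or (phenotype == "HFrEF" and name in hfref_only):
            matched.append(m.drug_name)
    return bool(matched), sorted(set(matched))


def compute_gdmt_use(medications: list[MedicationRecord],
                     phenotype: str,
                     as_of_date: date,
                     cfg: KpiConfig) -> tuple[dict[str, bool], dict[str, bool]]:
    """(on-therapy, at-target) per GDMT class applicable to the phenotype.

    A drug whose dose cannot be interpreted (NaN) counts as on-therapy
    but not at target.
    """
    active = _active_drugs(medications, as_of_date)
    on: dict[str, bool] = {}
    at_target: dict[str, bool] = {}
    for gdmt in cfg.gdmt_classes:
        if phenotype not in gdmt.phenotypes:
            continue
        members = gdmt.members()
        hits = [m for m in active if m.drug_name.lower() in members]
        on[gdmt.name] = bool(hits)
        at_target[gdmt.name] = any(
            not math.isnan(m.dose) and m.dose >= gdmt.target_doses[m.drug_name.lower()]
            for m in hits)
    return on, at_target


def compute_patient_flags(cohort: Cohort,
                          phenotypes: dict[str, PhenotypeResult],
                          as_of_date: date,
                          cfg: KpiConfig) -> pd.DataFrame:
    """Per-patient KPI flags for every included patient.

    Columns: the reporting IDs plus one column per KPI holding True /
    False / pd.NA (NA = patient not in that KPI's denominator).
    """
    meds: dict[str, list[MedicationRecord]] = {}
    adms: dict[str, list[AdmissionRecord]] = {}
    encs: dict[str, list[EncounterRecord]] = {}
    for m in cohort.medications:
        meds.setdefault(m.patient_id, []).append(m)
    for a in cohort.admissions:
        adms.setdefault(a.patient_id, []).append(a)
    for e in cohort.encounters:
        encs.setdefault(e.patient_id, []).append(e)

    kpi_names = ["high_risk", "high_risk_meds"]
    for gdmt in cfg.gdmt_classes:
        kpi_names += [f"gdmt_{gdmt.name}", f"gdmt_target_{gdmt.name}"]

    rows = []
    for patient in cohort.patients:
        pid = patient.patient_id
        result = phenotypes[pid]
        if not result.included:
            continue
        row: dict = {
            "patient_id": pid, "provider_id": patient.provider_id,
            "facility_id": patient.facility_id, "network_id": patient.network_id,
            "phenotype": result.phenotype,
        }
        for k in kpi_names:
            row[k] = pd.NA
        row["high_risk"] = flag_high_risk_patient(
            adms.get(pid, []), encs.get(pid, []), as_of_date, cfg)
        row["high_risk_meds"] = flag_high_risk_meds(
            meds.get(pid, []), result.phenotype, as_of_date, cfg)[0]
        if result.phenotype != "unspecified":
            on, target = compute_gdmt_use(meds.get(pid, []), result.phenotype,
                                          as_of_date, cfg)
            for cls, flag in on.items():
                row[f"gdmt_{cls}"] = flag
                row[f"gdmt_target_{cls}"] = target[cls]
        rows.append(row)
    columns = ["patient_id", "provider_id", "facility_id", "network_id",
               "phenotype"] + kpi_names
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class KpiReport:
    """One KPI score for one reporting unit."""

    level: str
    unit_id: str
    kpi: str
    numerator: int
    denominator: int
    percentage: float | None  # None when denominator is 0
    color: str

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")


_LEVEL_KEY = {"provider": "provider_id", "facility": "facility_id",
              "network": "network_id"}


def aggregate_kpis(flags: pd.DataFrame, cfg: KpiConfig) -> list[KpiReport]:
    """Roll up per-patient flags to provider/facility/network/national scores.

    Numerators and denominators are exact integers and are conserved
    across levels; the national row is always present.
    """
    id_cols = {"patient_id", "provider_id", "facility_id", "network_id", "phenotype"}
    kpi_names = [c for c in flags.columns if c not in id_cols]
    reports: list[KpiReport] = []

    def score(level: str, unit_id: str, kpi: str, series: pd.Series) -> KpiReport:
        den = int(series.notna().sum())
        num = int((series.dropna().astype(bool)).sum()) if den else 0
        pct = None if den == 0 else 100.0 * num / den
        return KpiReport(level, unit_id, kpi, num, den, pct, cfg.color(kpi, pct))

    for kpi in kpi_names:
        reports.append(score("national", "national", kpi, flags[kpi]))
        for level in ("network", "facility", "provider"):
            key = _LEVEL_KEY[level]
            for unit_id, group in flags.groupby(key, sort=True):
                reports.append(score(level, str(unit_id), kpi, group[kpi]))
    return reports


def kpi_report_frame(reports: list[KpiReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"level": r.level, "unit_id": r.unit_id, "kpi": r.kpi,
          "numerator": r.numerator, "denominator": r.denominator,
          "pct": r.percentage, "color": r.color} for r in reports],
        columns=["level", "unit_id", "kpi", "numerator", "denominator", "pct", "color"])
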