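"""Seeded generator of gold-labeled synthetic EHR cohorts.

No real registry data ship with the package, so testing end-to-end
requires a cohort whose truth is known. Each simulated patient gets a
true phenotype and a true LVEF drawn inside the phenotype's band, then
a multi-year record trail carrying that LVEF through the same noise
processes the real data sources exhibit:

* echo reports occasionally state a range of two values instead of one
  (the multi-value failure mode the resolution logic exists for);
* nuclear-sourced values (cath-lab registry entries and most radiology
  reports) carry an additive Gaussian error, biased low;
* a fraction of radiology reports state a gallbladder — not left
  ventricular — ejection fraction;
* ICD coding is imperfect: some patients lack any HF documentation,
  and some carry a code family that contradicts their true phenotype.

All randomness flows from the seed. The ``clean`` preset switches every
noise process off (one recent single-value echo per patient, perfect
coding) so the pipeline must recover the gold labels exactly; the
``paper_like`` preset switches them on at the package's documented
defaults.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from . import extraction as ex
from .model import (AdmissionRecord, CartRecord, Cohort, DiagnosisRecord,
                    EncounterRecord, ImagingReport, MedicationRecord, Patient)
from .selection import years_before

__all__ = ["SimulationParams", "preset", "generate", "generate_to_dir", "PRESETS"]

_SYSTOLIC_CODES = ("I50.20", "I50.22", "I50.23")
_DIASTOLIC_CODES = ("I50.30", "I50.32")
_UNSPECIFIED_CODES = ("I50.9",)
_ICD9 = {"systolic": "428.22", "diastolic": "428.32", "unspecified": "428.0"}

_GDMT_DRUGS = {
    "beta_blocker": (("metoprolol succinate", 200.0), ("carvedilol", 50.0)),
    "raas_inhibitor": (("lisinopril", 40.0), ("losartan", 150.0)),
    "mra": (("spironolactone", 50.0), ("eplerenone", 50.0)),
    "sglt2_inhibitor": (("dapagliflozin", 10.0), ("empagliflozin", 10.0)),
}
_GDMT_PHENOTYPES = {
    "beta_blocker": ("HFrEF",), "raas_inhibitor": ("HFrEF",), "mra": ("HFrEF",),
    "sglt2_inhibitor": ("HFrEF", "HFmrEF", "HFpEF"),
}
_ANY_HF_RISK_DRUGS = ("ibuprofen", "naproxen", "pioglitazone", "saxagliptin")
_HFREF_RISK_DRUGS = ("diltiazem", "verapamil", "dronedarone", "cilostazol")


@dataclass(frozen=True)
class SimulationParams:
    """Everything the generator needs; defaults are the noisy study conditions."""

    n_patients: int = 500
    seed: int = 0
    as_of_date: date = date(2023, 6, 30)
    timeline_years: int = 3
    phenotype_prevalence: dict[str, float] = field(
        default_factory=lambda: {"HFrEF": 0.40, "HFmrEF": 0.15, "HFpEF": 0.45},
        hash=False)
    # uniform integer bands, 2 points inside each class boundary
    true_lvef_bands: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"HFrEF": (15, 38), "HFmrEF": (43, 47),
                                 "HFpEF": (52, 73)}, hash=False)
    min_studies: int = 1
    max_studies: int = 5
    source_mix: dict[str, float] = field(
        default_factory=lambda: {"nlp_echo": 0.45, "nlp_note": 0.15,
                                 "nlp_radiology": 0.20, "cart": 0.20}, hash=False)
    cart_modality_mix: dict[str, float] = field(
        default_factory=lambda: {"TTE": 0.55, "TEE": 0.05, "MRI": 0.05,
                                 "ventriculography": 0.10, "nuclear": 0.25},
        hash=False)
    p_multi_value_echo: float = 0.30
    multi_value_spread: tuple[int, int] = (2, 20)  # even spread drawn uniformly
    nuclear_bias: float = -10.0
    nuclear_sd: float = 15.0
    p_radiology_noncardiac: float = 0.15
    p_icd_missing: float = 0.10
    p_icd_false_positive: float = 0.15
    p_problem_list_active: float = 0.50
    # care-process rates feeding the KPI engine
    p_gdmt_on: float = 0.55
    p_gdmt_target: float = 0.50
    p_high_risk_med: float = 0.10
    hf_admissions_per_year: float = 0.6
    p_cardiology_encounter: float = 0.40
    n_networks: int = 2
    facilities_per_network: int = 2
    providers_per_facility: int = 3

    def __post_init__(self) -> None:
        total = sum(self.phenotype_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype prevalence must sum to 1, got {total}")
        for name, p in [("p_multi_value_echo", self.p_multi_value_echo),
                        ("p_radiology_noncardiac", self.p_radiology_noncardiac),
                        ("p_icd_missing", self.p_icd_missing),
                        ("p_icd_false_positive", self.p_icd_false_positive),
                        ("p_problem_list_active", self.p_problem_list_active)]:
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


PRESETS = ("clean", "paper_like")


def preset(name: str, **overrides) -> SimulationParams:
    """Named parameter bundles: ``clean`` (all noise off) or ``paper_like``."""
    if name == "paper_like":
        return replace(SimulationParams(), **overrides)
    if name == "clean":
        base = SimulationParams(
            source_mix={"nlp_echo": 1.0, "nlp_note": 0.0, "nlp_radiology": 0.0,
                        "cart": 0.0},
            min_studies=1, max_studies=1, timeline_years=1,
            p_multi_value_echo=0.0, p_radiology_noncardiac=0.0,
            p_icd_missing=0.0, p_icd_false_positive=0.0,
            p_problem_list_active=1.0)
        return replace(base, **overrides)
    raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")


def _choose(rng: random.Random, weights: dict[str, float]) -> str:
    names = sorted(weights)
    return rng.choices(names, weights=[weights[n] for n in names], k=1)[0]


def _random_date(rng: random.Random, start: date, end: date) -> date:
    return start + timedelta(days=rng.randrange((end - start).days + 1))


def _family(phenotype: str) -> str:
    return {"HFrEF": "systolic", "HFmrEF": "unspecified", "HFpEF": "diastolic"}[phenotype]


def _code_for(rng: random.Random, family: str) -> tuple[str, str]:
    # one in ten coded records uses the legacy ICD-9 vocabulary
    if rng.random() < 0.10:
        return _ICD9[family], "ICD9"
    pool = {"systolic": _SYSTOLIC_CODES, "diastolic": _DIASTOLIC_CODES,
            "unspecified": _UNSPECIFIED_CODES}[family]
    return rng.choice(pool), "ICD10"


def _nuclear_value(rng: random.Random, true_lvef: float, p: SimulationParams) -> float:
    raw = true_lvef + rng.gauss(p.nuclear_bias, p.nuclear_sd)
    return float(min(95, max(5, round(raw))))


def generate(params: SimulationParams) -> tuple[Cohort, pd.DataFrame]:
    """Simulate one cohort; returns it with a gold-label frame
    (patient_id, true_phenotype, true_lvef)."""
    rng = random.Random(params.seed)
    window_start = years_before(params.as_of_date, params.timeline_years)
    year_start = years_before(params.as_of_date, 1)

    patients: list[Patient] = []
    diagnoses: list[DiagnosisRecord] = []
    reports: list[ImagingReport] = []
    cart: list[CartRecord] = []
    meds: list[MedicationRecord] = []
    admissions: list[AdmissionRecord] = []
    encounters: list[EncounterRecord] = []
    gold_rows: list[dict] = []
    report_counter = 0

    classes = sorted(params.phenotype_prevalence)
    for i in range(params.n_patients):
        pid = f"P{i:05d}"
        network = rng.randrange(params.n_networks)
        facility = rng.randrange(params.facilities_per_network)
        provider = rng.randrange(params.providers_per_facility)
        patients.append(Patient(
            patient_id=pid,
            facility_id=f"N{network}-F{facility}",
            provider_id=f"N{network}-F{facility}-D{provider}",
            network_id=f"N{network}"))

        phenotype = rng.choices(
            classes, weights=[params.phenotype_prevalence[c] for c in classes], k=1)[0]
        lo, hi = params.true_lvef_bands[phenotype]
        true_lvef = float(rng.randint(lo, hi))
        gold_rows.append({"patient_id": pid, "true_phenotype": phenotype,
                          "true_lvef": true_lvef})

        # --- diagnoses -------------------------------------------------
        documented = rng.random() >= params.p_icd_missing
        if documented:
            family = _family(phenotype)
            if rng.random() < params.p_icd_false_positive:
                family = rng.choice([f for f in ("systolic", "diastolic", "unspecified")
                                     if f != family])
            for _ in range(rng.randint(1, 3)):
                code, system = _code_for(rng, family)
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, code=code, code_system=system,
                    record_date=_random_date(rng, window_start, params.as_of_date),
                    origin="encounter", active=False))
            if rng.random() < params.p_problem_list_active:
                code, system = _code_for(rng, family)
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, code=code, code_system=system,
                    record_date=_random_date(rng, window_start, params.as_of_date),
                    origin="problem_list", active=True))

        # --- imaging / registry studies -------------------------------
        n_studies = rng.randint(params.min_studies, params.max_studies)
        for _ in range(n_studies):
            source = _choose(rng, params.source_mix)
            study_date = _random_date(rng, window_start, params.as_of_date)
            if source == "cart":
                modality = _choose(rng, params.cart_modality_mix)
                value = (_nuclear_value(rng, true_lvef, params)
                         if modality == "nuclear" else true_lvef)
                cart.append(CartRecord(patient_id=pid, record_date=study_date,
                                       lvef=value, source_modality=modality))
                continue
            report_counter += 1
            rid = f"R{report_counter:06d}"
            if source == "nlp_echo":
                if rng.random() < params.p_multi_value_echo:
                    spread = 2 * rng.randint(params.multi_value_spread[0] // 2,
                                             params.multi_value_spread[1] // 2)
                    lo_v = max(1.0, true_lvef - spread / 2)
                    hi_v = min(100.0, true_lvef + spread / 2)
                    text = ex.render_range(rng, lo_v, hi_v)
                else:
                    text = ex.render_single(rng, true_lvef)
                reports.append(ImagingReport(
                    report_id=rid, patient_id=pid, report_date=study_date,
                    source_system="echo",
                    modality_hint=rng.choice(["TTE", "TTE", "TTE", "TEE"]),
                    text=text))
            elif source == "nlp_note":
                text = ex.render_single(rng, true_lvef)
                reports.append(ImagingReport(
                    report_id=rid, patient_id=pid, report_date=study_date,
                    source_system="clinical_note", modality_hint=None, text=text))
            else:  # nlp_radiology: gallbladder decoy or nuclear-grade EF
                if rng.random() < params.p_radiology_noncardiac:
                    text = ex.render_non_cardiac(rng, float(rng.randint(80, 98)))
                else:
                    text = ex.render_single(rng, _nuclear_value(rng, true_lvef, params))
                reports.append(ImagingReport(
                    report_id=rid, patient_id=pid, report_date=study_date,
                    source_system="radiology", modality_hint="nuclear", text=text))

        # --- care processes for the KPI engine -------------------------
        if documented:
            for cls, drugs in _GDMT_DRUGS.items():
                if phenotype not in _GDMT_PHENOTYPES[cls]:
                    continue
                if rng.random() < params.p_gdmt_on:
                    drug, target = rng.choice(drugs)
                    dose = target if rng.random() < params.p_gdmt_target else target / 2
                    meds.append(MedicationRecord(
                        patient_id=pid, drug_name=drug, dose=dose, dose_unit="mg",
                        start_date=_random_date(rng, window_start, year_start),
                        end_date=None))
            if rng.random() < params.p_high_risk_med:
                pool = _ANY_HF_RISK_DRUGS + (
                    _HFREF_RISK_DRUGS if phenotype == "HFrEF" else ())
                meds.append(MedicationRecord(
                    patient_id=pid, drug_name=rng.choice(pool), dose=10.0,
                    dose_unit="mg",
                    start_date=_random_date(rng, window_start, year_start),
                    end_date=None))
        n_adm = min(6, _poisson(rng, params.hf_admissions_per_year))
        for _ in range(n_adm):
            admissions.append(AdmissionRecord(
                patient_id=pid,
                admit_date=_random_date(rng, year_start, params.as_of_date),
                primary_dx_is_hf=rng.random() < 0.8))
        if rng.random() < params.p_cardiology_encounter:
            encounters.append(EncounterRecord(
                patient_id=pid,
                encounter_date=_random_date(rng, year_start, params.as_of_date),
                specialty="cardiology"))
        if rng.random() < 0.5:
            encounters.append(EncounterRecord(
                patient_id=pid,
                encounter_date=_random_date(rng, year_start, params.as_of_date),
                specialty="primary care"))

    cohort = Cohort(patients=patients, diagnoses=diagnoses, imaging_reports=reports,
                    cart_records=cart, medications=meds, admissions=admissions,
                    encounters=encounters)
    gold = pd.DataFrame(gold_rows, columns=["patient_id", "true_phenotype", "true_lvef"])
    return cohort, gold


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small here
    import math
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def generate_to_dir(params: SimulationParams, out_dir: str | Path) -> tuple[Cohort, pd.DataFrame]:
    """Generate and persist cohort files plus gold_labels.csv."""
    from .model import write_cohort
    cohort, gold = generate(params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out)
    gold.to_csv(out / "gold_labels.csv", index=False)
    return cohort, gold


def gold_as_dict(gold: pd.DataFrame) -> dict[str, str]:
    return dict(zip(gold["patient_id"], gold["true_phenotype"]))
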