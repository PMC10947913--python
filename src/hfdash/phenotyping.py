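"""Cohort inclusion and heart-failure phenotype assignment.

A patient enters the dashboard only with documented heart failure: an
HF ICD code from any encounter on or before the as-of date, or an
active HF entry on the problem list. Included patients are phenotyped
from their effective LVEF:

* HFrEF   — LVEF <= 40%
* HFmrEF  — LVEF 41%-49% (non-integer values in the open interval
  (40, 50) also map here, so an averaged 40.5 is HFmrEF)
* HFpEF   — LVEF >= 50%
* unspecified — evidence absent, discordant, or implausible

Two algorithm versions are provided. The current one (v2) uses the
quality-hierarchy selection. The legacy one (v1) uses the lowest LVEF
from any source in the past 3 years with a two-class split (<= 40
reduced, > 40 preserved) and, when no LVEF exists at all, falls back to
ICD codes alone: systolic-HF codes map to HFrEF, diastolic-HF codes to
HFpEF, anything else to unspecified. The fallback code mapping is a
configurable assumption, not a published rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from .hierarchy import EvidenceItem
from .model import Cohort, DiagnosisRecord
from .selection import (ClassificationConfig, SelectionResult,
                        select_effective_lvef, select_effective_lvef_v1)

__all__ = [
    "HfCodeConfig",
    "PhenotypeResult",
    "has_documented_hf",
    "classify_lvef",
    "phenotype_patient",
    "phenotype_cohort",
    "write_phenotypes_csv",
]

PHENOTYPES = ("HFrEF", "HFmrEF", "HFpEF", "unspecified")


@dataclass(frozen=True)
class HfCodeConfig:
    """HF code-set prefixes (ICD-10 I50.*, ICD-9 428.*) and the legacy ICD-only fallback map."""

    hf_prefixes: tuple[str, ...] = ("I50", "428")
    systolic_prefixes: tuple[str, ...] = ("I50.2", "I50.4", "428.2", "428.4")
    diastolic_prefixes: tuple[str, ...] = ("I50.3", "428.3")

    def is_hf(self, code: str) -> bool:
        return code.upper().startswith(tuple(p.upper() for p in self.hf_prefixes))

    def icd_only_phenotype(self, codes: list[str]) -> str:
        """Legacy fallback when no LVEF exists: phenotype from code families alone."""
        upper = [c.upper() for c in codes]
        systolic = any(c.startswith(tuple(p.upper() for p in self.systolic_prefixes))
                       for c in upper)
        diastolic = any(c.startswith(tuple(p.upper() for p in self.diastolic_prefixes))
                        for c in upper)
        if systolic and not diastolic:
            return "HFrEF"
        if diastolic and not systolic:
            return "HFpEF"
        return "unspecified"


def has_documented_hf(diagnoses: list[DiagnosisRecord],
                      codes: HfCodeConfig,
                      as_of_date: date) -> bool:
    """True iff the patient has an HF encounter code on/before the as-of date
    or an active HF problem-list entry."""
    for d in diagnoses:
        if not codes.is_hf(d.code):
            continue
        if d.origin == "encounter" and d.record_date <= as_of_date:
            return True
        if d.origin == "problem_list" and d.active:
            return True
    return False


def classify_lvef(effective_lvef: float, cfg: ClassificationConfig) -> str:
    """Map an effective LVEF to a phenotype: <=40 reduced, (40, 50) mildly reduced, >=50 preserved."""
    if not (0 < effective_lvef <= 100):
        raise ValueError(f"effective LVEF {effective_lvef} outside (0, 100]")
    if effective_lvef <= cfg.hfref_max:
        return "HFrEF"
    if effective_lvef < cfg.hfmref_max + 1:
        return "HFmrEF"
    return "HFpEF"


@dataclass(frozen=True)
class PhenotypeResult:
    """Per-patient classification with its selection audit trail."""

    patient_id: str
    included: bool
    phenotype: str | None  # None iff not included
    algorithm_version: str  # "v1" | "v2"
    selection: SelectionResult | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.included != (self.phenotype is not None):
            raise ValueError("phenotype present iff included")
        if self.phenotype is not None and self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.algorithm_version == "v1" and self.phenotype == "HFmrEF":
            raise ValueError("legacy algorithm never emits HFmrEF")


def phenotype_patient(patient_id: str,
                      diagnoses: list[DiagnosisRecord],
                      evidence: list[EvidenceItem],
                      cfg: ClassificationConfig,
                      version: str = "v2",
                      codes: HfCodeConfig | None = None) -> PhenotypeResult:
    """Classify one patient under the chosen algorithm version."""
    if version not in ("v1", "v2"):
        raise ValueError(f"unknown algorithm version {version!r}")
    codes = codes or HfCodeConfig()
    if not has_documented_hf(diagnoses, codes, cfg.as_of_date):
        return PhenotypeResult(patient_id, False, None, version, None)

    if version == "v2":
        sel = select_effective_lvef(evidence, cfg, patient_id=patient_id)
        phenotype = (classify_lvef(sel.effective_lvef, cfg)
                     if sel.verdict == "value" else "unspecified")
        return PhenotypeResult(patient_id, True, phenotype, "v2", sel)

    sel = select_effective_lvef_v1(evidence, cfg, patient_id=patient_id)
    if sel.verdict == "value":
        phenotype = "HFrEF" if sel.effective_lvef <= cfg.hfref_max else "HFpEF"
    else:
        hf_codes = [d.code for d in diagnoses if codes.is_hf(d.code)
                    and (d.origin == "problem_list" or d.record_date <= cfg.as_of_date)]
        phenotype = codes.icd_only_phenotype(hf_codes)
    return PhenotypeResult(patient_id, True, phenotype, "v1", sel)


def phenotype_cohort(cohort: Cohort,
                     evidence: dict[str, list[EvidenceItem]],
                     cfg: ClassificationConfig,
                     version: str = "v2",
                     codes: HfCodeConfig | None = None) -> dict[str, PhenotypeResult]:
    """Classify every roster patient; the result partitions the roster."""
    dx_by_patient: dict[str, list[DiagnosisRecord]] = {pid: [] for pid in cohort.patient_ids}
    for d in cohort.diagnoses:
        dx_by_patient[d.patient_id].append(d)
    return {
        pid: phenotype_patient(pid, dx_by_patient[pid], evidence.get(pid, []),
                               cfg, version, codes)
        for pid in cohort.patient_ids
    }


def write_phenotypes_csv(results: dict[str, PhenotypeResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "algorithm_version", "included", "phenotype",
                         "effective_lvef", "rule_fired", "evidence_date",
                         "evidence_provenance"])
        for pid in sorted(results):
            r = results[pid]
            sel = r.selection
            writer.writerow([
                pid, r.algorithm_version,
                "true" if r.included else "false",
                r.phenotype if r.phenotype is not None else "not_included",
                "" if sel is None or sel.effective_lvef is None
                else format(sel.effective_lvef, "g"),
                sel.rule_fired if sel else "",
                ";".join(e.event_date.isoformat() for e in sel.chosen_items) if sel else "",
                ";".join(e.provenance for e in sel.chosen_items) if sel else ""])
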