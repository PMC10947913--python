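"""Imaging-quality hierarchy: tier every LVEF measurement by its source.

Not all ejection-fraction measurements are equally trustworthy. The
dashboard's quality model assigns each measurement a tier from its
provenance and modality:

==========================  =========================  ==========
provenance                  modality / multiplicity    tier
==========================  =========================  ==========
NLP of echo report          single value               high
NLP of echo report          more than one value        medium
NLP of clinical note        any                        medium
NLP of radiology report     any                        excluded
structured cath-lab entry   TTE / TEE / MRI / CT       high
structured cath-lab entry   ventriculography           medium
structured cath-lab entry   nuclear (SPECT / PET)      excluded
==========================  =========================  ==========

Radiology-derived and nuclear-sourced values are excluded outright:
radiology text is dominated by nuclear stress tests and non-cardiac
ejection fractions (gallbladder studies), and nuclear EF estimates are
too inaccurate to phenotype on. Excluded items are retained, marked,
for audit, but never participate in selection.

The mapping fails closed: an unknown provenance/modality combination
raises rather than being silently tiered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path

from .extraction import LvefMention, PatternConfig, extract_lvef
from .model import Cohort

__all__ = ["EvidenceItem", "TierError", "assign_tier", "build_evidence", "dump_evidence_csv"]

PROVENANCES = ("nlp_echo", "nlp_note", "nlp_radiology", "cart")
TIERS = ("high", "medium", "excluded")

_SOURCE_TO_PROVENANCE = {
    "echo": "nlp_echo",
    "clinical_note": "nlp_note",
    "radiology": "nlp_radiology",
}

_CART_TIER = {
    "TTE": "high",
    "TEE": "high",
    "MRI": "high",
    "CT": "high",
    "ventriculography": "medium",
    "nuclear": "excluded",
}


class TierError(ValueError):
    """Unknown provenance/modality combination — never silently tiered."""


def assign_tier(provenance: str, modality: str | None, n_values: int) -> str:
    """Quality tier for a measurement from (provenance, modality, value count).

    Total over the documented combinations; anything else raises
    :class:`TierError`.
    """
    if n_values < 1:
        raise ValueError("n_values must be >= 1")
    if provenance == "nlp_echo":
        return "high" if n_values == 1 else "medium"
    if provenance == "nlp_note":
        return "medium"
    if provenance == "nlp_radiology":
        return "excluded"
    if provenance == "cart":
        try:
            return _CART_TIER[modality]
        except KeyError:
            raise TierError(
                f"no tier defined for cath-lab source modality {modality!r}") from None
    raise TierError(f"unknown provenance {provenance!r}")


@dataclass(frozen=True)
class EvidenceItem:
    """A quality-tiered, dated LVEF measurement eligible for selection."""

    patient_id: str
    event_date: date
    values: tuple[float, ...]
    provenance: str
    modality: str | None
    tier: str

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("EvidenceItem requires at least one value")
        if self.provenance not in PROVENANCES:
            raise TierError(f"unknown provenance {self.provenance!r}")
        expected = assign_tier(self.provenance, self.modality, len(self.values))
        if self.tier != expected:
            raise TierError(
                f"tier {self.tier!r} inconsistent with ({self.provenance}, "
                f"{self.modality}, {len(self.values)} values): expected {expected!r}")


def make_evidence(patient_id: str, event_date: date, values: tuple[float, ...],
                  provenance: str, modality: str | None) -> EvidenceItem:
    """Construct an item with its tier derived from the hierarchy."""
    return EvidenceItem(
        patient_id=patient_id, event_date=event_date, values=tuple(values),
        provenance=provenance, modality=modality,
        tier=assign_tier(provenance, modality, len(values)))


def build_evidence(cohort: Cohort,
                   patterns: PatternConfig | None = None) -> dict[str, list[EvidenceItem]]:
    """Extract and tier all LVEF evidence, keyed by patient.

    Every roster patient gets a (possibly empty) list. Non-cardiac text
    mentions are dropped before tiering; excluded-tier items (radiology
    NLP, nuclear cath-lab entries) are kept and marked for audit.
    """
    patterns = patterns or PatternConfig()
    evidence: dict[str, list[EvidenceItem]] = {pid: [] for pid in cohort.patient_ids}
    for report in cohort.imaging_reports:
        mention = extract_lvef(report, patterns)
        if mention is None or mention.non_cardiac:
            continue
        evidence[report.patient_id].append(make_evidence(
            report.patient_id, report.report_date, mention.values,
            _SOURCE_TO_PROVENANCE[report.source_system], report.modality_hint))
    for rec in cohort.cart_records:
        evidence[rec.patient_id].append(make_evidence(
            rec.patient_id, rec.record_date, (rec.lvef,), "cart", rec.source_modality))
    for items in evidence.values():
        items.sort(key=lambda e: (e.event_date, e.provenance, e.values))
    return evidence


def dump_evidence_csv(evidence: dict[str, list[EvidenceItem]], path: str | Path) -> None:
    """Audit dump: one row per evidence item, including excluded ones."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "event_date", "provenance", "modality", "tier", "values"])
        for pid in sorted(evidence):
            for item in evidence[pid]:
                writer.writerow([
                    pid, item.event_date.isoformat(), item.provenance,
                    item.modality or "", item.tier,
                    ";".join(format(v, "g") for v in item.values)])
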