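"""Effective-LVEF selection: temporal windows, quality priority, multi-value logic.

Given a patient's tiered evidence, the current algorithm (v2) picks one
effective LVEF — or an "unspecified" verdict — as follows:

1. Restrict to non-excluded items dated within the lookback window
   (default 3 years, inclusive at both ends) ending at the as-of date.
   Nothing left → ``unspecified_no_data``.
2. If any high-tier item falls within the high-quality priority window
   (default 1 year), the candidates are the high-tier items on the most
   recent such date. Otherwise the candidates are the items on the most
   recent date in the lookback window; when high- and medium-tier items
   share that date, the medium ones are dropped.
3. Conflict check: if distinct single-valued candidate items on the
   chosen date individually imply both the reduced phenotype
   (<= 40) and the preserved phenotype (>= 50), the patient cannot be
   classified → ``unspecified_conflict``.
4. Pool all values across the candidates. One value → use it. Several →
   multi-value resolution: any value above the plausibility ceiling
   (default 75) → ``unspecified_implausible``; else if the spread
   between the highest and lowest value is <= 10 points use their
   average, otherwise use the highest value alone.

The legacy algorithm (v1) ignored quality entirely: the effective LVEF
was the minimum over every value of every item — excluded tiers
included — in the lookback window, with no multi-value or conflict
logic. Its failure mode (low outliers from nuclear and radiology
sources dragging preserved-EF patients into the reduced-EF class) is
what the hierarchy above was built to fix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from .hierarchy import EvidenceItem

__all__ = [
    "ClassificationConfig",
    "SelectionResult",
    "resolve_multi_value",
    "select_effective_lvef",
    "select_effective_lvef_v1",
    "years_before",
]

UNSPECIFIED_IMPLAUSIBLE = "unspecified_implausible"


def years_before(day: date, years: int) -> date:
    """Calendar anniversary ``years`` before ``day`` (Feb 29 maps to Feb 28)."""
    try:
        return day.replace(year=day.year - years)
    except ValueError:
        return day.replace(year=day.year - years, day=28)


@dataclass(frozen=True)
class ClassificationConfig:
    """All numeric knobs of the phenotyping cascade.

    Defaults: 3-year lookback, 1-year high-quality priority window,
    10-point multi-value averaging threshold, 75% plausibility ceiling,
    and phenotype boundaries at 40 (reduced) and 49 (mildly reduced).
    """

    as_of_date: date
    lookback_years: int = 3
    high_quality_priority_years: int = 1
    multi_value_avg_threshold: float = 10.0
    implausible_value_threshold: float = 75.0
    hfref_max: float = 40.0
    hfmref_max: float = 49.0

    def __post_init__(self) -> None:
        if not (0 < self.hfref_max < self.hfmref_max < 100):
            raise ValueError("need 0 < hfref_max < hfmref_max < 100")
        if self.high_quality_priority_years > self.lookback_years:
            raise ValueError("high_quality_priority_years must be <= lookback_years")

    @property
    def lookback_start(self) -> date:
        return years_before(self.as_of_date, self.lookback_years)

    @property
    def priority_start(self) -> date:
        return years_before(self.as_of_date, self.high_quality_priority_years)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ClassificationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "as_of_date" in data and isinstance(data["as_of_date"], str):
            data["as_of_date"] = date.fromisoformat(data["as_of_date"])
        data.update(overrides)
        return cls(**data)


@dataclass(frozen=True)
class SelectionResult:
    """One patient's selection outcome with a full audit trail."""

    patient_id: str
    effective_lvef: float | None
    verdict: str  # value | unspecified_conflict | unspecified_implausible | unspecified_no_data
    chosen_items: tuple[EvidenceItem, ...] = field(default=())
    rule_fired: str = ""

    def __post_init__(self) -> None:
        if (self.verdict == "value") != (self.effective_lvef is not None):
            raise ValueError("verdict 'value' iff effective_lvef present")


def resolve_multi_value(values: list[float] | tuple[float, ...],
                        cfg: ClassificationConfig) -> float | str:
    """Resolve several pooled LVEF values to one number or an implausibility verdict.

    Any value above the plausibility ceiling invalidates the set.
    Otherwise, spread (max - min) at most the averaging threshold →
    mean of min and max; larger spread → the high value alone.
    Symmetric in argument order.
    """
    if len(values) < 2:
        raise ValueError("resolve_multi_value requires at least 2 values")
    if any(v > cfg.implausible_value_threshold for v in values):
        return UNSPECIFIED_IMPLAUSIBLE
    hi, lo = max(values), min(values)
    if hi - lo <= cfg.multi_value_avg_threshold:
        return (hi + lo) / 2
    return hi


def _in_window(item: EvidenceItem, start: date, end: date) -> bool:
    return start <= item.event_date <= end


def select_effective_lvef(evidence: list[EvidenceItem],
                          cfg: ClassificationConfig,
                          patient_id: str | None = None) -> SelectionResult:
    """Current-algorithm selection (quality hierarchy + temporal windows)."""
    pid = patient_id or (evidence[0].patient_id if evidence else "")
    usable = [e for e in evidence
              if e.tier != "excluded" and _in_window(e, cfg.lookback_start, cfg.as_of_date)]
    if not usable:
        return SelectionResult(pid, None, "unspecified_no_data", (), "no_usable_evidence")

    priority_high = [e for e in usable
                     if e.tier == "high" and _in_window(e, cfg.priority_start, cfg.as_of_date)]
    if priority_high:
        chosen_date = max(e.event_date for e in priority_high)
        candidates = [e for e in priority_high if e.event_date == chosen_date]
        rule = "high_quality_within_priority_window"
    else:
        chosen_date = max(e.event_date for e in usable)
        same_day = [e for e in usable if e.event_date == chosen_date]
        highs = [e for e in same_day if e.tier == "high"]
        candidates = highs if highs else same_day
        rule = "most_recent_in_lookback"

    # Conflict: distinct single-valued studies on the chosen date that
    # individually imply both a reduced and a preserved phenotype.
    singles = [e.values[0] for e in candidates if len(e.values) == 1]
    if (any(v <= cfg.hfref_max for v in singles)
            and any(v >= cfg.hfmref_max + 1 for v in singles)):
        return SelectionResult(pid, None, "unspecified_conflict",
                               tuple(candidates), rule + ";same_date_conflict")

    pooled = [v for e in candidates for v in e.values]
    if len(pooled) == 1:
        return SelectionResult(pid, pooled[0], "value", tuple(candidates),
                               rule + ";single_value")
    resolved = resolve_multi_value(pooled, cfg)
    if resolved == UNSPECIFIED_IMPLAUSIBLE:
        return SelectionResult(pid, None, UNSPECIFIED_IMPLAUSIBLE,
                               tuple(candidates), rule + ";implausible_value")
    spread_rule = ("multi_value_average"
                   if max(pooled) - min(pooled) <= cfg.multi_value_avg_threshold
                   else "multi_value_high")
    return SelectionResult(pid, float(resolved), "value", tuple(candidates),
                           rule + ";" + spread_rule)


def select_effective_lvef_v1(evidence: list[EvidenceItem],
                             cfg: ClassificationConfig,
                             patient_id: str | None = None) -> SelectionResult:
    """Legacy selection: lowest LVEF from any source (any tier) in the lookback window."""
    pid = patient_id or (evidence[0].patient_id if evidence else "")
    in_window = [e for e in evidence if _in_window(e, cfg.lookback_start, cfg.as_of_date)]
    if not in_window:
        return SelectionResult(pid, None, "unspecified_no_data", (), "no_evidence_in_window")
    lowest = min(v for e in in_window for v in e.values)
    chosen = tuple(e for e in in_window if lowest in e.values)
    return SelectionResult(pid, lowest, "value", chosen, "lowest_any_source")


def dump_selection_csv(results: dict[str, SelectionResult], path: str | Path) -> None:
    """Audit dump of per-patient selection outcomes."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "verdict", "effective_lvef", "rule_fired",
                         "evidence_dates", "evidence_provenances"])
        for pid in sorted(results):
            r = results[pid]
            writer.writerow([
                pid, r.verdict,
                "" if r.effective_lvef is None else format(r.effective_lvef, "g"),
                r.rule_fired,
                ";".join(e.event_date.isoformat() for e in r.chosen_items),
                ";".join(e.provenance for e in r.chosen_items)])
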