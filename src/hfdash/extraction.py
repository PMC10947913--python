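"""Deterministic pattern-based extraction of ejection-fraction mentions.

Free-text imaging reports state the left ventricular ejection fraction
(LVEF) in many surface forms: "LVEF is 35%", "EF 50-55%", "ejection
fraction 0.40". This module extracts every numeric EF value from one
report into a single :class:`LvefMention`, preserving order, so the
downstream multi-value resolution logic can handle reports that state
more than one number.

Rules:

* a range ``X-Y%`` (hyphen, en-dash, or "to") yields both endpoints;
* fraction-style values in (0, 1] are rescaled by 100;
* qualitative wording without a number ("normal LV systolic function")
  yields no mention — no word-to-number mapping is invented;
* mentions in a non-cardiac context (e.g. a gallbladder ejection
  fraction in an abdominal imaging report) are flagged ``non_cardiac``
  and carry their values for audit, but are never treated as LV data;
* values outside (0, 100] after normalization are discarded with a
  warning.

Patterns are configurable via YAML (:class:`PatternConfig`) so sites
with different report conventions can extend them.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import yaml

from .model import ImagingReport

__all__ = ["LvefMention", "PatternConfig", "extract_lvef", "fuzz_reports"]

logger = logging.getLogger(__name__)

_DEFAULT_LV_CONTEXT = [
    r"\bLVEF\b",
    r"\bleft\s+ventricular\s+ejection\s+fraction\b",
    r"\bLV\s+ejection\s+fraction\b",
    r"\bejection\s+fraction\b",
    r"\bEF\b",
]
_DEFAULT_NON_CARDIAC_CONTEXT = [
    r"\bgall[\s-]?bladder\b",
    r"\bright\s+ventricular\b",
    r"\bRVEF\b",
]
_NUMBER = r"\d{1,3}(?:\.\d+)?"
_DEFAULT_VALUE = [rf"({_NUMBER})\s*%?"]
_DEFAULT_RANGE = [rf"({_NUMBER})\s*(?:-|–|—|to)\s*({_NUMBER})\s*%?"]

# filler tolerated between the EF phrase and its number
_CONNECTOR = r"(?:\s*(?:is|was|of|at|:|=|~|approximately|estimated\s+(?:at|to\s+be)|measured\s+at)\s*|\s+)?"


@dataclass
class PatternConfig:
    """Regular-expression bank for EF extraction, loadable from YAML."""

    lv_context: list[str] = field(default_factory=lambda: list(_DEFAULT_LV_CONTEXT))
    value: list[str] = field(default_factory=lambda: list(_DEFAULT_VALUE))
    range: list[str] = field(default_factory=lambda: list(_DEFAULT_RANGE))
    non_cardiac_context: list[str] = field(
        default_factory=lambda: list(_DEFAULT_NON_CARDIAC_CONTEXT))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PatternConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {k: list(v) for k, v in data.items() if k in
                  ("lv_context", "value", "range", "non_cardiac_context")}
        unknown = set(data) - set(kwargs)
        if unknown:
            raise ValueError(f"unknown pattern keys in {path}: {sorted(unknown)}")
        return cls(**kwargs)

    def compiled(self):
        flags = re.IGNORECASE
        return (
            re.compile("|".join(f"(?:{p})" for p in self.lv_context), flags),
            [re.compile(p, flags) for p in self.range],
            [re.compile(p, flags) for p in self.value],
            re.compile("|".join(f"(?:{p})" for p in self.non_cardiac_context), flags),
        )


@dataclass(frozen=True)
class LvefMention:
    """All EF values found in one report, with provenance snippets.

    ``non_cardiac`` marks mentions whose context refers to an ejection
    fraction that is not the left ventricle's.
    """

    report_id: str
    values: tuple[float, ...]
    raw_spans: tuple[str, ...]
    non_cardiac: bool = False

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("LvefMention requires at least one value")
        for v in self.values:
            if not (0 < v <= 100):
                raise ValueError(f"EF value {v} outside (0, 100]")


def _normalize_value(raw: float, report_id: str) -> float | None:
    # round after rescaling so 0.29 -> 29 exactly, not 28.999999999999996
    v = round(raw * 100, 6) if 0 < raw <= 1 else raw
    if not (0 < v <= 100):
        logger.warning("report %s: EF value %s outside (0, 100] after normalization; discarded",
                       report_id, raw)
        return None
    return v


def extract_lvef(report: ImagingReport,
                 patterns: PatternConfig | None = None) -> LvefMention | None:
    """Extract all EF values from one report, or None if no EF phrase matches.

    Pure function of ``(report.text, patterns)``. If the report contains
    both cardiac and non-cardiac EF phrases, the cardiac values win and
    the non-cardiac ones are ignored; a report with only non-cardiac EF
    phrases yields a mention flagged ``non_cardiac=True``.
    """
    patterns = patterns or PatternConfig()
    ctx_re, range_res, value_res, noncardiac_re = patterns.compiled()

    cardiac_vals: list[float] = []
    cardiac_spans: list[str] = []
    noncardiac_vals: list[float] = []
    noncardiac_spans: list[str] = []

    for m in ctx_re.finditer(report.text):
        tail = report.text[m.end():]
        conn = re.match(_CONNECTOR, tail, re.IGNORECASE)
        offset = conn.end() if conn else 0
        candidate = tail[offset:]
        numbers: list[float] = []
        span_end = m.end()
        for rng in range_res:
            rm = rng.match(candidate)
            if rm:
                numbers = [float(g) for g in rm.groups() if g is not None]
                span_end = m.end() + offset + rm.end()
                break
        if not numbers:
            for val in value_res:
                vm = val.match(candidate)
                if vm:
                    numbers = [float(vm.group(1))]
                    span_end = m.end() + offset + vm.end()
                    break
        if not numbers:
            continue
        window_start = max(0, m.start() - 40)
        is_non_cardiac = bool(noncardiac_re.search(report.text[window_start:m.start() + 1]))
        span = report.text[m.start():span_end]
        for raw in numbers:
            norm = _normalize_value(raw, report.report_id)
            if norm is None:
                continue
            if is_non_cardiac:
                noncardiac_vals.append(norm)
                noncardiac_spans.append(span)
            else:
                cardiac_vals.append(norm)
                cardiac_spans.append(span)

    if cardiac_vals:
        return LvefMention(report.report_id, tuple(cardiac_vals), tuple(cardiac_spans), False)
    if noncardiac_vals:
        return LvefMention(report.report_id, tuple(noncardiac_vals), tuple(noncardiac_spans), True)
    return None


# ---------------------------------------------------------------------------
# Template bank — shared with the synthetic-cohort generator so that every
# generated report is parseable by the extractor above.

SINGLE_TEMPLATES = [
    "LVEF is {v}%.",
    "The left ventricular ejection fraction is {v}%.",
    "LV ejection fraction estimated at {v}%.",
    "Ejection fraction of {v}%.",
    "EF {v}%.",
    "Conclusion: LVEF {v}%. No pericardial effusion.",
]
RANGE_TEMPLATES = [
    "EF {lo}-{hi}%.",
    "LVEF {lo}-{hi}%.",
    "Ejection fraction {lo} to {hi}%.",
    "Visually estimated LVEF {lo}–{hi}%.",
]
FRACTION_TEMPLATES = [
    "Ejection fraction {f:.2f}.",
    "LVEF {f:.2f} by biplane method.",
]
QUALITATIVE_TEMPLATES = [
    "Normal LV systolic function.",
    "Mildly reduced left ventricular systolic function.",
    "Technically limited study; LV function not quantified.",
]
NON_CARDIAC_TEMPLATES = [
    "Gallbladder ejection fraction of {v}%.",
    "HIDA scan: gallbladder ejection fraction {v}%, within normal limits.",
]


def render_single(rng: random.Random, value: float) -> str:
    return rng.choice(SINGLE_TEMPLATES).format(v=format(value, "g"))


def render_range(rng: random.Random, lo: float, hi: float) -> str:
    return rng.choice(RANGE_TEMPLATES).format(lo=format(lo, "g"), hi=format(hi, "g"))


def render_non_cardiac(rng: random.Random, value: float) -> str:
    return rng.choice(NON_CARDIAC_TEMPLATES).format(v=format(value, "g"))


def fuzz_reports(n: int, seed: int) -> list[tuple[ImagingReport, LvefMention | None]]:
    """Generate ``n`` (report, expected mention) pairs for extractor testing.

    Deterministic for a seed. Covers single values, ranges (all
    separators), decimal fractions, qualitative-only text (expected
    None), and non-cardiac gallbladder decoys.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out: list[tuple[ImagingReport, LvefMention | None]] = []
    base = date(2022, 1, 1)
    for i in range(n):
        rid = f"FZ{i:05d}"
        report_date = base + timedelta(days=rng.randrange(365))
        kind = rng.choice(["single", "single", "range", "fraction", "qualitative", "non_cardiac"])
        if kind == "single":
            v = float(rng.randrange(5, 81))
            text = render_single(rng, v)
            expected_vals: tuple[float, ...] | None = (v,)
            non_cardiac = False
        elif kind == "range":
            lo = float(rng.randrange(10, 70))
            hi = lo + rng.randrange(1, 21)
            text = render_range(rng, lo, hi)
            expected_vals = (lo, hi)
            non_cardiac = False
        elif kind == "fraction":
            f = rng.randrange(10, 76) / 100
            text = rng.choice(FRACTION_TEMPLATES).format(f=f)
            expected_vals = (round(f * 100, 6),)
            non_cardiac = False
        elif kind == "qualitative":
            text = rng.choice(QUALITATIVE_TEMPLATES)
            expected_vals = None
            non_cardiac = False
        else:
            v = float(rng.randrange(35, 99))
            text = render_non_cardiac(rng, v)
            expected_vals = (v,)
            non_cardiac = True
        source = "radiology" if kind == "non_cardiac" else rng.choice(["echo", "clinical_note"])
        report = ImagingReport(
            report_id=rid, patient_id="PFUZZ", report_date=report_date,
            source_system=source, modality_hint=None, text=text)
        if expected_vals is None:
            out.append((report, None))
        else:
            # Expected mentions are built from the values embedded in the
            # template, never by running the extractor; raw_spans are an
            # extractor detail and are left empty here (compare with
            # ``mentions_agree``).
            out.append((report, LvefMention(rid, expected_vals, (), non_cardiac)))
    return out


def mentions_agree(found: LvefMention | None, expected: LvefMention | None) -> bool:
    """Exact agreement on report, values and cardiac/non-cardiac flag.

    ``raw_spans`` carry audit snippets and are not part of the contract.
    """
    if found is None or expected is None:
        return found is None and expected is None
    return (found.report_id == expected.report_id
            and found.values == expected.values
            and found.non_cardiac == expected.non_cardiac)
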