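"""Brute-force reference for effective-LVEF selection.

An intentionally plain enumeration of the rule cascade, written
independently of the package's implementation so the two can be
compared on random evidence sets. Keep this file boring: no shared
helpers with hfdash.selection beyond the config and data types.
"""

from __future__ import annotations

from hfdash.hierarchy import EvidenceItem
from hfdash.selection import ClassificationConfig


def oracle_v2(evidence: list[EvidenceItem], cfg: ClassificationConfig):
    """Returns (verdict, effective_lvef_or_None)."""
    lookback_start = cfg.lookback_start
    priority_start = cfg.priority_start

    usable = []
    for item in evidence:
        if item.tier == "excluded":
            continue
        if item.event_date < lookback_start or item.event_date > cfg.as_of_date:
            continue
        usable.append(item)
    if len(usable) == 0:
        return ("unspecified_no_data", None)

    recent_high = []
    for item in usable:
        if item.tier == "high" and item.event_date >= priority_start:
            recent_high.append(item)

    if len(recent_high) > 0:
        best_date = None
        for item in recent_high:
            if best_date is None or item.event_date > best_date:
                best_date = item.event_date
        candidates = [i for i in recent_high if i.event_date == best_date]
    else:
        best_date = None
        for item in usable:
            if best_date is None or item.event_date > best_date:
                best_date = item.event_date
        same_day = [i for i in usable if i.event_date == best_date]
        high_same_day = [i for i in same_day if i.tier == "high"]
        candidates = high_same_day if len(high_same_day) > 0 else same_day

    saw_reduced = False
    saw_preserved = False
    for item in candidates:
        if len(item.values) == 1:
            v = item.values[0]
            if v <= cfg.hfref_max:
                saw_reduced = True
            if v >= cfg.hfmref_max + 1:
                saw_preserved = True
    if saw_reduced and saw_preserved:
        return ("unspecified_conflict", None)

    pooled = []
    for item in candidates:
        for v in item.values:
            pooled.append(v)
    if len(pooled) == 1:
        return ("value", pooled[0])
    for v in pooled:
        if v > cfg.implausible_value_threshold:
            return ("unspecified_implausible", None)
    high = max(pooled)
    low = min(pooled)
    if high - low <= cfg.multi_value_avg_threshold:
        return ("value", (high + low) / 2)
    return ("value", high)


def oracle_v1(evidence: list[EvidenceItem], cfg: ClassificationConfig):
    """Legacy rule: lowest value from any study of any tier in the lookback window."""
    lowest = None
    for item in evidence:
        if item.event_date < cfg.lookback_start or item.event_date > cfg.as_of_date:
            continue
        for v in item.values:
            if lowest is None or v < lowest:
                lowest = v
    if lowest is None:
        return ("unspecified_no_data", None)
    return ("value", lowest)
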