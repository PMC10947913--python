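"""Diagnostic-accuracy evaluation against gold-standard labels.

Each phenotype is evaluated one-vs-rest: the class in turn is the
positive label, everything else negative. From the TP/FP/TN/FN counts:

* sensitivity = 100 * TP / (TP + FN)
* specificity = 100 * TN / (TN + FP)
* accuracy    = 100 * (TP + TN) / (TP + FP + TN + FN)
* PPV         = 100 * TP / (TP + FP)
* NPV         = 100 * TN / (TN + FN)

A zero denominator leaves the metric undefined (None) rather than 0.

``compare_versions`` runs both algorithm generations on one cohort and
tabulates per-class summaries side by side. By default only patients
the algorithm actually classified (included, non-unspecified) enter the
confusion counts; ``population="all_included"`` instead counts
unspecified predictions as negative for every class.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hierarchy import EvidenceItem
from .model import Cohort
from .phenotyping import (HfCodeConfig, PhenotypeResult, phenotype_cohort)
from .selection import ClassificationConfig

__all__ = ["ConfusionSummary", "confusion", "evaluate_predictions", "compare_versions"]

CLASSES = ("HFrEF", "HFmrEF", "HFpEF")


@dataclass(frozen=True)
class ConfusionSummary:
    """One-vs-rest counts and derived metrics for one phenotype class."""

    positive_class: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "class": self.positive_class, "TP": self.tp, "FP": self.fp,
            "TN": self.tn, "FN": self.fn, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "ppv": self.ppv, "npv": self.npv,
        }


def confusion(gold: dict[str, str], predicted: dict[str, str],
              positive_class: str) -> ConfusionSummary:
    """One-vs-rest confusion for ``positive_class`` over matching patient sets."""
    if set(gold) != set(predicted):
        missing = set(gold) ^ set(predicted)
        raise ValueError(f"gold and predicted patient sets differ: {sorted(missing)[:5]} ...")
    tp = fp = tn = fn = 0
    for pid, g in gold.items():
        p = predicted[pid]
        if p == positive_class:
            if g == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if g == positive_class:
                fn += 1
            else:
                tn += 1
    return ConfusionSummary(positive_class, tp, fp, tn, fn)


def evaluate_predictions(gold: dict[str, str],
                         results: dict[str, PhenotypeResult],
                         population: str = "classified_only",
                         classes: tuple[str, ...] = CLASSES) -> dict[str, ConfusionSummary]:
    """Per-class one-vs-rest summaries of one algorithm run against gold labels.

    ``classified_only`` drops patients the algorithm left unspecified or
    excluded; ``all_included`` keeps unspecified predictions (they count
    as negative for every class).
    """
    if population not in ("classified_only", "all_included"):
        raise ValueError(f"unknown population {population!r}")
    predicted: dict[str, str] = {}
    for pid, r in results.items():
        if not r.included or pid not in gold:
            continue
        if population == "classified_only" and r.phenotype == "unspecified":
            continue
        predicted[pid] = r.phenotype
    sub_gold = {pid: gold[pid] for pid in predicted}
    return {c: confusion(sub_gold, predicted, c) for c in classes}


def compare_versions(cohort: Cohort,
                     evidence: dict[str, list[EvidenceItem]],
                     gold: dict[str, str],
                     cfg: ClassificationConfig,
                     codes: HfCodeConfig | None = None,
                     population: str = "classified_only") -> pd.DataFrame:
    """Run both algorithm generations and tabulate per-class metrics plus deltas.

    Returns a tidy frame: version, class, TP/FP/TN/FN, the five metrics;
    v2 - v1 metric deltas appear as version == "delta".
    """
    rows = []
    summaries: dict[str, dict[str, ConfusionSummary]] = {}
    for version in ("v1", "v2"):
        results = phenotype_cohort(cohort, evidence, cfg, version=version, codes=codes)
        summaries[version] = evaluate_predictions(gold, results, population=population)
        for c, s in summaries[version].items():
            rows.append({"version": version, **s.as_dict()})
    for c in CLASSES:
        s1, s2 = summaries["v1"][c], summaries["v2"][c]
        delta = {"version": "delta", "class": c, "TP": s2.tp - s1.tp,
                 "FP": s2.fp - s1.fp, "TN": s2.tn - s1.tn, "FN": s2.fn - s1.fn}
        for metric in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            a, b = getattr(s1, metric), getattr(s2, metric)
            delta[metric] = None if a is None or b is None else b - a
        rows.append(delta)
    return pd.DataFrame(rows, columns=["version", "class", "TP", "FP", "TN", "FN",
                                       "sensitivity", "specificity", "accuracy",
                                       "ppv", "npv"])
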