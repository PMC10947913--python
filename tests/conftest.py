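from __future__ import annotations

import random
from datetime import date, timedelta

import pytest
from hypothesis import settings

settings.register_profile("derandomized", deadline=None, derandomize=True)
settings.load_profile("derandomized")

from hfdash.hierarchy import EvidenceItem, assign_tier
from hfdash.selection import ClassificationConfig

AS_OF = date(2023, 6, 30)


@pytest.fixture
def cfg() -> ClassificationConfig:
    return ClassificationConfig(as_of_date=AS_OF)


def ev(days_ago: int, *values: float, provenance: str = "nlp_echo",
       modality: str | None = "TTE", patient_id: str = "P1") -> EvidenceItem:
    """Shorthand evidence-item builder used across the test suite."""
    if provenance == "nlp_echo" and modality not in ("TTE", "TEE"):
        modality = "TTE"
    return EvidenceItem(
        patient_id=patient_id,
        event_date=AS_OF - timedelta(days=days_ago),
        values=tuple(float(v) for v in values),
        provenance=provenance,
        modality=modality,
        tier=assign_tier(provenance, modality, len(values)),
    )


def random_evidence_set(rng: random.Random, max_items: int = 6) -> list[EvidenceItem]:
    """Random evidence spanning both temporal windows and every tier."""
    items = []
    for _ in range(rng.randint(0, max_items)):
        kind = rng.choice(["nlp_echo", "nlp_note", "nlp_radiology", "cart"])
        if kind == "cart":
            modality = rng.choice(["TTE", "TEE", "MRI", "CT", "ventriculography", "nuclear"])
            n_vals = 1
        else:
            modality = rng.choice(["TTE", "TEE", None])
            n_vals = rng.choice([1, 1, 1, 2, 3]) if kind == "nlp_echo" else 1
        values = tuple(float(rng.randint(5, 90)) for _ in range(n_vals))
        # span from inside the 1-year window to beyond the 3-year lookback
        days_ago = rng.randint(0, 4 * 366)
        items.append(ev(days_ago, *values, provenance=kind, modality=modality))
    return items
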