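from __future__ import annotations

import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import AS_OF, ev, random_evidence_set
from hfdash.selection import (ClassificationConfig, resolve_multi_value,
                              select_effective_lvef, select_effective_lvef_v1,
                              years_before)
from oracle_selection import oracle_v1, oracle_v2


class TestResolveMultiValue:
    @pytest.mark.parametrize("values,expected", [
        ([55, 60], 57.5),          # spread 5 <= 10 -> average of extremes
        ([20, 35], 35),            # spread 15 > 10 -> high value alone
        ([40, 40], 40),            # zero spread
        ([30, 35, 38], 34.0),      # >=3 values: extremes are max and min
        ([20, 28, 40], 40),
    ])
    def test_rules(self, values, expected, cfg):
        assert resolve_multi_value(values, cfg) == expected

    @pytest.mark.parametrize("values", [[80, 60], [20, 76], [76, 77]])
    def test_implausible_value_wins(self, values, cfg):
        assert resolve_multi_value(values, cfg) == "unspecified_implausible"

    def test_requires_two_values(self, cfg):
        with pytest.raises(ValueError):
            resolve_multi_value([40], cfg)

    @given(st.lists(st.floats(min_value=1, max_value=100, allow_nan=False),
                    min_size=2, max_size=6))
    @settings(deadline=None)
    def test_symmetric_in_argument_order(self, values):
        cfg = ClassificationConfig(as_of_date=AS_OF)
        assert resolve_multi_value(values, cfg) == resolve_multi_value(values[::-1], cfg)


class TestSelectV2:
    def test_high_within_priority_window_beats_newer_medium(self, cfg):
        evidence = [ev(180, 30), ev(30, 55, provenance="nlp_note", modality=None)]
        result = select_effective_lvef(evidence, cfg)
        assert result.effective_lvef == 30
        assert result.rule_fired.startswith("high_quality_within_priority_window")

    def test_most_recent_used_when_no_recent_high(self, cfg):
        result = select_effective_lvef([ev(2 * 365, 62)], cfg)
        assert result.effective_lvef == 62
        assert result.rule_fired.startswith("most_recent_in_lookback")

    def test_same_day_reduced_vs_preserved_is_conflict(self, cfg):
        evidence = [ev(100, 30),
                    ev(100, 55, provenance="cart", modality="TTE")]
        result = select_effective_lvef(evidence, cfg)
        assert result.verdict == "unspecified_conflict"
        assert result.effective_lvef is None

    def test_adjacent_classes_same_day_pool_instead_of_conflict(self, cfg):
        # reduced vs mildly-reduced disagreement is not a conflict
        evidence = [ev(100, 38), ev(100, 45, provenance="cart", modality="TTE")]
        result = select_effective_lvef(evidence, cfg)
        assert result.verdict == "value"
        assert result.effective_lvef == 41.5

    def test_old_evidence_only_is_no_data(self, cfg):
        result = select_effective_lvef([ev(4 * 365, 40)], cfg)
        assert result.verdict == "unspecified_no_data"

    def test_excluded_tier_invisible(self, cfg):
        evidence = [ev(10, 20, provenance="nlp_radiology", modality=None)]
        assert select_effective_lvef(evidence, cfg).verdict == "unspecified_no_data"

    def test_same_date_high_preferred_over_medium_outside_priority_window(self, cfg):
        evidence = [ev(2 * 365, 60, provenance="cart", modality="TTE"),
                    ev(2 * 365, 30, provenance="nlp_note", modality=None)]
        result = select_effective_lvef(evidence, cfg)
        assert result.effective_lvef == 60
        assert all(item.tier == "high" for item in result.chosen_items)

    def test_multi_value_item_resolved(self, cfg):
        result = select_effective_lvef([ev(30, 50, 55)], cfg)
        assert result.effective_lvef == 52.5


class TestWindowBoundaries:
    def test_lookback_boundary_inclusive(self, cfg):
        boundary = years_before(AS_OF, cfg.lookback_years)
        item_in = ev((AS_OF - boundary).days, 42)
        assert select_effective_lvef([item_in], cfg).effective_lvef == 42

    def test_one_day_older_is_out(self, cfg):
        boundary = years_before(AS_OF, cfg.lookback_years) - timedelta(days=1)
        item_out = ev((AS_OF - boundary).days, 42)
        assert select_effective_lvef([item_out], cfg).verdict == "unspecified_no_data"

    def test_priority_window_boundary_inclusive(self, cfg):
        days = (AS_OF - years_before(AS_OF, 1)).days
        evidence = [ev(days, 30), ev(days - 100, 60, provenance="nlp_note",
                                     modality=None)]
        result = select_effective_lvef(evidence, cfg)
        assert result.effective_lvef == 30

    def test_leap_day_anniversary(self):
        cfg = ClassificationConfig(as_of_date=date(2024, 2, 29))
        assert cfg.lookback_start == date(2021, 2, 28)


class TestSelectV1:
    def test_lowest_from_any_source_any_tier(self, cfg):
        evidence = [ev(30, 55),
                    ev(300, 38, provenance="nlp_radiology", modality=None)]
        assert select_effective_lvef_v1(evidence, cfg).effective_lvef == 38

    def test_single_item(self, cfg):
        assert select_effective_lvef_v1([ev(10, 60)], cfg).effective_lvef == 60

    def test_empty_window(self, cfg):
        assert select_effective_lvef_v1([], cfg).verdict == "unspecified_no_data"

    def test_adding_evidence_never_raises_v1_estimate(self, cfg):
        rng = random.Random(5)
        for _ in range(200):
            base = random_evidence_set(rng)
            extra = base + random_evidence_set(rng, max_items=2)
            r_base = select_effective_lvef_v1(base, cfg)
            r_more = select_effective_lvef_v1(extra, cfg)
            if r_base.verdict == "value" and r_more.verdict == "value":
                assert r_more.effective_lvef <= r_base.effective_lvef


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_v2_matches_bruteforce(self, seed, cfg):
        rng = random.Random(seed)
        for _ in range(400):
            evidence = random_evidence_set(rng)
            got = select_effective_lvef(evidence, cfg, patient_id="P1")
            verdict, value = oracle_v2(evidence, cfg)
            assert (got.verdict, got.effective_lvef) == (verdict, value)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_v1_matches_bruteforce(self, seed, cfg):
        rng = random.Random(seed + 100)
        for _ in range(400):
            evidence = random_evidence_set(rng)
            got = select_effective_lvef_v1(evidence, cfg, patient_id="P1")
            assert (got.verdict, got.effective_lvef) == oracle_v1(evidence, cfg)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        ClassificationConfig(as_of_date=AS_OF, hfref_max=50, hfmref_max=45)
    with pytest.raises(ValueError):
        ClassificationConfig(as_of_date=AS_OF, lookback_years=1,
                             high_quality_priority_years=2)


def test_config_yaml_loading(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("as_of_date: '2023-06-30'\nlookback_years: 2\n")
    cfg = ClassificationConfig.from_yaml(path)
    assert cfg.as_of_date == AS_OF
    assert cfg.lookback_years == 2
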