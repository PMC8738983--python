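"""Timing-window semantics of the per-event adherence classifier."""

import pytest
from hypothesis import given, settings, strategies as st

from prepdiary.adherence import (
    AdherenceConfig,
    check_daily,
    check_ed,
    classify_diary,
    classify_event,
    merge_doses,
)
from prepdiary.diary_model import AdherenceLabel, Diary, DoseLog, Regimen

from conftest import T0, dose, make_event

CFG = AdherenceConfig()
EVENT = make_event()


# ---------------------------------------------------------------- daily rule

@pytest.mark.parametrize(
    "offsets, expected",
    [
        ([-150, -120, -96, -48], True),        # 4 pills inside the week
        ([-150, -120, -96], False),            # only 3
        ([], False),                           # no doses
        ([-168, -120, -96, -48], True),        # boundary pill at exactly -168h counts
        ([-168.02, -120, -96, -48], False),    # just outside the lookback
        ([-150, -120, -96, 0], False),         # pill at the event time is not "before"
    ],
)
def test_daily_rule_window(offsets, expected):
    doses = [dose(h) for h in offsets]
    assert check_daily(T0, doses, CFG) is expected


def test_daily_rule_counts_pills_not_logs():
    # two 2-pill logs = 4 pills
    doses = [dose(-100, pills=2), dose(-50, pills=2)]
    assert check_daily(T0, doses, CFG)


@given(st.lists(st.floats(min_value=-167.9, max_value=-0.1), min_size=0, max_size=10),
       st.floats(min_value=-167.9, max_value=-0.1))
@settings(max_examples=100, deadline=None)
def test_daily_rule_monotone_in_added_pills(offsets, extra):
    """Adding a pill inside the lookback never revokes the daily rule."""
    doses = [dose(h) for h in offsets]
    before = check_daily(T0, doses, CFG)
    after = check_daily(T0, doses + [dose(extra)], CFG)
    assert after >= before


# ----------------------------------------------------------------- ED rule

def test_ed_x_hours_scenario():
    # 2 pills 10h before sex; follow-up pills 24h and 48h after the pre-dose
    doses = [dose(-10, pills=2), dose(14), dose(38)]
    assert check_ed(T0, doses, CFG)


def test_ed_single_pre_exception():
    # 1-pill pre-dose allowed because another pill was taken 30h before sex
    doses = [dose(-10), dose(-30), dose(14), dose(38)]
    assert check_ed(T0, doses, CFG)


def test_ed_single_pre_without_backup_fails():
    doses = [dose(-10), dose(14), dose(38)]
    assert not check_ed(T0, doses, CFG)


def test_ed_missing_post_doses_fails():
    assert not check_ed(T0, [dose(-10, pills=2)], CFG)


def test_ed_missing_second_post_fails():
    assert not check_ed(T0, [dose(-10, pills=2), dose(14)], CFG)


@pytest.mark.parametrize(
    "x_hours, expected",
    [(2.0, True), (24.0, True), (1.0 + 59 / 60, False), (24.0 + 1 / 60, False)],
)
def test_ed_pre_window_boundaries_closed(x_hours, expected):
    doses = [dose(-x_hours, pills=2), dose(-x_hours + 24), dose(-x_hours + 48)]
    assert check_ed(T0, doses, CFG) is expected


@pytest.mark.parametrize(
    "b_off, c_off, expected",
    [
        (22, 46, True), (26, 50, True),       # window edges included
        (21.98, 48, False), (26.02, 48, False),  # first follow-up outside
        (24, 45.98, False), (24, 50.02, False),  # second follow-up outside
    ],
)
def test_ed_post_window_boundaries_closed(b_off, c_off, expected):
    x = 10
    doses = [dose(-x, pills=2), dose(-x + b_off), dose(-x + c_off)]
    assert check_ed(T0, doses, CFG) is expected


def test_ed_double_dose_merge():
    # two 1-pill logs 30 minutes apart act as the 2-pill pre-dose
    doses = [dose(-10), dose(-9.5), dose(14), dose(38)]
    assert check_ed(T0, doses, CFG)
    # 70 minutes apart: not merged, and no backup pill for the single-pre rule
    doses = [dose(-10), dose(-10 - 70 / 60), dose(14), dose(38)]
    assert not check_ed(T0, doses, CFG)


def test_merge_uses_earliest_time_and_only_single_pill_logs():
    doses = [DoseLog("p", 100, 1), DoseLog("p", 130, 1), DoseLog("p", 500, 2)]
    merged = merge_doses(doses, 60)
    assert [(m.time, m.pills) for m in merged] == [(100, 2), (500, 2)]


def test_ed_follow_up_pills_must_be_distinct_from_pre_dose():
    # the same merged cluster cannot double as pre-dose and follow-up
    doses = [dose(-10, pills=2)]
    assert not check_ed(T0, doses, CFG)


# ------------------------------------------------------------ classification

def test_classify_daily_only():
    doses = [dose(h) for h in (-150, -120, -96, -48)]
    assert classify_event(EVENT, doses, CFG) is AdherenceLabel.CORRECT_DAILY


def test_classify_ed_only():
    doses = [dose(-10, pills=2), dose(14), dose(38)]
    assert classify_event(EVENT, doses, CFG) is AdherenceLabel.CORRECT_ED


def test_classify_neither_is_incorrect():
    assert classify_event(EVENT, [dose(-30)], CFG) is AdherenceLabel.INCORRECT
    assert classify_event(EVENT, [], CFG) is AdherenceLabel.INCORRECT


def test_classify_both_pass_uses_declared_regimen():
    both = [
        dose(-150, regimen=Regimen.DAILY),
        dose(-120, regimen=Regimen.DAILY),
        dose(-96, regimen=Regimen.DAILY),
        dose(-10, pills=2, regimen=Regimen.EVENT_DRIVEN),
        dose(14, regimen=Regimen.EVENT_DRIVEN),
        dose(38, regimen=Regimen.EVENT_DRIVEN),
    ]
    assert check_daily(T0, both, CFG) and check_ed(T0, both, CFG)
    assert classify_event(EVENT, both, CFG) is AdherenceLabel.CORRECT_ED
    # most recent dose before the event declared DAILY -> daily wins
    daily_latest = both[:4] + [
        dose(-5, regimen=Regimen.DAILY),
        dose(14, regimen=Regimen.EVENT_DRIVEN),
        dose(38, regimen=Regimen.EVENT_DRIVEN),
    ]
    assert classify_event(EVENT, daily_latest, CFG) is AdherenceLabel.CORRECT_DAILY
    # UNKNOWN declared regimen falls back to daily
    unknown = [dose(h, regimen=Regimen.UNKNOWN) for h in (-150, -120, -96)] + [
        dose(-10, pills=2, regimen=Regimen.UNKNOWN),
        dose(14, regimen=Regimen.UNKNOWN),
        dose(38, regimen=Regimen.UNKNOWN),
    ]
    assert classify_event(EVENT, unknown, CFG) is AdherenceLabel.CORRECT_DAILY
    forced = AdherenceConfig(both_pass_precedence="ed")
    assert classify_event(EVENT, unknown, forced) is AdherenceLabel.CORRECT_ED


def test_classification_partition_is_exhaustive(rng):
    """Every random dose configuration receives exactly one of three labels."""
    for _ in range(200):
        doses = [dose(float(h), pills=int(p)) for h, p in zip(
            rng.uniform(-170, 60, size=rng.integers(0, 8)),
            rng.integers(1, 3, size=8),
        )]
        assert classify_event(EVENT, doses, CFG) in AdherenceLabel


def test_classify_diary_order_invariance(tiny_diary, rng):
    base = classify_diary(tiny_diary, CFG)
    for _ in range(5):
        shuffled = list(tiny_diary.dose_logs)
        rng.shuffle(shuffled)
        d = Diary(participants=tiny_diary.participants,
                  dose_logs=shuffled, sex_events=tiny_diary.sex_events)
        assert classify_diary(d, CFG) == base


def test_classify_diary_zero_doses_all_incorrect(tiny_diary):
    d = Diary(participants=tiny_diary.participants, dose_logs=[],
              sex_events=tiny_diary.sex_events)
    assert set(classify_diary(d, CFG).values()) == {AdherenceLabel.INCORRECT}


def test_config_invariant_validation():
    with pytest.raises(ValueError):
        AdherenceConfig(ed_pre_window=(24.0, 2.0))
    with pytest.raises(ValueError):
        AdherenceConfig(ed_post1_window=(22.0, 47.0))
    with pytest.raises(ValueError):
        AdherenceConfig(both_pass_precedence="coin-flip")
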