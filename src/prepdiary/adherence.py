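"""Per-event PrEP adherence classification from raw pill-log timelines.

Every sex event is labelled with exactly one of three categories:

* ``CORRECT_DAILY`` — at least 4 pills were taken within the 168 hours before
  the event (the >=4 pills/week threshold associated with protective drug
  levels under daily dosing).
* ``CORRECT_ED`` — a valid event-driven (2-1-1) sequence exists: a pre-sex
  dose of 2 pills taken 2-24 hours before the event (1 pill suffices when at
  least one pill was already taken more than 24 and at most 168 hours before
  the event), plus one pill 22-26 hours and one pill 46-50 hours after the
  pre-sex dose.  The +-2h slack on the nominal 24h/48h follow-up pills is the
  logging buffer and is already built into the windows.
* ``INCORRECT`` — neither rule is satisfied.

All window bounds are closed unless stated otherwise and are configurable via
:class:`AdherenceConfig`.  Times are integer minutes since the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .diary_model import AdherenceLabel, Diary, DoseLog, Regimen, SexEventRecord

__all__ = [
    "AdherenceConfig",
    "MergedDose",
    "merge_doses",
    "check_daily",
    "check_ed",
    "classify_event",
    "classify_diary",
]

MIN_PER_H = 60


def _h(hours: float) -> int:
    """Hours to integer minutes (windows are specified in hours)."""
    return int(round(hours * MIN_PER_H))


@dataclass(frozen=True)
class AdherenceConfig:
    """Timing windows of the adherence rules.

    All intervals are in hours.  ``ed_pre_window`` is the closed interval of
    admissible gaps X between the pre-sex dose and the sex event;
    ``ed_post1_window`` / ``ed_post2_window`` are closed windows *after the
    pre-sex dose time*.  ``ed_single_pre_lookback = (lo, hi)`` permits a
    1-pill pre-sex dose when at least one pill lies in
    ``(event - hi, event - lo]`` (open at the far end, closed at the near
    end).  ``both_pass_precedence`` resolves events satisfying both rules:
    ``"declared"`` labels by the regimen declared on the most recent dose at
    or before the event (UNKNOWN falls back to daily, whose coverage
    condition is stronger); ``"daily"`` / ``"ed"`` force one label.
    """

    daily_lookback_hours: float = 168.0
    daily_min_pills: int = 4
    ed_pre_window: tuple[float, float] = (2.0, 24.0)
    ed_single_pre_lookback: tuple[float, float] = (24.0, 168.0)
    ed_post1_window: tuple[float, float] = (22.0, 26.0)
    ed_post2_window: tuple[float, float] = (46.0, 50.0)
    double_dose_merge_minutes: int = 60
    both_pass_precedence: str = "declared"

    def __post_init__(self) -> None:
        for name in ("ed_pre_window", "ed_single_pre_lookback",
                     "ed_post1_window", "ed_post2_window"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must be a nonempty interval with lower bound >= 0")
        if self.ed_post1_window[1] >= self.ed_post2_window[0]:
            raise ValueError("ed post windows must be disjoint")
        if self.daily_lookback_hours <= 0 or self.daily_min_pills < 1:
            raise ValueError("daily rule parameters must be positive")
        if self.both_pass_precedence not in ("declared", "daily", "ed"):
            raise ValueError("both_pass_precedence must be 'declared', 'daily' or 'ed'")


@dataclass(frozen=True)
class MergedDose:
    """A dose after double-dose merging: earliest time, summed pills, source log ids."""

    time: int
    pills: int
    log_ids: tuple[int, ...]


def merge_doses(doses: Sequence[DoseLog], merge_minutes: int) -> list[MergedDose]:
    """Merge 1-pill logs within ``merge_minutes`` of each other into one dose.

    App users sometimes log a double dose as two taps; chains of 1-pill logs
    with consecutive gaps <= merge_minutes collapse into a single dose at the
    earliest timestamp.  2-pill logs always stand alone.
    """
    order = sorted(range(len(doses)), key=lambda i: (doses[i].time, i))
    merged: list[MergedDose] = []
    cluster: list[int] = []

    def flush() -> None:
        if cluster:
            merged.append(
                MergedDose(
                    time=doses[cluster[0]].time,
                    pills=sum(doses[i].pills for i in cluster),
                    log_ids=tuple(cluster),
                )
            )
            cluster.clear()

    for i in order:
        d = doses[i]
        if d.pills != 1:
            flush()
            merged.append(MergedDose(time=d.time, pills=d.pills, log_ids=(i,)))
            continue
        if cluster and d.time - doses[cluster[-1]].time > merge_minutes:
            flush()
        cluster.append(i)
    flush()
    return merged


def check_daily(event_time: int, doses: Sequence[DoseLog],
                cfg: AdherenceConfig = AdherenceConfig()) -> bool:
    """True iff >= ``daily_min_pills`` pills lie in ``[event - lookback, event)``."""
    lo = event_time - _h(cfg.daily_lookback_hours)
    total = sum(d.pills for d in doses if lo <= d.time < event_time)
    return total >= cfg.daily_min_pills


def check_ed(event_time: int, doses: Sequence[DoseLog],
             cfg: AdherenceConfig = AdherenceConfig()) -> bool:
    """True iff some pre-sex dose completes a valid event-driven sequence.

    Existential over pre-dose candidates: any merged dose at ``T_pre`` with
    ``event - T_pre`` inside the pre window qualifies if (a) it covers 2
    pills, or 1 pill with a backup pill inside the single-pre lookback; (b) a
    distinct pill log lies in ``[T_pre + 22h, T_pre + 26h]``; and (c) another
    distinct pill log lies in ``[T_pre + 46h, T_pre + 50h]``.
    """
    if not doses:
        return False
    merged = merge_doses(doses, cfg.double_dose_merge_minutes)
    pre_lo = event_time - _h(cfg.ed_pre_window[1])
    pre_hi = event_time - _h(cfg.ed_pre_window[0])
    back_lo = event_time - _h(cfg.ed_single_pre_lookback[1])  # exclusive
    back_hi = event_time - _h(cfg.ed_single_pre_lookback[0])  # inclusive

    for md in merged:
        if not (pre_lo <= md.time <= pre_hi):
            continue
        if md.pills >= 2:
            pre_ids = set(md.log_ids)
        elif any(
            back_lo < doses[i].time <= back_hi
            for i in range(len(doses))
            if i not in md.log_ids
        ):
            pre_ids = set(md.log_ids)
        else:
            continue
        t = md.time
        p1_lo, p1_hi = t + _h(cfg.ed_post1_window[0]), t + _h(cfg.ed_post1_window[1])
        p2_lo, p2_hi = t + _h(cfg.ed_post2_window[0]), t + _h(cfg.ed_post2_window[1])
        has_p1 = any(
            p1_lo <= doses[i].time <= p1_hi for i in range(len(doses)) if i not in pre_ids
        )
        # post windows are disjoint, so distinctness of the two follow-up
        # pills from each other is automatic
        has_p2 = any(
            p2_lo <= doses[i].time <= p2_hi for i in range(len(doses)) if i not in pre_ids
        )
        if has_p1 and has_p2:
            return True
    return False


def _declared_precedence(event_time: int, doses: Sequence[DoseLog]) -> AdherenceLabel:
    at_or_before = [d for d in doses if d.time <= event_time]
    if not at_or_before:  # unreachable when both rules pass, kept for safety
        return AdherenceLabel.CORRECT_DAILY
    latest = max(at_or_before, key=lambda d: (d.time, d.declared_regimen.value))
    if latest.declared_regimen is Regimen.EVENT_DRIVEN:
        return AdherenceLabel.CORRECT_ED
    return AdherenceLabel.CORRECT_DAILY


def classify_event(event: SexEventRecord, doses: Sequence[DoseLog],
                   cfg: AdherenceConfig = AdherenceConfig()) -> AdherenceLabel:
    """Label one sex event from the participant's dose logs."""
    daily = check_daily(event.time, doses, cfg)
    ed = check_ed(event.time, doses, cfg)
    if daily and ed:
        if cfg.both_pass_precedence == "daily":
            return AdherenceLabel.CORRECT_DAILY
        if cfg.both_pass_precedence == "ed":
            return AdherenceLabel.CORRECT_ED
        return _declared_precedence(event.time, doses)
    if daily:
        return AdherenceLabel.CORRECT_DAILY
    if ed:
        return AdherenceLabel.CORRECT_ED
    return AdherenceLabel.INCORRECT


def classify_diary(diary: Diary,
                   cfg: AdherenceConfig = AdherenceConfig()) -> dict[str, AdherenceLabel]:
    """One adherence label per sex event, keyed by event_id.

    Deterministic given the diary contents; invariant to the row order of the
    dose logs.
    """
    doses_by = diary.doses_by_participant()
    return {
        ev.event_id: classify_event(ev, doses_by.get(ev.participant_id, []), cfg)
        for ev in diary.sex_events
    }
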