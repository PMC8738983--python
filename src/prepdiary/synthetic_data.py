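"""Synthetic sex-diary generation from a 3-class generative model.

Events are drawn from a latent-class mixture: each event gets a class from
the mixing proportions, four categorical indicators drawn independently given
the class, and a condom outcome whose condomless probability is class
specific (optionally shifted by a participant-level random intercept on the
logit scale).  The adherence indicator is then *realized* as raw pill-log
timestamps such that the event-level adherence classifier reproduces the
drawn label exactly, so the full pipeline (dose logs -> labels -> indicator
matrix -> LCA) can be exercised end to end without any external data.

Realizing labels as timestamps has one global subtlety: the daily rule counts
every pill in a 168-hour lookback, so pills generated for one event are
visible to its neighbours.  The generator therefore (1) schedules all
INCORRECT-labelled events at the start of each participant's follow-up,
before pill history accumulates (a pure permutation of event order, which
leaves the joint distribution of classes and indicators untouched); (2)
declares each dose with the regimen it was generated for, so that events
satisfying both rules resolve to the intended label under declared-regimen
precedence; and (3) verifies every participant with the actual classifier and
re-draws times/doses on mismatch.  Round-trip label fidelity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .adherence import AdherenceConfig, classify_event
from .diary_model import (
    AGE_TOKENS,
    AdherenceLabel,
    AgeCategory,
    Diary,
    DoseLog,
    PartnerHIV,
    Positioning,
    Regimen,
    SexEventRecord,
    parse_time,
)
from .indicators import DECLARED_LEVELS, INDICATOR_COLUMNS, IndicatorMatrix

__all__ = [
    "SynthConfig",
    "GenerationTruth",
    "DEFAULT_RESPONSE",
    "generate",
    "generate_dose_pattern",
    "sample_matrix",
]

MIN_PER_H = 60
H24 = 24 * MIN_PER_H


def _h(hours: float) -> int:
    return int(round(hours * MIN_PER_H))


#: Class-conditional response probabilities of the default generative model
#: (rows = classes 1..3).  Class 1 mixes positions on a mixed regimen with
#: many unknown-status partners; class 2 is almost exclusively receptive with
#: HIV-negative partners; class 3 is exclusively insertive with
#: undetectable-viral-load positive partners and near-perfect event-driven
#: adherence.  The partner-HIV indicator has four levels: the
#: positive-unknown-viral-load level is never generated.
DEFAULT_RESPONSE: dict[str, list[list[float]]] = {
    "adherence": [
        [0.285, 0.524, 0.191],
        [0.165, 0.720, 0.114],
        [0.120, 0.867, 0.013],
    ],
    "positioning": [
        [0.613, 0.139, 0.248],
        [0.011, 0.989, 0.000],
        [1.000, 0.000, 0.000],
    ],
    "partner_hiv": [
        [0.441, 0.368, 0.177, 0.014],
        [0.363, 0.094, 0.457, 0.086],
        [0.048, 0.000, 0.000, 0.952],
    ],
    "age_comparison": [
        [0.090, 0.563, 0.347],
        [0.288, 0.495, 0.217],
        [0.746, 0.000, 0.254],
    ],
}

#: Level tokens generated per indicator (matches the indicator registry after
#: dropping the unobserved positive-unknown-viral-load partner level).
GENERATED_LEVELS: dict[str, tuple[str, ...]] = {
    "adherence": DECLARED_LEVELS["adherence"],
    "positioning": DECLARED_LEVELS["positioning"],
    "partner_hiv": ("unknown", "neg_on_prep", "neg_no_prep", "pos_uvl"),
    "age_comparison": DECLARED_LEVELS["age_comparison"],
}


def _normalized_response(
    response: dict[str, Sequence[Sequence[float]]]
) -> dict[str, np.ndarray]:
    out = {}
    for col, rows in response.items():
        arr = np.asarray(rows, dtype=float)
        if (arr < 0).any():
            raise ValueError(f"negative response probability in {col!r}")
        out[col] = arr / arr.sum(axis=1, keepdims=True)
    return out


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the fitted 3-class model of a 4-month, 32-participant
    app diary study: mixing proportions (0.42, 0.52, 0.06), the conditional
    response probabilities of :data:`DEFAULT_RESPONSE`, class-wise condomless
    probabilities (0.85, 0.69, 1.00), and a zero-truncated Poisson event
    count with mean 17.2 per participant.  Participant ages default to the
    two central bins (the study population's mean age was ~29), so every
    age-comparison outcome is reachable.
    """

    n_participants: int = 32
    events_per_participant_mean: float = 17.2
    mixing: tuple[float, float, float] = (0.42, 0.52, 0.06)
    response: dict[str, list[list[float]]] = field(
        default_factory=lambda: {k: [list(r) for r in v]
                                 for k, v in DEFAULT_RESPONSE.items()}
    )
    condomless_prob: tuple[float, ...] = (0.85, 0.69, 1.00)
    random_intercept_sd: float = 0.0
    participant_age_dist: tuple[float, ...] = (0.0, 0.5, 0.5, 0.0, 0.0, 0.0)
    followup_days: float = 120.0
    min_event_gap_hours: float = 24.0
    start_time: str = "2020-05-01T00:00"
    seed: int = 0
    max_events_per_participant: int = 70
    max_participant_attempts: int = 60

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixing, float)
        if abs(mix.sum() - 1.0) > 1e-8 or (mix < 0).any():
            raise ValueError("mixing must be a probability vector")
        if len(self.condomless_prob) != len(self.mixing):
            raise ValueError("condomless_prob must have one entry per class")
        age = np.asarray(self.participant_age_dist, float)
        if len(age) != 6 or abs(age.sum() - 1.0) > 1e-8 or (age < 0).any():
            raise ValueError("participant_age_dist must be a 6-bin probability vector")
        _normalized_response(self.response)  # validates

    @property
    def n_classes(self) -> int:
        return len(self.mixing)


@dataclass
class GenerationTruth:
    """Ground truth of one generated diary (oracle for recovery tests)."""

    events: pd.DataFrame        # event_id, participant_id, true_class (1-based),
                                # adherence, positioning, partner_hiv,
                                # age_comparison, condomless
    participants: pd.DataFrame  # participant_id, intercept, age_cat, n_events


# ---------------------------------------------------------------------------
# Interval bookkeeping for pill placement
# ---------------------------------------------------------------------------


def _subtract_intervals(
    window: tuple[int, int], forbidden: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Closed-interval subtraction on integer minutes."""
    lo, hi = window
    if hi < lo:
        return []
    pieces = [(lo, hi)]
    for flo, fhi in sorted(forbidden):
        nxt = []
        for plo, phi in pieces:
            if fhi < plo or flo > phi:
                nxt.append((plo, phi))
                continue
            if plo < flo:
                nxt.append((plo, flo - 1))
            if fhi < phi:
                nxt.append((fhi + 1, phi))
        pieces = nxt
    return [(a, b) for a, b in pieces if b >= a]


def _sample_minutes(
    pieces: Sequence[tuple[int, int]], k: int, rng: np.random.Generator
) -> list[int] | None:
    """Sample k distinct minutes from a union of closed intervals."""
    lengths = np.array([b - a + 1 for a, b in pieces], dtype=float)
    total = int(lengths.sum())
    if total < k:
        return None
    offsets = rng.choice(total, size=k, replace=False)
    starts = np.cumsum(np.concatenate([[0], lengths[:-1]]))
    out = []
    for off in offsets:
        idx = int(np.searchsorted(starts, off, side="right") - 1)
        out.append(int(pieces[idx][0] + (off - starts[idx])))
    return sorted(out)


# ---------------------------------------------------------------------------
# Isolated per-event dose patterns
# ---------------------------------------------------------------------------

_INCORRECT_VARIANTS = ("none", "late_pre", "three_per_week", "missing_second_post")


def generate_dose_pattern(
    label: AdherenceLabel,
    event_time: int,
    rng: np.random.Generator,
    participant_id: str = "p",
    cfg: AdherenceConfig = AdherenceConfig(),
    variant: str | None = None,
) -> list[DoseLog]:
    """Dose logs that, in isolation, classify the event exactly as ``label``.

    CORRECT_DAILY places 4-6 pills in the weekly lookback while leaving the
    event-driven pre-window empty; CORRECT_ED draws a pre-sex dose gap X
    uniformly over the pre window (two pills, or one pill plus an older
    backup pill) and places the two follow-up pills inside their windows;
    INCORRECT draws one of four near-miss variants: no pills at all, a
    2-pill dose just outside the pre window, 3 pills per week, or a valid
    pre-sex dose whose second follow-up pill is missing.
    """
    t = int(event_time)
    if label is AdherenceLabel.CORRECT_DAILY:
        lo = t - _h(cfg.daily_lookback_hours) + MIN_PER_H
        hi = t - _h(cfg.ed_pre_window[1]) - 2 * MIN_PER_H
        k = int(rng.integers(cfg.daily_min_pills, cfg.daily_min_pills + 3))
        times = _sample_minutes([(lo, hi)], k, rng)
        return [DoseLog(participant_id, s, 1, Regimen.DAILY) for s in times]

    if label is AdherenceLabel.CORRECT_ED:
        x_lo, x_hi = cfg.ed_pre_window
        x = float(rng.uniform(x_lo + 0.05, x_hi - 0.05))
        t_pre = t - _h(x)
        logs = []
        if rng.random() < 0.35:
            # single-pre variant: 1-pill pre-sex dose plus an older backup
            back = float(rng.uniform(cfg.ed_single_pre_lookback[0] + 1.0,
                                     cfg.ed_single_pre_lookback[1] - 1.0))
            logs.append(DoseLog(participant_id, t - _h(back), 1, Regimen.EVENT_DRIVEN))
            logs.append(DoseLog(participant_id, t_pre, 1, Regimen.EVENT_DRIVEN))
        else:
            logs.append(DoseLog(participant_id, t_pre, 2, Regimen.EVENT_DRIVEN))
        b_off = float(rng.uniform(max(cfg.ed_post1_window[0], x) + 0.05,
                                  cfg.ed_post1_window[1] - 0.05))
        c_off = float(rng.uniform(cfg.ed_post2_window[0] + 0.05,
                                  cfg.ed_post2_window[1] - 0.05))
        logs.append(DoseLog(participant_id, t_pre + _h(b_off), 1, Regimen.EVENT_DRIVEN))
        logs.append(DoseLog(participant_id, t_pre + _h(c_off), 1, Regimen.EVENT_DRIVEN))
        return logs

    v = variant or _INCORRECT_VARIANTS[rng.integers(len(_INCORRECT_VARIANTS))]
    if v == "none":
        return []
    if v == "late_pre":
        off = _h(cfg.ed_pre_window[1]) + MIN_PER_H  # just outside the pre window
        return [DoseLog(participant_id, t - off, 2, Regimen.EVENT_DRIVEN)]
    if v == "three_per_week":
        lo = t - _h(cfg.daily_lookback_hours) + MIN_PER_H
        hi = t - _h(cfg.ed_pre_window[1]) - 2 * MIN_PER_H
        times = _sample_minutes([(lo, hi)], cfg.daily_min_pills - 1, rng)
        return [DoseLog(participant_id, s, 1, Regimen.DAILY) for s in times]
    if v == "missing_second_post":
        x = float(rng.uniform(cfg.ed_pre_window[0] + 0.05, cfg.ed_pre_window[1] - 0.05))
        t_pre = t - _h(x)
        b_off = float(rng.uniform(max(cfg.ed_post1_window[0], x) + 0.05,
                                  cfg.ed_post1_window[1] - 0.05))
        return [
            DoseLog(participant_id, t_pre, 2, Regimen.EVENT_DRIVEN),
            DoseLog(participant_id, t_pre + _h(b_off), 1, Regimen.EVENT_DRIVEN),
        ]
    raise ValueError(f"unknown incorrect-use variant {v!r}")


# ---------------------------------------------------------------------------
# Full-diary generation
# ---------------------------------------------------------------------------


def _draw_participant_age(
    rng: np.random.Generator, dist: np.ndarray, comparisons: set[str]
) -> AgeCategory:
    """Participant age bin admitting every drawn age comparison.

    Boundary bins cannot realize OLDER (top bin) or YOUNGER (bottom bin);
    if the first draw is inadmissible the bin is re-drawn from the admissible
    bins (documented fallback), weighted by the configured distribution.
    """
    admissible = np.ones(6, bool)
    if "older" in comparisons:
        admissible[5] = False
    if "younger" in comparisons:
        admissible[0] = False
    cat = int(rng.choice(6, p=dist))
    if admissible[cat]:
        return AgeCategory(cat)
    w = np.where(admissible, dist, 0.0)
    if w.sum() == 0:
        w = admissible.astype(float)
    return AgeCategory(int(rng.choice(6, p=w / w.sum())))


def _partner_age(
    rng: np.random.Generator, participant: AgeCategory, comparison: str
) -> AgeCategory:
    if comparison == "same":
        return participant
    if comparison == "older":
        choices = [c for c in AgeCategory if c > participant]
    else:
        choices = [c for c in AgeCategory if c < participant]
    return choices[int(rng.integers(len(choices)))]


def _schedule_times(
    labels: Sequence[AdherenceLabel],
    cfg: SynthConfig,
    start_min: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Event times (minutes) with label-aware minimum gaps inside the window."""
    n = len(labels)
    window = _h(cfg.followup_days * 24.0)
    base = _h(cfg.min_event_gap_hours)
    min_gaps = np.zeros(n)
    for i, lab in enumerate(labels):
        if i == 0:
            continue
        min_gaps[i] = base
        if lab is AdherenceLabel.CORRECT_DAILY:
            min_gaps[i] = max(base, _h(36))
    total_min = min_gaps.sum()
    slack = window - total_min
    if slack <= 0:
        return None
    u = rng.dirichlet(np.ones(n + 1)) * slack
    times = start_min + np.cumsum(min_gaps + u[:n])
    return np.round(times).astype(np.int64)


def _pill_sum(placed: list[DoseLog], lo: int, hi: int) -> int:
    """Total pills with lo <= time < hi."""
    return sum(d.pills for d in placed if lo <= d.time < hi)


def _in_zones(s: int, zones: Sequence[tuple[int, int]]) -> bool:
    return any(a <= s <= b for a, b in zones)


def _place_participant_doses(
    labels: Sequence[AdherenceLabel],
    times: np.ndarray,
    pid: str,
    acfg: AdherenceConfig,
    rng: np.random.Generator,
    conservative: bool,
) -> list[DoseLog] | None:
    """Place dose logs for all events of one participant, in time order.

    Returns None when a label is locally infeasible at the drawn times (the
    caller re-draws).  Correctness is ultimately established by running the
    classifier over the result; this routine only has to succeed with high
    probability.
    """
    look = _h(acfg.daily_lookback_hours)
    pre_lo_h, pre_hi_h = acfg.ed_pre_window
    placed: list[DoseLog] = []
    # zones where an extra pill would complete a deliberately broken
    # event-driven sequence of an earlier INCORRECT event
    completion_zones: list[tuple[int, int]] = []
    # pre-dose candidate zones of every event: placing stray pills here can
    # create unintended event-driven candidates
    pre_zones = [
        (int(t) - _h(pre_hi_h), int(t) - _h(pre_lo_h)) for t in times
    ]

    for i, (lab, t64) in enumerate(zip(labels, times)):
        t = int(t64)
        t_prev = int(times[i - 1]) if i > 0 else None
        forbidden = completion_zones + pre_zones

        if lab is AdherenceLabel.CORRECT_DAILY:
            lo = t - look + MIN_PER_H
            if t_prev is not None:
                lo = max(lo, t_prev + 1)
            hi = t - _h(pre_hi_h) - 2 * MIN_PER_H
            pieces = _subtract_intervals((lo, hi), forbidden)
            k = int(rng.integers(acfg.daily_min_pills, acfg.daily_min_pills + 3))
            pill_times = _sample_minutes(pieces, k, rng)
            if pill_times is None:
                return None
            placed.extend(DoseLog(pid, s, 1, Regimen.DAILY) for s in pill_times)
            continue

        if lab is AdherenceLabel.CORRECT_ED:
            ok = False
            for _ in range(30):
                x = float(rng.uniform(pre_lo_h + 0.05, pre_hi_h - 0.05))
                t_pre = t - _h(x)
                b_time = t_pre + _h(float(rng.uniform(
                    max(acfg.ed_post1_window[0], x) + 0.05,
                    acfg.ed_post1_window[1] - 0.05)))
                c_time = t_pre + _h(float(rng.uniform(
                    acfg.ed_post2_window[0] + 0.05, acfg.ed_post2_window[1] - 0.05)))
                own_zone_ok = not any(
                    _in_zones(s, completion_zones) for s in (t_pre, b_time, c_time)
                )
                # keep follow-up pills out of *other* events' pre-dose zones
                other_pre = [z for j, z in enumerate(pre_zones) if j != i]
                stray_ok = not any(_in_zones(s, other_pre) for s in (b_time, c_time))
                if own_zone_ok and stray_ok:
                    ok = True
                    break
            if not ok:
                return None
            backup_exists = any(
                t - look < d.time <= t - _h(acfg.ed_single_pre_lookback[0])
                for d in placed
            )
            single = backup_exists and not conservative and rng.random() < 0.35
            if single:
                placed.append(DoseLog(pid, t_pre, 1, Regimen.EVENT_DRIVEN))
            else:
                placed.append(DoseLog(pid, t_pre, 2, Regimen.EVENT_DRIVEN))
            placed.append(DoseLog(pid, b_time, 1, Regimen.EVENT_DRIVEN))
            placed.append(DoseLog(pid, c_time, 1, Regimen.EVENT_DRIVEN))
            continue

        # INCORRECT: both rules must fail, so the weekly pill total (own +
        # pills inherited from neighbours) must stay below the daily
        # threshold and no event-driven sequence may complete.
        foreign = _pill_sum(placed, t - look, t)
        budget = acfg.daily_min_pills - 1 - foreign
        if budget < 0:
            return None
        options = ["none"]
        if not conservative:
            if budget >= 2:
                options += ["late_pre", "missing_second_post"]
            if budget >= acfg.daily_min_pills - 1 and t_prev is None:
                options.append("three_per_week")
        for _ in range(20):
            v = options[int(rng.integers(len(options)))]
            logs = generate_dose_pattern(
                AdherenceLabel.INCORRECT, t, rng, pid, acfg, variant=v
            )
            if all(not _in_zones(d.time, forbidden) for d in logs):
                break
        else:
            v, logs = "none", []
        if v == "missing_second_post":
            t_pre = min(d.time for d in logs)
            completion_zones.append(
                (t_pre + _h(acfg.ed_post2_window[0]), t_pre + _h(acfg.ed_post2_window[1]))
            )
        placed.extend(logs)

    return placed


def generate(config: SynthConfig) -> tuple[Diary, GenerationTruth]:
    """Generate a full diary plus ground truth from the mixture model.

    Per participant: a zero-truncated Poisson event count, a random intercept
    ~ Normal(0, sd) on the condomless-logit scale, event times at least 24h
    apart inside the follow-up window (INCORRECT-labelled events are
    scheduled first — see the module docstring), indicators drawn from the
    class-conditional response probabilities, and dose logs realizing each
    adherence label.  The classifier is run on every participant and the
    participant is re-drawn until the labels round-trip exactly.
    """
    rng = np.random.default_rng(config.seed)
    resp = _normalized_response(config.response)
    mixing = np.asarray(config.mixing, float)
    age_dist = np.asarray(config.participant_age_dist, float)
    acfg = AdherenceConfig()
    start_min = parse_time(config.start_time)
    n_classes = config.n_classes
    adh_levels = [AdherenceLabel(tok) for tok in GENERATED_LEVELS["adherence"]]

    all_events: list[SexEventRecord] = []
    all_doses: list[DoseLog] = []
    truth_rows: list[dict] = []
    part_rows: list[dict] = []
    participants: set[str] = set()
    width = max(4, len(str(config.n_participants)))

    for p in range(config.n_participants):
        pid = f"p{p + 1:0{width}d}"
        participants.add(pid)
        # zero-truncated Poisson: the emulated study analyzed participants
        # with at least one logged event
        n = 0
        while n == 0:
            n = int(rng.poisson(config.events_per_participant_mean))
        n = min(n, config.max_events_per_participant)
        intercept = float(rng.normal(0.0, config.random_intercept_sd)) \
            if config.random_intercept_sd > 0 else 0.0

        classes = rng.choice(n_classes, size=n, p=mixing)
        draws = {
            col: np.array([
                rng.choice(len(GENERATED_LEVELS[col]), p=resp[col][k])
                for k in classes
            ])
            for col in INDICATOR_COLUMNS
        }
        comparisons = {GENERATED_LEVELS["age_comparison"][c]
                       for c in draws["age_comparison"]}
        age_cat = _draw_participant_age(rng, age_dist, comparisons)

        condomless = np.empty(n, dtype=bool)
        for i, k in enumerate(classes):
            pr = float(config.condomless_prob[k])
            if 0.0 < pr < 1.0 and config.random_intercept_sd > 0:
                pr = float(expit(logit(pr) + intercept))
            condomless[i] = rng.random() < pr

        labels = [adh_levels[c] for c in draws["adherence"]]
        # schedule INCORRECT events first (permutation of event order only)
        order = sorted(
            range(n),
            key=lambda i: (labels[i] is not AdherenceLabel.INCORRECT, rng.random()),
        )

        placed = times = None
        for attempt in range(config.max_participant_attempts):
            conservative = attempt >= config.max_participant_attempts // 3
            ordered_labels = [labels[i] for i in order]
            times = _schedule_times(ordered_labels, config, start_min, rng)
            if times is None:
                continue
            placed = _place_participant_doses(
                ordered_labels, times, pid, acfg, rng, conservative
            )
            if placed is None:
                continue
            ok = all(
                classify_event(
                    SexEventRecord(
                        event_id="tmp", participant_id=pid, time=int(t),
                        condom_used=False, positioning=Positioning.INSERTIVE,
                        partner_hiv=PartnerHIV.UNKNOWN,
                        partner_age_cat=age_cat, participant_age_cat=age_cat,
                    ),
                    placed, acfg,
                ) is lab
                for lab, t in zip(ordered_labels, times)
            )
            if ok:
                break
            placed = None
        if placed is None:
            raise RuntimeError(
                f"could not realize adherence labels for participant {pid} "
                f"after {config.max_participant_attempts} attempts"
            )

        for slot, (orig, t) in enumerate(zip(order, times)):
            eid = f"{pid}-e{slot + 1:03d}"
            pos = Positioning(GENERATED_LEVELS["positioning"][draws["positioning"][orig]])
            hiv = PartnerHIV(GENERATED_LEVELS["partner_hiv"][draws["partner_hiv"][orig]])
            comp = GENERATED_LEVELS["age_comparison"][draws["age_comparison"][orig]]
            partner_cat = _partner_age(rng, age_cat, comp)
            all_events.append(
                SexEventRecord(
                    event_id=eid, participant_id=pid, time=int(t),
                    condom_used=not condomless[orig],
                    positioning=pos, partner_hiv=hiv,
                    partner_age_cat=partner_cat, participant_age_cat=age_cat,
                )
            )
            truth_rows.append(
                {
                    "event_id": eid,
                    "participant_id": pid,
                    "true_class": int(classes[orig]) + 1,
                    "adherence": labels[orig].value,
                    "positioning": pos.value,
                    "partner_hiv": hiv.value,
                    "age_comparison": comp,
                    "condomless": bool(condomless[orig]),
                }
            )
        all_doses.extend(placed)
        part_rows.append(
            {
                "participant_id": pid,
                "intercept": intercept,
                "age_cat": AGE_TOKENS[age_cat],
                "n_events": n,
            }
        )

    diary = Diary(participants=participants, dose_logs=all_doses, sex_events=all_events)
    diary.validate()
    truth = GenerationTruth(
        events=pd.DataFrame(truth_rows),
        participants=pd.DataFrame(part_rows),
    )
    return diary, truth


def sample_matrix(
    config: SynthConfig, n_events: int, seed: int | None = None
) -> tuple[IndicatorMatrix, np.ndarray]:
    """Draw an indicator matrix directly from the mixture (no dose logs).

    Fast path for estimator studies that only need the categorical data;
    returns the matrix plus the true class per event (1-based).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    resp = _normalized_response(config.response)
    mixing = np.asarray(config.mixing, float)
    classes = rng.choice(config.n_classes, size=n_events, p=mixing)
    codes = np.zeros((n_events, len(INDICATOR_COLUMNS)), dtype=np.int64)
    for j, col in enumerate(INDICATOR_COLUMNS):
        C = len(GENERATED_LEVELS[col])
        cum = np.cumsum(resp[col], axis=1)
        u = rng.random(n_events)
        codes[:, j] = np.minimum(
            (u[:, None] > cum[classes]).sum(axis=1), C - 1
        )
    m = IndicatorMatrix(
        event_ids=[f"e{i + 1:05d}" for i in range(n_events)],
        columns=INDICATOR_COLUMNS,
        codes=codes,
        levels={c: list(GENERATED_LEVELS[c]) for c in INDICATOR_COLUMNS},
    )
    m.validate()
    return m, classes + 1
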