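"""Latent-class indicator matrix construction and protection summaries.

Each sex event contributes four categorical indicators: the adherence label
(correct daily / correct event-driven / incorrect), sexual positioning
(insertive / receptive / both), partner HIV status, and the ordinal
comparison between the partner's and the participant's age category.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .diary_model import (
    AdherenceLabel,
    AgeCategory,
    Diary,
    PartnerHIV,
    Positioning,
)

__all__ = [
    "AgeComparison",
    "age_comparison",
    "IndicatorMatrix",
    "build_matrix",
    "ProtectionSummary",
    "summarize_protection",
    "INDICATOR_COLUMNS",
    "DECLARED_LEVELS",
]


class AgeComparison(enum.Enum):
    """Partner's age category relative to the participant's."""

    OLDER = "older"
    SAME = "same"
    YOUNGER = "younger"


def age_comparison(participant_cat: AgeCategory, partner_cat: AgeCategory) -> AgeComparison:
    """OLDER iff the partner's age bin is above the participant's, etc.

    Comparison is on the ordinal bin index (the study compares category bins,
    not exact ages); antisymmetric under swapping the arguments.
    """
    p = AgeCategory(participant_cat)
    q = AgeCategory(partner_cat)
    if q > p:
        return AgeComparison.OLDER
    if q < p:
        return AgeComparison.YOUNGER
    return AgeComparison.SAME


INDICATOR_COLUMNS = ("adherence", "positioning", "partner_hiv", "age_comparison")

#: Declared level token order per indicator (fixes category code order).
DECLARED_LEVELS: Mapping[str, tuple[str, ...]] = {
    "adherence": tuple(lab.value for lab in AdherenceLabel),
    "positioning": tuple(p.value for p in Positioning),
    "partner_hiv": tuple(h.value for h in PartnerHIV),
    "age_comparison": tuple(c.value for c in AgeComparison),
}


@dataclass
class IndicatorMatrix:
    """N events x 4 categorical indicators with a per-column level registry."""

    event_ids: list[str]
    columns: tuple[str, ...]
    codes: np.ndarray  # (N, 4) integer category codes
    levels: dict[str, list[str]]

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(self.levels[c]) for c in self.columns)

    def decode(self, column: str) -> list[str]:
        """Map a column's codes back to level tokens."""
        j = self.columns.index(column)
        lv = self.levels[column]
        return [lv[c] for c in self.codes[:, j]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.decode(c) for c in self.columns},
            index=pd.Index(self.event_ids, name="event_id"),
        )

    def validate(self) -> None:
        if self.codes.shape != (len(self.event_ids), len(self.columns)):
            raise ValueError("codes shape does not match event_ids/columns")
        for j, c in enumerate(self.columns):
            col = self.codes[:, j]
            if col.min(initial=0) < 0 or (len(col) and col.max() >= len(self.levels[c])):
                raise ValueError(f"column {c!r} has codes outside its level registry")


def build_matrix(
    diary: Diary,
    labels: Mapping[str, AdherenceLabel],
    drop_unobserved_levels: bool = True,
) -> IndicatorMatrix:
    """Assemble the event x indicator matrix from a labelled diary.

    With ``drop_unobserved_levels`` (default), partner-HIV levels with zero
    observations are removed from the level registry, so e.g. a diary with no
    positive-unknown-viral-load partners yields a 4-level HIV indicator.  The
    other three indicators keep their full declared 3-level sets.
    """
    tokens: dict[str, list[str]] = {c: [] for c in INDICATOR_COLUMNS}
    for ev in diary.sex_events:
        if ev.event_id not in labels:
            raise ValueError(f"event {ev.event_id!r} has no adherence label")
        tokens["adherence"].append(labels[ev.event_id].value)
        tokens["positioning"].append(ev.positioning.value)
        tokens["partner_hiv"].append(ev.partner_hiv.value)
        tokens["age_comparison"].append(
            age_comparison(ev.participant_age_cat, ev.partner_age_cat).value
        )

    levels: dict[str, list[str]] = {}
    for c in INDICATOR_COLUMNS:
        declared = list(DECLARED_LEVELS[c])
        if c == "partner_hiv" and drop_unobserved_levels:
            observed = set(tokens[c])
            declared = [t for t in declared if t in observed]
        levels[c] = declared

    n = len(diary.sex_events)
    codes = np.zeros((n, len(INDICATOR_COLUMNS)), dtype=np.int64)
    for j, c in enumerate(INDICATOR_COLUMNS):
        index = {t: k for k, t in enumerate(levels[c])}
        codes[:, j] = [index[t] for t in tokens[c]]

    m = IndicatorMatrix(
        event_ids=[ev.event_id for ev in diary.sex_events],
        columns=INDICATOR_COLUMNS,
        codes=codes,
        levels=levels,
    )
    m.validate()
    return m


@dataclass
class ProtectionSummary:
    """Event-level protection breakdown by PrEP and condoms.

    An event is PrEP-protected iff its adherence label is CORRECT_DAILY or
    CORRECT_ED, and condom-protected iff a condom was used.  Set identity:
    ``n_either = n_prep_protected + n_condom_protected - n_both`` and
    ``n_either + n_neither = n_events``.
    """

    n_events: int = 0
    n_prep_protected: int = 0
    n_condom_protected: int = 0
    n_both: int = 0
    n_either: int = 0
    n_neither: int = 0
    per_participant: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_prep_protected": self.n_prep_protected,
            "n_condom_protected": self.n_condom_protected,
            "n_both": self.n_both,
            "n_either": self.n_either,
            "n_neither": self.n_neither,
            "per_participant": self.per_participant,
        }


PREP_PROTECTIVE = (AdherenceLabel.CORRECT_DAILY, AdherenceLabel.CORRECT_ED)


def summarize_protection(
    diary: Diary, labels: Mapping[str, AdherenceLabel]
) -> ProtectionSummary:
    """Count events protected by PrEP, condoms, both, either, or neither."""
    s = ProtectionSummary()
    per: dict[str, dict] = {
        p: {"n_events": 0, "fully_prep_protected": True, "any_unprotected": False}
        for p in diary.participants
    }
    for ev in diary.sex_events:
        if ev.event_id not in labels:
            raise ValueError(f"event {ev.event_id!r} has no adherence label")
        prep = labels[ev.event_id] in PREP_PROTECTIVE
        condom = ev.condom_used
        s.n_events += 1
        s.n_prep_protected += prep
        s.n_condom_protected += condom
        s.n_both += prep and condom
        s.n_either += prep or condom
        s.n_neither += not (prep or condom)
        row = per[ev.participant_id]
        row["n_events"] += 1
        row["fully_prep_protected"] = row["fully_prep_protected"] and prep
        row["any_unprotected"] = row["any_unprotected"] or not (prep or condom)
    # participants with no events carry no protection claim
    s.per_participant = {
        p: row for p, row in sorted(per.items()) if row["n_events"] > 0
    }
    return s
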