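"""Domain types and CSV I/O for app-based sex/PrEP diaries.

A diary is a pair of per-participant event streams: timestamped sex events
(condom use, positioning, partner HIV status, age categories) and pill-intake
logs (time, pill count, declared dosing regimen).  Timestamps are stored
internally as integer minutes since the Unix epoch; on disk they are ISO-8601
strings with minute resolution.  All enum fields use fixed canonical CSV
tokens (case-insensitive on read, canonical case on write).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Regimen",
    "Positioning",
    "PartnerHIV",
    "AgeCategory",
    "AdherenceLabel",
    "DoseLog",
    "SexEventRecord",
    "Diary",
    "DiaryError",
    "SchemaError",
    "ValidationError",
    "parse_time",
    "format_time",
    "read_diary",
    "write_diary",
]

MINUTE_NS = 60_000_000_000


class DiaryError(Exception):
    """Base class for diary I/O and validation failures."""


class SchemaError(DiaryError):
    """A required CSV column is missing or the file is malformed."""


class ValidationError(DiaryError):
    """Row-level content violates the declared vocabulary or invariants."""


class Regimen(enum.Enum):
    """Dosing regimen the participant declared when logging a pill."""

    DAILY = "daily"
    EVENT_DRIVEN = "event_driven"
    UNKNOWN = "unknown"


class Positioning(enum.Enum):
    """Sexual positioning during one anal-sex event."""

    INSERTIVE = "insertive"
    RECEPTIVE = "receptive"
    BOTH = "both"


class PartnerHIV(enum.Enum):
    """Partner HIV/PrEP status as reported by the participant."""

    UNKNOWN = "unknown"
    NEG_ON_PREP = "neg_on_prep"
    NEG_NO_PREP = "neg_no_prep"
    POS_UVL = "pos_uvl"
    POS_UNKNOWN_VL = "pos_unknown_vl"


class AgeCategory(enum.IntEnum):
    """Ordinal age bins used for both participant and partner ages."""

    LT20 = 0
    A21_30 = 1
    A31_40 = 2
    A41_50 = 3
    A51_60 = 4
    GT60 = 5


AGE_TOKENS: Mapping[AgeCategory, str] = {
    AgeCategory.LT20: "lt20",
    AgeCategory.A21_30: "21-30",
    AgeCategory.A31_40: "31-40",
    AgeCategory.A41_50: "41-50",
    AgeCategory.A51_60: "51-60",
    AgeCategory.GT60: "gt60",
}
_AGE_FROM_TOKEN = {tok: cat for cat, tok in AGE_TOKENS.items()}


class AdherenceLabel(enum.Enum):
    """Per-event PrEP use category: correct daily, correct event-driven, or incorrect."""

    CORRECT_DAILY = "correct_daily"
    CORRECT_ED = "correct_ed"
    INCORRECT = "incorrect"


def parse_time(value: str) -> int:
    """Parse an ISO-8601 timestamp into integer minutes since the epoch.

    Sub-minute components are truncated (the source app logs clock times and
    every adherence window is specified in hours).
    """
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        raise ValueError(f"unparseable timestamp: {value!r}")
    return int(ts.value // MINUTE_NS)


def format_time(minutes: int) -> str:
    """Render minutes-since-epoch as a canonical ISO-8601 minute string."""
    return pd.Timestamp(int(minutes) * 60, unit="s").strftime("%Y-%m-%dT%H:%M")


@dataclass(frozen=True, order=True)
class DoseLog:
    """One pill-intake record.

    pills is the count taken at this clock time (1 or 2; a "double dose" may
    equivalently appear as two 1-pill rows — merging is an adherence-rule
    concern, not an I/O one).
    """

    participant_id: str
    time: int
    pills: int
    declared_regimen: Regimen = Regimen.UNKNOWN

    def __post_init__(self) -> None:
        if self.pills not in (1, 2):
            raise ValidationError(f"pills must be 1 or 2, got {self.pills}")


@dataclass(frozen=True)
class SexEventRecord:
    """One logged sex event with its latent-class-indicator raw fields."""

    event_id: str
    participant_id: str
    time: int
    condom_used: bool
    positioning: Positioning
    partner_hiv: PartnerHIV
    partner_age_cat: AgeCategory
    participant_age_cat: AgeCategory


@dataclass
class Diary:
    """A validated collection of participants, dose logs, and sex events."""

    participants: set[str] = field(default_factory=set)
    dose_logs: list[DoseLog] = field(default_factory=list)
    sex_events: list[SexEventRecord] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for ev in self.sex_events:
            if ev.event_id in seen:
                raise ValidationError(f"duplicate event_id: {ev.event_id!r}")
            seen.add(ev.event_id)
            if ev.participant_id not in self.participants:
                raise ValidationError(
                    f"event {ev.event_id!r} references unknown participant "
                    f"{ev.participant_id!r}"
                )
        for d in self.dose_logs:
            if d.participant_id not in self.participants:
                raise ValidationError(
                    f"dose log at {format_time(d.time)} references unknown "
                    f"participant {d.participant_id!r}"
                )

    def doses_by_participant(self) -> dict[str, list[DoseLog]]:
        out: dict[str, list[DoseLog]] = {p: [] for p in self.participants}
        for d in self.dose_logs:
            out[d.participant_id].append(d)
        for logs in out.values():
            logs.sort(key=lambda d: (d.time, d.pills, d.declared_regimen.value))
        return out

    def events_by_participant(self) -> dict[str, list[SexEventRecord]]:
        out: dict[str, list[SexEventRecord]] = {p: [] for p in self.participants}
        for ev in self.sex_events:
            out[ev.participant_id].append(ev)
        for evs in out.values():
            evs.sort(key=lambda e: (e.time, e.event_id))
        return out


EVENT_COLUMNS = [
    "event_id",
    "participant_id",
    "time",
    "condom_used",
    "positioning",
    "partner_hiv",
    "partner_age_cat",
    "participant_age_cat",
]
DOSE_COLUMNS = ["participant_id", "time", "pills", "declared_regimen"]

_BOOL_TOKENS = {"true": True, "false": False}


def _parse_enum(enum_cls, token: str, *, column: str, row: int):
    try:
        return enum_cls(token.strip().lower())
    except ValueError:
        raise ValidationError(
            f"row {row}, column {column!r}: unknown token {token!r} "
            f"(expected one of {[e.value for e in enum_cls]})"
        ) from None


def _parse_age(token: str, *, column: str, row: int) -> AgeCategory:
    tok = token.strip().lower()
    if tok not in _AGE_FROM_TOKEN:
        raise ValidationError(
            f"row {row}, column {column!r}: unknown token {token!r} "
            f"(expected one of {sorted(_AGE_FROM_TOKEN)})"
        )
    return _AGE_FROM_TOKEN[tok]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_diary(events_path, doses_path) -> Diary:
    """Read and validate a diary from events.csv / doses.csv.

    Rows with unparseable timestamps or out-of-vocabulary tokens are rejected
    with row-numbered diagnostics (row numbers count data rows from 1).
    """
    events_df = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    doses_df = pd.read_csv(doses_path, dtype=str, keep_default_na=False)
    _require_columns(events_df, EVENT_COLUMNS, events_path)
    _require_columns(doses_df, DOSE_COLUMNS, doses_path)

    errors: list[str] = []
    events: list[SexEventRecord] = []
    for i, rec in enumerate(events_df.to_dict("records"), start=1):
        try:
            try:
                t = parse_time(rec["time"])
            except ValueError as exc:
                raise ValidationError(f"row {i}, column 'time': {exc}") from None
            condom_tok = rec["condom_used"].strip().lower()
            if condom_tok not in _BOOL_TOKENS:
                raise ValidationError(
                    f"row {i}, column 'condom_used': expected true/false, "
                    f"got {rec['condom_used']!r}"
                )
            events.append(
                SexEventRecord(
                    event_id=rec["event_id"],
                    participant_id=rec["participant_id"],
                    time=t,
                    condom_used=_BOOL_TOKENS[condom_tok],
                    positioning=_parse_enum(
                        Positioning, rec["positioning"], column="positioning", row=i
                    ),
                    partner_hiv=_parse_enum(
                        PartnerHIV, rec["partner_hiv"], column="partner_hiv", row=i
                    ),
                    partner_age_cat=_parse_age(
                        rec["partner_age_cat"], column="partner_age_cat", row=i
                    ),
                    participant_age_cat=_parse_age(
                        rec["participant_age_cat"], column="participant_age_cat", row=i
                    ),
                )
            )
        except ValidationError as exc:
            errors.append(f"{events_path}: {exc}")

    doses: list[DoseLog] = []
    for i, rec in enumerate(doses_df.to_dict("records"), start=1):
        try:
            try:
                t = parse_time(rec["time"])
            except ValueError as exc:
                raise ValidationError(f"row {i}, column 'time': {exc}") from None
            try:
                pills = int(rec["pills"])
            except ValueError:
                raise ValidationError(
                    f"row {i}, column 'pills': expected integer, got {rec['pills']!r}"
                ) from None
            if pills not in (1, 2):
                raise ValidationError(
                    f"row {i}, column 'pills': expected 1 or 2, got {pills}"
                )
            doses.append(
                DoseLog(
                    participant_id=rec["participant_id"],
                    time=t,
                    pills=pills,
                    declared_regimen=_parse_enum(
                        Regimen, rec["declared_regimen"], column="declared_regimen", row=i
                    ),
                )
            )
        except ValidationError as exc:
            errors.append(f"{doses_path}: {exc}")

    if errors:
        raise ValidationError("; ".join(errors))

    diary = Diary(
        participants={e.participant_id for e in events}
        | {d.participant_id for d in doses},
        dose_logs=doses,
        sex_events=events,
    )
    diary.validate()
    return diary


def write_diary(diary: Diary, events_path, doses_path) -> None:
    """Write a diary as two CSVs under a fixed canonical ordering.

    read_diary(write_diary(d)) reproduces d field-for-field at minute
    precision; writing the same diary twice yields byte-identical files.
    """
    diary.validate()
    events = sorted(diary.sex_events, key=lambda e: (e.participant_id, e.time, e.event_id))
    doses = sorted(
        diary.dose_logs,
        key=lambda d: (d.participant_id, d.time, d.pills, d.declared_regimen.value),
    )
    events_df = pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "participant_id": e.participant_id,
                "time": format_time(e.time),
                "condom_used": "true" if e.condom_used else "false",
                "positioning": e.positioning.value,
                "partner_hiv": e.partner_hiv.value,
                "partner_age_cat": AGE_TOKENS[e.partner_age_cat],
                "participant_age_cat": AGE_TOKENS[e.participant_age_cat],
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    doses_df = pd.DataFrame(
        [
            {
                "participant_id": d.participant_id,
                "time": format_time(d.time),
                "pills": d.pills,
                "declared_regimen": d.declared_regimen.value,
            }
            for d in doses
        ],
        columns=DOSE_COLUMNS,
    )
    Path(events_path).parent.mkdir(parents=True, exist_ok=True)
    Path(doses_path).parent.mkdir(parents=True, exist_ok=True)
    events_df.to_csv(events_path, index=False, lineterminator="\n")
    doses_df.to_csv(doses_path, index=False, lineterminator="\n")
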