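import numpy as np
import pytest

from prepdiary.diary_model import (
    AgeCategory,
    DoseLog,
    Diary,
    PartnerHIV,
    Positioning,
    Regimen,
    SexEventRecord,
    parse_time,
)

H = 60  # minutes per hour
T0 = parse_time("2020-06-15T12:00")  # reference event time used across tests


def make_event(event_id="e1", pid="p1", time=T0, condom=False,
               positioning=Positioning.RECEPTIVE,
               partner_hiv=PartnerHIV.UNKNOWN,
               partner_age=AgeCategory.A21_30,
               participant_age=AgeCategory.A21_30):
    return SexEventRecord(
        event_id=event_id, participant_id=pid, time=time, condom_used=condom,
        positioning=positioning, partner_hiv=partner_hiv,
        partner_age_cat=partner_age, participant_age_cat=participant_age,
    )


def dose(hours_from_event, pills=1, pid="p1", regimen=Regimen.UNKNOWN, event_time=T0):
    """DoseLog at a signed hour offset from the reference event time."""
    return DoseLog(pid, event_time + int(round(hours_from_event * H)), pills, regimen)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_diary():
    """Two participants, three events, a handful of doses."""
    events = [
        make_event("e1", "p1", T0),
        make_event("e2", "p1", T0 + 48 * H, condom=True,
                   positioning=Positioning.INSERTIVE),
        make_event("e3", "p2", T0, positioning=Positioning.BOTH,
                   partner_hiv=PartnerHIV.POS_UVL,
                   partner_age=AgeCategory.A31_40),
    ]
    doses = [
        dose(-10, pills=2, regimen=Regimen.EVENT_DRIVEN),
        dose(14),
        dose(38),
        DoseLog("p2", T0 - 100 * H, 1, Regimen.DAILY),
    ]
    return Diary(participants={"p1", "p2"}, dose_logs=doses, sex_events=events)
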