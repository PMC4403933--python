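import pytest

from bpqc.survey_data import (
    CuffSpec,
    ParticipantRecord,
    Reading,
    SurveyDataset,
    SurveyProtocol,
)


def make_participant(pid, readings, survey_id="S1", **kwargs):
    """Participant with readings given as three (sbp, dbp) pairs; None for
    a missing value."""
    slots = tuple(
        Reading(i + 1, sbp, dbp) for i, (sbp, dbp) in enumerate(readings)
    )
    return ParticipantRecord(
        participant_id=pid, survey_id=survey_id, readings=slots, **kwargs
    )


@pytest.fixture
def simple_protocol():
    return SurveyProtocol(
        survey_id="S1",
        n_participants=0,
        device_type="oscillometric",
        device_model="Omron M6",
        cuff_inventory=[
            CuffSpec("17–22 cm", 17, 22),
            CuffSpec("22–32 cm", 22, 32),
            CuffSpec("32–42 cm", 32, 42),
        ],
        stethoscope_side="not_relevant",
    )


@pytest.fixture
def make_dataset(simple_protocol):
    def _make(participants):
        return SurveyDataset(protocol=simple_protocol, participants=list(participants))

    return _make
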