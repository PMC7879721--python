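import pandas as pd
import pytest

from textpheno.simulate import MESSAGE_COLUMNS


def make_messages(rows):
    """Build a message frame from (message_id, transcript_id, patient_id, timestamp, text)."""
    return pd.DataFrame(rows, columns=MESSAGE_COLUMNS)


@pytest.fixture
def tiny_corpus():
    """Eight messages, four transcripts, three calendar days."""
    return make_messages(
        [
            ("m0", "t0", "p0", "2020-03-01T09:00:00", "The coronavirus scares me"),
            ("m1", "t0", "p0", "2020-03-01T10:00:00", "feeling ok today"),
            ("m2", "t1", "p1", "2020-03-01T11:00:00", "work was fine"),
            ("m3", "t1", "p1", "2020-03-01T12:00:00", "slept badly"),
            ("m4", "t2", "p2", "2020-03-02T09:00:00", "COVID-19 update worried me"),
            ("m5", "t2", "p2", "2020-03-02T10:00:00", "the PANDEMIC news again"),
            ("m6", "t3", "p3", "2020-03-03T09:00:00", ""),
            ("m7", "t3", "p3", "2020-03-03T10:00:00", "quiet day"),
        ]
    )
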