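"""Readers and writers for the package's on-disk formats.

Messages travel as JSON-lines (one object per message), assessments as CSV
with ``item_1..item_9`` columns (items 8-9 empty for GAD-7), and ground
truth as JSON.  These are the same schemas the synthetic generator writes,
so real exports with matching columns drop in unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import ASSESSMENT_COLUMNS, MESSAGE_COLUMNS, GroundTruth


def write_messages(messages: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in messages[MESSAGE_COLUMNS].to_dict(orient="records"):
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_messages(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    df = pd.DataFrame(records, columns=MESSAGE_COLUMNS)
    return df


def write_assessments(assessments: pd.DataFrame, path) -> None:
    assessments[ASSESSMENT_COLUMNS].to_csv(path, index=False)


def read_assessments(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str, "instrument": str})


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "covid_assoc_terms": sorted(truth.covid_assoc_terms),
        "anti_assoc_terms": sorted(truth.anti_assoc_terms),
        "neutral_terms": sorted(truth.neutral_terms),
        "planted_gad7_shift": truth.planted_gad7_shift,
        "planted_phq9_shift": truth.planted_phq9_shift,
        "per_message_mention_flag": [bool(f) for f in truth.per_message_mention_flag],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        covid_assoc_terms=frozenset(payload["covid_assoc_terms"]),
        anti_assoc_terms=frozenset(payload["anti_assoc_terms"]),
        neutral_terms=frozenset(payload["neutral_terms"]),
        planted_gad7_shift=payload["planted_gad7_shift"],
        planted_phq9_shift=payload["planted_phq9_shift"],
        per_message_mention_flag=payload["per_message_mention_flag"],
    )
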