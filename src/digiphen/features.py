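"""The ten digital-phenotype features and their long-format observation table.

Every feature module emits :class:`FeatureObservation` rows; one observation is
one value of one feature for one participant at one time index (a day since
enrollment, a wave index, or NaN for the single per-participant aggregate).
This long table is the only interchange format between feature extraction and
the statistics stage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .events import Group


class Feature(enum.IntEnum):
    QUESTIONNAIRE_LATENCY = 1          # hours per questionnaire
    QUESTIONNAIRE_LATENCY_SD = 2       # hours, one scalar per participant
    QUESTIONNAIRE_INTERVAL_MEAN = 3    # hours per wave
    QUESTIONNAIRE_INTERVAL_SD = 4      # hours per wave
    NOTIFICATION_LATENCY_DAILY_MEAN = 5  # seconds per participant-day
    NOTIFICATION_LATENCY_DAILY_SD = 6    # seconds per participant-day
    AMBIENT_LIGHT_SD = 7               # lux per session
    STEPS_IN_SESSION = 8               # steps per session
    SESSION_DURATION = 9               # seconds per session
    NEW_APPS_DAILY = 10                # count per participant-day


FEATURE_UNITS = {
    Feature.QUESTIONNAIRE_LATENCY: "hours",
    Feature.QUESTIONNAIRE_LATENCY_SD: "hours",
    Feature.QUESTIONNAIRE_INTERVAL_MEAN: "hours",
    Feature.QUESTIONNAIRE_INTERVAL_SD: "hours",
    Feature.NOTIFICATION_LATENCY_DAILY_MEAN: "seconds",
    Feature.NOTIFICATION_LATENCY_DAILY_SD: "seconds",
    Feature.AMBIENT_LIGHT_SD: "lux",
    Feature.STEPS_IN_SESSION: "steps",
    Feature.SESSION_DURATION: "seconds",
    Feature.NEW_APPS_DAILY: "count",
}

FEATURE_NAMES = {
    Feature.QUESTIONNAIRE_LATENCY: "Questionnaire notification response latency",
    Feature.QUESTIONNAIRE_LATENCY_SD: "SD in questionnaire notification response latency",
    Feature.QUESTIONNAIRE_INTERVAL_MEAN: "Mean intervals between questionnaires",
    Feature.QUESTIONNAIRE_INTERVAL_SD: "SD in intervals between questionnaires",
    Feature.NOTIFICATION_LATENCY_DAILY_MEAN: "Daily mean of social/communication notification response latency",
    Feature.NOTIFICATION_LATENCY_DAILY_SD: "Daily SD in social/communication notification response latency",
    Feature.AMBIENT_LIGHT_SD: "SD in ambient light",
    Feature.STEPS_IN_SESSION: "Steps during the active sessions",
    Feature.SESSION_DURATION: "Active session duration",
    Feature.NEW_APPS_DAILY: "Number of new apps added",
}

#: Feature 2 is a single per-participant aggregate (t-test); all others are
#: repeated measures analysed with a linear mixed model.
AGGREGATED_FEATURES = frozenset({Feature.QUESTIONNAIRE_LATENCY_SD})


@dataclass(frozen=True, slots=True)
class FeatureObservation:
    feature_id: Feature
    participant_id: str
    value: float
    time_index: float = math.nan  # days since enrollment, or wave index
    group: Group | None = None

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError(f"feature value must be finite, got {self.value!r}")

    @property
    def units(self) -> str:
        return FEATURE_UNITS[self.feature_id]


_COLUMNS = ["feature_id", "participant_id", "group", "time_index", "value", "units"]


def to_frame(observations) -> pd.DataFrame:
    """Long-format observation table."""
    rows = [
        (
            int(o.feature_id),
            o.participant_id,
            o.group.value if o.group is not None else None,
            o.time_index,
            o.value,
            o.units,
        )
        for o in observations
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def attach_groups(frame: pd.DataFrame, manifest) -> pd.DataFrame:
    """Fill the group column from a cohort manifest."""
    mapping = {e.participant_id: e.group.value for e in manifest}
    unknown = set(frame["participant_id"]) - set(mapping)
    if unknown:
        raise ValueError(f"participants missing from manifest: {sorted(unknown)}")
    out = frame.copy()
    out["group"] = out["participant_id"].map(mapping)
    return out


def write_feature_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return frame
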