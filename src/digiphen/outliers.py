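"""Outlier handling: the IQR proximity rule and participant-level sensitivity
exclusions.

The IQR proximity rule suits the heavily right-skewed distributions these
behavioural features produce: values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(quartiles by linear interpolation between order statistics) are removed
before the group comparison. Limits are computed per feature on the pooled
values of both groups. The sensitivity analysis instead re-runs the statistics
after dropping whole participants (the two with the highest ambient-light
variability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import Feature


@dataclass(frozen=True, slots=True)
class IqrLimits:
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr


def iqr_limits(values: Sequence[float]) -> IqrLimits:
    """Quartiles and proximity-rule limits of a sample (>= 4 values).

    Percentiles use numpy's default linear interpolation between order
    statistics, fixed here so the rule is reproducible.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"IQR limits need at least 4 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("IQR limits require finite values")
    q1, q3 = np.percentile(arr, [25, 75])
    return IqrLimits(float(q1), float(q3))


def remove_outliers(
    observations: pd.DataFrame, limits: IqrLimits | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one feature's observation table into retained and removed rows.

    Values within the closed interval [lower, upper] are retained. Limits are
    computed on the pooled (both groups) values unless supplied. Retained and
    removed partition the input row-for-row (conservation). Re-applying with
    the *same* limits is a no-op; recomputing limits on the retained subset
    may remove more — callers apply the rule once.
    """
    if observations["feature_id"].nunique() > 1:
        raise ValueError("remove_outliers operates on a single feature")
    if limits is None:
        limits = iqr_limits(observations["value"].to_numpy())
    keep = (observations["value"] >= limits.lower) & (observations["value"] <= limits.upper)
    return observations[keep], observations[~keep]


def outlier_audit(removed: pd.DataFrame, limits: IqrLimits) -> pd.DataFrame:
    """Audit table of removed observations with the limit each breached."""
    audit = removed[["feature_id", "participant_id", "value"]].copy()
    audit["limit_breached"] = np.where(removed["value"] > limits.upper, "upper", "lower")
    audit["limit_value"] = np.where(removed["value"] > limits.upper, limits.upper, limits.lower)
    return audit


def exclude_participants(observations: pd.DataFrame, participant_ids: Sequence[str]) -> pd.DataFrame:
    """Drop all observations of the listed participants (sensitivity analysis)."""
    ids = set(participant_ids)
    unknown = ids - set(observations["participant_id"])
    if unknown:
        raise ValueError(f"unknown participant ids: {sorted(unknown)}")
    return observations[~observations["participant_id"].isin(ids)]


def top_participants_by_feature(
    observations: pd.DataFrame, feature: Feature = Feature.AMBIENT_LIGHT_SD, k: int = 2
) -> list[str]:
    """The k participants with the highest per-participant mean of a feature.

    Used to pick the sensitivity-analysis exclusions (highest SD in ambient
    light).
    """
    sub = observations[observations["feature_id"] == int(feature)]
    means = sub.groupby("participant_id")["value"].mean().sort_values(ascending=False)
    return list(means.index[:k])
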