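"""End-to-end driver: raw streams -> features -> outlier rule -> statistics -> report.

Stages run in a fixed order (sessionize, notifications, feature extraction,
outlier removal, group comparison, report), each writing its intermediate
table; records dropped at each stage are counted so that input = output +
drops holds throughout. A sensitivity re-analysis excluding the two
participants with the highest ambient-light variability is produced alongside
the main report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .events import Group
from .features import (
    Feature,
    FeatureObservation,
    attach_groups,
    to_frame,
    write_feature_table,
)
from .notifications import (
    DEFAULT_LATENCY_CAP,
    daily_latency_stats,
    exclude_sleep,
    extract_notifications,
    match_unlock,
)
from .outliers import (
    exclude_participants,
    iqr_limits,
    outlier_audit,
    remove_outliers,
    top_participants_by_feature,
)
from .passive import ambient_light_sd, daily_new_apps, session_durations, steps_in_sessions
from .questionnaires import (
    latency_sd_aggregate,
    questionnaire_intervals,
    questionnaire_latency,
)
from .sessions import derive_sessions, write_sessions
from .simulate import Cohort, load_cohort
from .stats import (
    GroupComparisonResult,
    build_report,
    compare_feature,
    fit_interaction_lmm,
    format_report,
)

log = logging.getLogger(__name__)

#: Features 1, 3 and 4 get the day-by-group interaction analysis.
INTERACTION_FEATURES = (
    Feature.QUESTIONNAIRE_LATENCY,
    Feature.QUESTIONNAIRE_INTERVAL_MEAN,
    Feature.QUESTIONNAIRE_INTERVAL_SD,
)


@dataclass(frozen=True)
class PipelineConfig:
    latency_cap_s: float = DEFAULT_LATENCY_CAP
    during_session_policy: str = "next_unlock"
    min_daily_responses: int = 2
    min_light_readings: int = 2
    burn_in_days: int = 1
    availability_window_hours: float = 72.0
    utc_offset_hours: float = 0.0
    outlier_rule: str = "pooled"  # pooled | per_group | off
    descriptive: str = "observations"  # observations | participants
    random_slope_day: bool = False
    sensitivity_top_k: int = 2

    def __post_init__(self):
        if self.outlier_rule not in ("pooled", "per_group", "off"):
            raise ValueError(f"unknown outlier_rule {self.outlier_rule!r}")


def extract_features(cohort: Cohort, cfg: PipelineConfig = PipelineConfig()):
    """Derive all ten features from the raw streams of every participant.

    Returns the long-format observation table (with groups attached) and the
    per-stage drop counters.
    """
    if not cohort.streams:
        raise ValueError("empty cohort: nothing to extract")
    observations: list[FeatureObservation] = []
    counts = {
        "notifications_total": 0,
        "notifications_sleep_excluded": 0,
        "notifications_matched": 0,
        "notifications_unmatched": 0,
        "notifications_over_cap": 0,
        "notifications_in_session_dropped": 0,
        "questionnaires_observed": 0,
        "questionnaires_never_started": 0,
        "questionnaires_over_window": 0,
        "sessions_total": 0,
    }
    all_sessions = []
    for pid, ps in cohort.streams.items():
        enroll = ps.enrollment_epoch
        sessions = derive_sessions(ps.phone_status)
        all_sessions.extend(sessions)
        counts["sessions_total"] += len(sessions)

        notifications = extract_notifications(ps.app_events, cohort.category_map)
        counts["notifications_total"] += len(notifications)
        awake = exclude_sleep(notifications, ps.sleep)
        counts["notifications_sleep_excluded"] += len(notifications) - len(awake)
        responses, match_counts = match_unlock(
            awake,
            ps.phone_status,
            latency_cap=cfg.latency_cap_s,
            during_session_policy=cfg.during_session_policy,
            sessions=sessions,
        )
        for key in ("matched", "unmatched", "over_cap", "in_session_dropped"):
            counts[f"notifications_{key}"] += match_counts[key]
        observations.extend(
            daily_latency_stats(responses, enroll, cfg.utc_offset_hours, cfg.min_daily_responses)
        )

        observations.extend(
            ambient_light_sd(ps.light, sessions, enroll, cfg.utc_offset_hours, cfg.min_light_readings)
        )
        observations.extend(steps_in_sessions(ps.steps, sessions, enroll, cfg.utc_offset_hours))
        observations.extend(session_durations(sessions, enroll, cfg.utc_offset_hours))
        observations.extend(
            daily_new_apps(ps.app_events, enroll, cfg.utc_offset_hours, cfg.burn_in_days)
        )

        latency_obs, q_counts = questionnaire_latency(
            ps.questionnaires, enroll, cfg.utc_offset_hours, cfg.availability_window_hours
        )
        counts["questionnaires_observed"] += q_counts["observed"]
        counts["questionnaires_never_started"] += q_counts["never_started"]
        counts["questionnaires_over_window"] += q_counts["over_window"]
        observations.extend(latency_obs)
        sd_obs = latency_sd_aggregate(latency_obs)
        if sd_obs is not None:
            observations.append(sd_obs)
        observations.extend(
            questionnaire_intervals(ps.questionnaires, enroll, cfg.utc_offset_hours)
        )

    frame = attach_groups(to_frame(observations), cohort.manifest)
    return frame, counts, all_sessions


def clean_features(frame: pd.DataFrame, cfg: PipelineConfig = PipelineConfig()):
    """Apply the IQR proximity rule per feature (pooled groups by default).

    Features with fewer than 4 observations are passed through untouched.
    Returns (retained table, audit table of removed rows, per-feature counts).
    """
    if cfg.outlier_rule == "off":
        return frame, frame.iloc[0:0], {}
    retained_parts, audit_parts, counts = [], [], {}
    for fid, sub in frame.groupby("feature_id"):
        groups = [sub] if cfg.outlier_rule == "pooled" else [g for _, g in sub.groupby("group")]
        kept_n = 0
        for part in groups:
            if len(part) < 4:
                retained_parts.append(part)
                kept_n += len(part)
                continue
            limits = iqr_limits(part["value"].to_numpy())
            kept, removed = remove_outliers(part, limits)
            retained_parts.append(kept)
            kept_n += len(kept)
            if len(removed):
                audit_parts.append(outlier_audit(removed, limits))
        counts[int(fid)] = {"in": len(sub), "removed": len(sub) - kept_n}
    retained = pd.concat(retained_parts, ignore_index=True) if retained_parts else frame.iloc[0:0]
    audit = pd.concat(audit_parts, ignore_index=True) if audit_parts else pd.DataFrame(
        columns=["feature_id", "participant_id", "value", "limit_breached", "limit_value"]
    )
    return retained, audit, counts


def analyze(frame: pd.DataFrame, cfg: PipelineConfig = PipelineConfig()):
    """Group comparison per feature plus the day-by-group interaction models."""
    results: dict[Feature, GroupComparisonResult] = {}
    for feat in Feature:
        sub = frame[frame["feature_id"] == int(feat)]
        if sub.empty:
            continue
        try:
            results[feat] = compare_feature(
                sub,
                feat,
                **(
                    {}
                    if feat in (Feature.QUESTIONNAIRE_LATENCY_SD,)
                    else {"random_slope_day": cfg.random_slope_day, "descriptive": cfg.descriptive}
                ),
            )
        except ValueError as exc:
            log.warning("feature %s comparison skipped: %s", feat, exc)
    interactions = {}
    for feat in INTERACTION_FEATURES:
        sub = frame[frame["feature_id"] == int(feat)]
        if sub.empty or sub["time_index"].nunique() < 2:
            continue
        try:
            interactions[feat] = fit_interaction_lmm(sub, feat)
        except Exception as exc:
            log.warning("interaction model for feature %s failed: %s", feat, exc)
    return results, interactions


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    retained_table: pd.DataFrame
    report: pd.DataFrame
    sensitivity_report: pd.DataFrame | None
    interactions: dict
    stage_counts: dict
    excluded_participants: list = field(default_factory=list)


def run_pipeline(
    cohort: Cohort | str | Path,
    output_dir: str | Path,
    cfg: PipelineConfig = PipelineConfig(),
    sensitivity: bool = True,
) -> PipelineResult:
    """Run every stage on a cohort (in memory or a directory) and write all
    intermediate and final tables under ``output_dir``."""
    if not isinstance(cohort, Cohort):
        cohort = load_cohort(cohort)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    frame, counts, sessions = extract_features(cohort, cfg)
    write_feature_table(frame, out / "features_raw.csv")
    write_sessions(sessions, out / "sessions.csv")

    retained, audit, outlier_counts = clean_features(frame, cfg)
    write_feature_table(retained, out / "features_retained.csv")
    audit.to_csv(out / "outlier_audit.csv", index=False)
    counts["outliers"] = outlier_counts

    results, interactions = analyze(retained, cfg)
    report = build_report(results)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(format_report(report))
    if interactions:
        pd.DataFrame(
            [
                {
                    "feature": int(f),
                    "day_coef": r.day_coef,
                    "day_p": r.day_p,
                    "interaction_coef": r.interaction_coef,
                    "interaction_p": r.interaction_p,
                }
                for f, r in interactions.items()
            ]
        ).to_csv(out / "interactions.csv", index=False)

    sens_report = None
    excluded: list = []
    if sensitivity:
        try:
            excluded = top_participants_by_feature(retained, Feature.AMBIENT_LIGHT_SD, cfg.sensitivity_top_k)
        except Exception as exc:
            log.warning("sensitivity selection failed: %s", exc)
        if excluded:
            sens_frame = exclude_participants(retained, excluded)
            sens_results, _ = analyze(sens_frame, cfg)
            sens_report = build_report(sens_results)
            sens_report.to_csv(out / "report_sensitivity.csv", index=False)
            (out / "report_sensitivity.txt").write_text(format_report(sens_report))

    with open(out / "stage_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    log.info("pipeline complete: %d observations, %d retained", len(frame), len(retained))
    return PipelineResult(
        feature_table=frame,
        retained_table=retained,
        report=report,
        sensitivity_report=sens_report,
        interactions=interactions,
        stage_counts=counts,
        excluded_participants=excluded,
    )
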