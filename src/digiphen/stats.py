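"""Two-group comparison of the derived features.

Repeatedly measured features are compared with a linear mixed model (LMM):
value ~ group (+ day and day-by-group terms for the time-trend analysis) with
a random intercept per participant, fitted by REML. The single time-aggregated
feature (the per-participant SD of questionnaire response latency) is compared
with a two-sample t-test.

Effect sizes: for LMM features, the fixed-effect group difference divided by
the square root of the summed variance components (random intercepts and
slopes per participant and per item, plus residual variance; components absent
from the fitted model count as zero). For the t-test feature, Cohen's d with
the pooled SD.

Significance reporting follows the study conventions: the Wald standard score
(Z) of the group term with comparison-minus-ADHD sign, no multiple-testing
correction, alpha = .05. P-values for the group term use a Student-t reference
with (participants − 2) degrees of freedom — a small-sample correction to the
Wald-normal reference, which is anti-conservative when the number of
participants is small.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .events import Group
from .features import AGGREGATED_FEATURES, FEATURE_NAMES, FEATURE_UNITS, Feature

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True, slots=True)
class VarianceComponents:
    """Group mean difference and the five variance terms of the LMM effect size."""

    diff: float
    var_intercept_part: float = 0.0
    var_intercept_item: float = 0.0
    var_slope_part: float = 0.0
    var_slope_item: float = 0.0
    var_residual: float = 0.0

    def __post_init__(self):
        for name in (
            "var_intercept_part",
            "var_intercept_item",
            "var_slope_part",
            "var_slope_item",
            "var_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_variance(self) -> float:
        return (
            self.var_intercept_part
            + self.var_intercept_item
            + self.var_slope_part
            + self.var_slope_item
            + self.var_residual
        )


def lmm_effect_size(vc: VarianceComponents) -> float:
    """Effect size d = |group difference| / sqrt(summed variance components)."""
    total = vc.total_variance
    if total == 0:
        if vc.diff == 0:
            return 0.0
        raise ValueError("effect size undefined: all variance components are zero")
    return abs(vc.diff) / math.sqrt(total)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled (n−1-weighted) SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("Cohen's d needs >= 2 values per group")
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("Cohen's d undefined: zero pooled variance")
    return float(abs(np.mean(a) - np.mean(b)) / math.sqrt(pooled_var))


class Method(enum.Enum):
    LMM = "LMM"
    TTEST = "TTEST"


@dataclass(frozen=True, slots=True)
class GroupComparisonResult:
    feature_id: Feature
    mean_adhd: float
    sd_adhd: float
    mean_comp: float
    sd_comp: float
    p_value: float
    z_score: float
    effect_size_d: float
    method: Method
    n_obs: int
    n_participants: int
    fallback: bool = False
    variance_components: VarianceComponents | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.sd_adhd < 0 or self.sd_comp < 0:
            raise ValueError("group SDs must be >= 0")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _descriptives(frame: pd.DataFrame, mode: str = "observations"):
    """Group mean (SD): over observations (default, matching the repeated-
    measures presentation) or over per-participant means."""
    if mode == "participants":
        frame = (
            frame.groupby(["participant_id", "group"], as_index=False)["value"].mean()
        )
    elif mode != "observations":
        raise ValueError(f"unknown descriptive mode {mode!r}")
    out = {}
    for gname, sub in frame.groupby("group"):
        values = sub["value"].to_numpy(dtype=float)
        out[gname] = (float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0)
    for g in (Group.ADHD.value, Group.COMPARISON.value):
        out.setdefault(g, (math.nan, math.nan))
    return out


def _check_long_frame(frame: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "group", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"long-format frame missing columns {sorted(missing)}")
    per_group = frame.groupby("group")["participant_id"].nunique()
    if set(per_group.index) != {Group.ADHD.value, Group.COMPARISON.value} or (per_group < 2).any():
        raise ValueError("need >= 2 participants in each of the two groups")
    return frame


def _group_indicator(frame: pd.DataFrame) -> np.ndarray:
    # comparison-minus-ADHD coding: ADHD is the reference level
    return (frame["group"] == Group.COMPARISON.value).to_numpy(dtype=float)


def _wald_p(z: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(z), df))


def fit_group_lmm(
    frame: pd.DataFrame,
    feature_id: Feature | None = None,
    random_slope_day: bool = False,
    descriptive: str = "observations",
) -> GroupComparisonResult:
    """Mixed-model group comparison of one repeatedly measured feature.

    value ~ 1 + group, random intercept per participant (REML); optionally a
    random slope on the day index. On a singular or failed fit, falls back to
    a t-test on per-participant means, flagged in the result.
    """
    frame = _check_long_frame(frame)
    if feature_id is None:
        feature_id = Feature(int(frame["feature_id"].iloc[0]))
    desc = _descriptives(frame, descriptive)
    n_obs = len(frame)
    n_part = frame["participant_id"].nunique()

    y = frame["value"].to_numpy(dtype=float)
    g = _group_indicator(frame)
    exog = np.column_stack([np.ones_like(y), g])
    exog_re = None
    if random_slope_day:
        if "time_index" not in frame.columns:
            raise ValueError("random_slope_day requires a time_index column")
        day = frame["time_index"].to_numpy(dtype=float)
        exog_re = np.column_stack([np.ones_like(y), day])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=frame["participant_id"].to_numpy(), exog_re=exog_re)
            fit = model.fit(reml=True)
        if not fit.converged or not np.isfinite(fit.bse[1]):
            raise RuntimeError("mixed model did not converge")
    except Exception as exc:  # singular/failed fit: descriptive fallback
        log.warning("LMM fit failed for feature %s (%s); falling back to participant-mean t-test",
                    feature_id, exc)
        return _participant_mean_fallback(frame, feature_id, desc, n_obs, n_part, descriptive)

    diff = float(fit.params[1])
    z = diff / float(fit.bse[1])
    p = _wald_p(z, df=n_part - 2)
    cov_re = np.asarray(fit.cov_re)
    vc = VarianceComponents(
        diff=diff,
        var_intercept_part=max(float(cov_re[0, 0]), 0.0),
        var_slope_part=max(float(cov_re[1, 1]), 0.0) if random_slope_day else 0.0,
        var_residual=float(fit.scale),
    )
    return GroupComparisonResult(
        feature_id=feature_id,
        mean_adhd=desc[Group.ADHD.value][0],
        sd_adhd=desc[Group.ADHD.value][1],
        mean_comp=desc[Group.COMPARISON.value][0],
        sd_comp=desc[Group.COMPARISON.value][1],
        p_value=p,
        z_score=z,
        effect_size_d=lmm_effect_size(vc),
        method=Method.LMM,
        n_obs=n_obs,
        n_participants=n_part,
        variance_components=vc,
    )


def _participant_mean_fallback(frame, feature_id, desc, n_obs, n_part, descriptive):
    means = frame.groupby(["participant_id", "group"], as_index=False)["value"].mean()
    a = means.loc[means["group"] == Group.ADHD.value, "value"].to_numpy()
    b = means.loc[means["group"] == Group.COMPARISON.value, "value"].to_numpy()
    t, p = sps.ttest_ind(b, a)
    if not np.isfinite(p):  # degenerate (e.g. zero-variance) data
        t, p = 0.0, 1.0
    try:
        d = cohens_d(a, b)
    except ValueError:
        d = 0.0
    return GroupComparisonResult(
        feature_id=feature_id,
        mean_adhd=desc[Group.ADHD.value][0],
        sd_adhd=desc[Group.ADHD.value][1],
        mean_comp=desc[Group.COMPARISON.value][0],
        sd_comp=desc[Group.COMPARISON.value][1],
        p_value=float(p),
        z_score=float(t),
        effect_size_d=d,
        method=Method.LMM,
        n_obs=n_obs,
        n_participants=n_part,
        fallback=True,
    )


def ttest_aggregate(
    frame: pd.DataFrame, feature_id: Feature | None = None
) -> GroupComparisonResult:
    """Two-sided two-sample t-test on one-scalar-per-participant values, with
    Cohen's d. The statistic is signed ADHD-minus-comparison."""
    frame = _check_long_frame(frame)
    if frame.groupby("participant_id").size().max() > 1:
        raise ValueError("ttest_aggregate expects one value per participant")
    if feature_id is None:
        feature_id = Feature(int(frame["feature_id"].iloc[0]))
    a = frame.loc[frame["group"] == Group.ADHD.value, "value"].to_numpy(dtype=float)
    b = frame.loc[frame["group"] == Group.COMPARISON.value, "value"].to_numpy(dtype=float)
    t, p = sps.ttest_ind(a, b)
    d = cohens_d(a, b)
    return GroupComparisonResult(
        feature_id=feature_id,
        mean_adhd=float(np.mean(a)),
        sd_adhd=float(np.std(a, ddof=1)),
        mean_comp=float(np.mean(b)),
        sd_comp=float(np.std(b, ddof=1)),
        p_value=float(p),
        z_score=float(t),
        effect_size_d=d,
        method=Method.TTEST,
        n_obs=len(frame),
        n_participants=frame["participant_id"].nunique(),
    )


@dataclass(frozen=True, slots=True)
class InteractionResult:
    feature_id: Feature
    day_coef: float
    day_p: float
    interaction_coef: float
    interaction_p: float
    group_coef: float
    n_obs: int
    n_participants: int


def fit_interaction_lmm(frame: pd.DataFrame, feature_id: Feature | None = None) -> InteractionResult:
    """Day-by-group interaction model for the questionnaire time-trend analysis.

    value ~ 1 + group + day + group:day with a random intercept per
    participant. With comparison-minus-ADHD coding, a negative interaction
    coefficient means the per-day increase is smaller in the comparison group.
    """
    frame = _check_long_frame(frame)
    if "time_index" not in frame.columns or frame["time_index"].isna().any():
        raise ValueError("interaction model requires a day-valued time_index")
    if feature_id is None:
        feature_id = Feature(int(frame["feature_id"].iloc[0]))
    y = frame["value"].to_numpy(dtype=float)
    g = _group_indicator(frame)
    day = frame["time_index"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones_like(y), g, day, g * day])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(y, exog, groups=frame["participant_id"].to_numpy()).fit(reml=True)
    n_obs, n_part = len(frame), frame["participant_id"].nunique()
    resid_df = max(n_obs - 4, 1)
    return InteractionResult(
        feature_id=feature_id,
        day_coef=float(fit.params[2]),
        day_p=_wald_p(float(fit.params[2] / fit.bse[2]), resid_df),
        interaction_coef=float(fit.params[3]),
        interaction_p=_wald_p(float(fit.params[3] / fit.bse[3]), resid_df),
        group_coef=float(fit.params[1]),
        n_obs=n_obs,
        n_participants=n_part,
    )


def compare_feature(frame: pd.DataFrame, feature_id: Feature, **lmm_kwargs) -> GroupComparisonResult:
    """Dispatch to the t-test for the aggregated feature, else the LMM."""
    if feature_id in AGGREGATED_FEATURES:
        return ttest_aggregate(frame, feature_id)
    return fit_group_lmm(frame, feature_id, **lmm_kwargs)


_REPORT_COLUMNS = [
    "feature", "name", "units", "adhd_mean", "adhd_sd", "comparison_mean",
    "comparison_sd", "p_value", "z_score", "effect_size_d", "method",
    "significant", "n_obs", "n_participants", "fallback",
]


def build_report(results: dict[Feature, GroupComparisonResult]) -> pd.DataFrame:
    """Ten-row summary table: group mean (SD), P, Z, d per feature.

    Features without a result get an NA row with a warning. No
    multiple-testing correction is applied.
    """
    rows = []
    for feat in Feature:
        res = results.get(feat)
        if res is None:
            log.warning("no result for feature %d (%s); emitting NA row", int(feat), FEATURE_NAMES[feat])
            rows.append(
                dict.fromkeys(_REPORT_COLUMNS, math.nan)
                | {"feature": int(feat), "name": FEATURE_NAMES[feat], "units": FEATURE_UNITS[feat]}
            )
            continue
        rows.append(
            {
                "feature": int(feat),
                "name": FEATURE_NAMES[feat],
                "units": FEATURE_UNITS[feat],
                "adhd_mean": res.mean_adhd,
                "adhd_sd": res.sd_adhd,
                "comparison_mean": res.mean_comp,
                "comparison_sd": res.sd_comp,
                "p_value": res.p_value,
                "z_score": res.z_score,
                "effect_size_d": res.effect_size_d,
                "method": res.method.value,
                "significant": res.significant,
                "n_obs": res.n_obs,
                "n_participants": res.n_participants,
                "fallback": res.fallback,
            }
        )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of the summary table."""
    lines = [
        f"{'#':>2}  {'Feature':<58} {'ADHD mean (SD)':>20} {'Comparison mean (SD)':>22} "
        f"{'P':>6} {'Z':>7} {'d':>6}  method",
        "-" * 130,
    ]
    for _, r in report.iterrows():
        if pd.isna(r["p_value"]):
            lines.append(f"{int(r['feature']):>2}  {r['name']:<58} {'NA':>20} {'NA':>22} {'NA':>6}")
            continue
        flag = "*" if r["significant"] else " "
        lines.append(
            f"{int(r['feature']):>2}  {r['name']:<58} "
            f"{r['adhd_mean']:>10.2f} ({r['adhd_sd']:.2f}) "
            f"{r['comparison_mean']:>11.2f} ({r['comparison_sd']:.2f}) "
            f"{r['p_value']:>6.3f} {r['z_score']:>7.2f} {r['effect_size_d']:>6.2f}  {r['method']}{flag}"
        )
    lines.append("")
    lines.append("* P < .05, two-sided, no multiple-testing correction.")
    return "\n".join(lines)
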