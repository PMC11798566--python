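"""Simulation studies that validate the statistical pipeline.

Two Monte-Carlo checks over questionnaire-only synthetic cohorts:

- type-I error calibration: with zero injected group difference, the mixed-
  model group test should reject at the nominal 5% rate;
- interaction sign recovery: with a positive day-slope injected into the ADHD
  group only, the fitted day-by-group interaction coefficient (comparison-
  minus-ADHD coding) should be negative — the comparison group's per-day
  increase is smaller.

Both draw participant-level means at random (stratification off): calibration
is meaningful only under the mixed model's own sampling assumptions, where
participant effects are random draws from their population.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .events import Group
from .features import Feature, attach_groups, to_frame
from .questionnaires import questionnaire_latency
from .simulate import CohortConfig, generate_cohort
from .stats import fit_group_lmm, fit_interaction_lmm


def _questionnaire_latency_frame(cohort):
    obs = []
    for ps in cohort.streams.values():
        latency_obs, _ = questionnaire_latency(ps.questionnaires, ps.enrollment_epoch)
        obs.extend(latency_obs)
    return attach_groups(to_frame(obs), cohort.manifest)


def _null_config(base: CohortConfig) -> CohortConfig:
    """Both groups share the ADHD target distributions, with no day slope."""
    shared = dataclasses.replace(base.targets[Group.ADHD], day_slope_hours=0.0)
    return dataclasses.replace(
        base,
        targets={Group.ADHD: shared, Group.COMPARISON: shared},
        stratify_participants=False,
    )


def type_i_error_rate(
    n_sims: int = 500,
    n_per_group: int = 10,
    weeks: int = 2,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of null cohorts where the LMM group test rejects at alpha.

    Each simulated cohort carries identical latency distributions in both
    groups; questionnaire response latencies are extracted and the group model
    fitted exactly as in the main pipeline.
    """
    base = _null_config(CohortConfig(n_per_group=n_per_group, weeks=weeks))
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    rejections = 0
    for s in seeds:
        cohort = generate_cohort(
            dataclasses.replace(base, seed=int(s)), include_passive=False
        )
        frame = _questionnaire_latency_frame(cohort)
        result = fit_group_lmm(frame, Feature.QUESTIONNAIRE_LATENCY)
        if result.p_value < alpha:
            rejections += 1
    return rejections / n_sims


def interaction_sign_rate(
    n_sims: int = 100,
    n_per_group: int = 10,
    weeks: int = 10,
    adhd_slope_hours: float | None = None,
    seed: int = 0,
) -> float:
    """Fraction of simulations with a negative day-by-group interaction.

    The ADHD group gets a positive questionnaire-latency day slope (the
    configured default unless overridden); the comparison group none. Under
    comparison-minus-ADHD coding the interaction coefficient should come out
    negative.
    """
    base = CohortConfig(n_per_group=n_per_group, weeks=weeks, stratify_participants=False)
    if adhd_slope_hours is not None:
        base = dataclasses.replace(
            base,
            targets={
                Group.ADHD: dataclasses.replace(
                    base.targets[Group.ADHD], day_slope_hours=adhd_slope_hours
                ),
                Group.COMPARISON: base.targets[Group.COMPARISON],
            },
        )
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    negative = 0
    for s in seeds:
        cohort = generate_cohort(
            dataclasses.replace(base, seed=int(s)), include_passive=False
        )
        frame = _questionnaire_latency_frame(cohort)
        result = fit_interaction_lmm(frame, Feature.QUESTIONNAIRE_LATENCY)
        if result.interaction_coef < 0:
            negative += 1
    return negative / n_sims
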