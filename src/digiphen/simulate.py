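"""Synthetic two-group cohort generator.

Emulates the raw event streams of a 10-week, 24/7 remote-monitoring study of
20 participants with ADHD and 20 comparison participants, so that every
pipeline stage is testable without any real data. The generator is built
around the *derived* feature distributions: each group's published mean (SD)
per feature is the target, and the raw streams (phone status transitions, app
events, light samples, step records, sleep intervals, questionnaire
timestamps) are constructed so that running the extraction pipeline over them
recovers those targets.

Positive-valued features use moment-matched gamma draws (these behavioural
quantities are positive and right-skewed, and several targets have SD > mean,
which a gamma supports without negative values); the daily new-app count uses
a Poisson with matched mean. Observation-level dispersion is split into a
between-participant part (participant-specific means) and a within-participant
part, so the mixed models have genuine variance components to estimate.

Day structure per participant: one nightly sleep interval with jitter; during
waking hours, a renewal process of notification-driven phone-use cycles —
wait, then a social/communication app notification, then an unlock after the
group's response latency, then an active session of the group's duration
distribution carrying ambient-light and step traces. A configurable positive
day-slope on questionnaire response latency (centred on the middle assessment
wave) gives the day-by-group interaction analysis a recoverable target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats as sps

from .events import (
    AppCategory,
    AppEvent,
    AppEventType,
    Group,
    LightReading,
    ManifestEntry,
    PhoneState,
    PhoneStatusEvent,
    QuestionnaireRecord,
    SleepInterval,
    StepRecord,
    StreamKind,
    write_category_map,
    write_manifest,
    write_stream,
)

DAY = 86400.0
HOUR = 3600.0

#: 2020-09-01 00:00 UTC — a nominal enrollment date in the study's
#: recruitment window; all participants share it (local midnight, UTC offset 0).
DEFAULT_START_EPOCH = 1598918400.0

SOCIAL_PACKAGES = tuple(f"app.social.{i}" for i in range(5))
COMM_PACKAGES = tuple(f"app.comm.{i}" for i in range(5))
BASE_PACKAGES = tuple(f"app.base.{i}" for i in range(20))


def default_category_map() -> dict[str, AppCategory]:
    mapping = {p: AppCategory.SOCIAL for p in SOCIAL_PACKAGES}
    mapping |= {p: AppCategory.COMMUNICATION for p in COMM_PACKAGES}
    mapping |= {p: AppCategory.OTHER_CATEGORY for p in BASE_PACKAGES}
    return mapping


def sample_moment_matched(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n positive draws from a gamma with the given mean and SD.

    shape = (mean/sd)^2, scale = sd^2/mean; sd = 0 returns constants.
    """
    if mean <= 0:
        raise ValueError(f"moment-matched gamma needs mean > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


@dataclass(frozen=True)
class GroupTargets:
    """Target feature distributions for one group, in feature units.

    Defaults are the two groups' published mean (SD) per derived feature.
    ``day_slope_hours`` is the drift per study day injected into questionnaire
    response latency (centred on the middle wave so the overall mean is
    unchanged).
    """

    questionnaire_latency_hours: tuple[float, float]
    questionnaire_interval_hours: tuple[float, float]
    notification_latency_seconds: tuple[float, float]
    light_session_sd_lux: tuple[float, float]
    steps_per_session: tuple[float, float]
    session_duration_seconds: tuple[float, float]
    new_apps_per_day: float
    day_slope_hours: float = 0.0


ADHD_TARGETS = GroupTargets(
    questionnaire_latency_hours=(19.14, 12.98),
    questionnaire_interval_hours=(1.12, 2.17),
    notification_latency_seconds=(2304.27, 1406.62),
    light_session_sd_lux=(83.96, 155.57),
    steps_per_session=(313.14, 263.88),
    session_duration_seconds=(1778.07, 1653.87),
    new_apps_per_day=1.18,
    day_slope_hours=0.1,
)

COMPARISON_TARGETS = GroupTargets(
    questionnaire_latency_hours=(11.69, 10.31),
    questionnaire_interval_hours=(0.18, 0.64),
    notification_latency_seconds=(1516.45, 785.78),
    light_session_sd_lux=(43.63, 73.57),
    steps_per_session=(179.20, 177.26),
    session_duration_seconds=(1047.68, 1060.45),
    new_apps_per_day=1.43,
    day_slope_hours=0.0,
)


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: int = 20
    weeks: int = 10
    seed: int = 0
    targets: dict = field(
        default_factory=lambda: {Group.ADHD: ADHD_TARGETS, Group.COMPARISON: COMPARISON_TARGETS}
    )
    #: fraction of each target SD assigned to between-participant heterogeneity
    between_fraction: float = 0.6
    questionnaires_per_wave: int = 5
    wave_weeks: tuple = (2, 6, 10)
    availability_window_hours: float = 72.0
    inter_notification_wait_s: float = 900.0
    night_notifications_per_day: float = 2.0
    light_sampling_interval_s: float = 60.0
    ambient_light_base_lux: float = 10.0
    sleep_start_hour: float = 23.5
    sleep_duration_hours: float = 8.0
    sleep_jitter_hours: float = 0.5
    walking_records_per_day: int = 10
    walking_steps_mean: float = 30.0
    start_epoch: float = DEFAULT_START_EPOCH
    utc_offset_hours: float = 0.0
    #: tile participant-level means across their between-participant
    #: distribution (representative-points stratification). Disable for
    #: calibration studies, where participant effects must be random draws to
    #: match the mixed model's sampling assumptions.
    stratify_participants: bool = True

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if not 0.0 <= self.between_fraction < 1.0:
            raise ValueError("between_fraction must be in [0, 1)")
        for rate in (self.inter_notification_wait_s, self.light_sampling_interval_s):
            if rate <= 0:
                raise ValueError("rates must be > 0")

    @property
    def span_days(self) -> int:
        return self.weeks * 7

    @property
    def wave_days(self) -> list[int]:
        return [w * 7 for w in self.wave_weeks if w * 7 <= self.span_days]

    def split_sd(self, sd: float) -> tuple[float, float]:
        """(between-participant SD, within-participant SD); quadrature split."""
        sd_b = self.between_fraction * sd
        return sd_b, float(np.sqrt(max(sd**2 - sd_b**2, 0.0)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = {g.value: dataclasses.asdict(t) for g, t in self.targets.items()}
        d["wave_weeks"] = list(self.wave_weeks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "targets" in d:
            targets = {}
            for gname, tdict in d["targets"].items():
                tdict = {
                    k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in tdict.items()
                }
                targets[Group(gname)] = GroupTargets(**tdict)
            d["targets"] = targets
        if "wave_weeks" in d:
            d["wave_weeks"] = tuple(d["wave_weeks"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ParticipantStreams:
    participant_id: str
    group: Group
    enrollment_epoch: float
    phone_status: list
    app_events: list
    light: list
    steps: list
    sleep: list
    questionnaires: list


#: Participant-level means that are stratified across a group's members.
STRATIFIED_KEYS = (
    "questionnaire_latency",
    "questionnaire_interval",
    "notification_latency",
    "light",
    "steps",
    "session_duration",
)


def _participant_mean(
    mean: float, sd_b: float, rng: np.random.Generator, stratum: tuple[int, int] | None = None
) -> float:
    """One participant-specific mean from the between-participant gamma.

    When a ``(index, n)`` stratum is given, the participant's mean is the
    conditional mean of the between-participant gamma within its quantile
    slice [index/n, (index+1)/n) — a representative-points stratification, so
    a group of n participants tiles the configured spread and the average of
    their means equals the configured group mean exactly, without Monte-Carlo
    imbalance. Floored at 5% of the group mean so the within-participant
    gamma stays well-defined.
    """
    if sd_b == 0:
        return mean
    if stratum is None:
        value = float(sample_moment_matched(mean, sd_b, 1, rng)[0])
    else:
        idx, n = stratum
        shape = (mean / sd_b) ** 2
        scale = sd_b**2 / mean
        q_lo, q_hi = idx / n, (idx + 1) / n
        x_lo = sps.gamma.ppf(q_lo, shape, scale=scale)
        x_hi = sps.gamma.ppf(q_hi, shape, scale=scale)
        # E[X | x_lo < X < x_hi] via the shape+1 identity for the gamma
        mass = sps.gamma.cdf(x_hi, shape + 1, scale=scale) - sps.gamma.cdf(x_lo, shape + 1, scale=scale)
        value = mean * mass / (q_hi - q_lo)
    return max(value, 0.05 * mean)


def _generate_sleep(cfg: CohortConfig, pid: str, rng) -> list[SleepInterval]:
    sleep = []
    for d in range(cfg.span_days):
        start = (
            cfg.start_epoch
            + d * DAY
            + (cfg.sleep_start_hour + rng.uniform(-cfg.sleep_jitter_hours, cfg.sleep_jitter_hours)) * HOUR
        )
        dur = (cfg.sleep_duration_hours + rng.uniform(-cfg.sleep_jitter_hours, cfg.sleep_jitter_hours)) * HOUR
        sleep.append(SleepInterval(pid, start, start + dur))
    return sleep


def _generate_questionnaires(cfg: CohortConfig, targets: GroupTargets, pid: str, rng, strata=None) -> list:
    strata = strata or {}
    m_lat, sd_lat = targets.questionnaire_latency_hours
    m_gap, sd_gap = targets.questionnaire_interval_hours
    sd_lat_b, sd_lat_w = cfg.split_sd(sd_lat)
    sd_gap_b, sd_gap_w = cfg.split_sd(sd_gap)
    mu_lat = _participant_mean(m_lat, sd_lat_b, rng, strata.get("questionnaire_latency"))
    mu_gap = _participant_mean(m_gap, sd_gap_b, rng, strata.get("questionnaire_interval"))
    wave_days = cfg.wave_days
    if not wave_days:
        return []
    mid_day = float(np.mean(wave_days))
    records = []
    for wave_idx, wave_day in enumerate(wave_days, start=1):
        # centre the injected day slope so the group's overall latency mean
        # stays on target
        wave_mu = max(mu_lat + targets.day_slope_hours * (wave_day - mid_day), 0.05 * m_lat)
        anchor = cfg.start_epoch + wave_day * DAY + 9.0 * HOUR
        last_finished = None
        for q in range(cfg.questionnaires_per_wave):
            name = f"questionnaire_{q + 1}"
            latency_h = float(sample_moment_matched(wave_mu, sd_lat_w, 1, rng)[0])
            if latency_h > cfg.availability_window_hours:
                # never started within the availability window
                notified = anchor if last_finished is None else last_finished
                records.append(QuestionnaireRecord(pid, wave_idx, name, notified))
                continue
            if last_finished is None:
                notified = anchor
                started = anchor + latency_h * HOUR
            else:
                gap_h = (
                    float(sample_moment_matched(mu_gap, sd_gap_w, 1, rng)[0]) if m_gap > 0 else 0.0
                )
                started = last_finished + gap_h * HOUR
                notified = max(started - latency_h * HOUR, 0.0)
            duration = rng.uniform(5.0, 15.0) * 60.0
            finished = started + duration
            records.append(QuestionnaireRecord(pid, wave_idx, name, notified, started, finished))
            last_finished = finished
    # back-computed notification times need not be monotone; keep the stream
    # in its on-disk sort order
    records.sort(key=lambda r: r.notified_at)
    return records


def _exact_sd_deviations(n: int, sd: float, rng) -> np.ndarray:
    """n deviations with mean 0 and sample SD (n−1 denominator) exactly ``sd``:
    balanced ± pairs (plus a zero when n is odd), in shuffled order."""
    k = n // 2
    if k == 0:
        return np.zeros(n)
    a = sd * np.sqrt((n - 1) / (2 * k))
    dev = np.concatenate([np.full(k, a), np.full(k, -a), np.zeros(n - 2 * k)])
    rng.shuffle(dev)
    return dev


def _generate_passive(cfg: CohortConfig, targets: GroupTargets, pid: str, rng, strata=None):
    strata = strata or {}
    m_nlat, sd_nlat = targets.notification_latency_seconds
    m_dur, sd_dur = targets.session_duration_seconds
    m_light, sd_light = targets.light_session_sd_lux
    m_steps, sd_steps = targets.steps_per_session

    sd_nlat_b, sd_nlat_w = cfg.split_sd(sd_nlat)
    sd_dur_b, sd_dur_w = cfg.split_sd(sd_dur)
    sd_light_b, sd_light_w = cfg.split_sd(sd_light)
    sd_steps_b, sd_steps_w = cfg.split_sd(sd_steps)
    mu_nlat = _participant_mean(m_nlat, sd_nlat_b, rng, strata.get("notification_latency"))
    mu_dur = _participant_mean(m_dur, sd_dur_b, rng, strata.get("session_duration"))
    mu_light = _participant_mean(m_light, sd_light_b, rng, strata.get("light"))
    mu_steps = _participant_mean(m_steps, sd_steps_b, rng, strata.get("steps"))
    # participants with faster responses / shorter sessions would otherwise
    # mechanically accumulate more notification cycles; lengthening their
    # waits keeps the cycle rate roughly participant-independent so pooled
    # per-session means are not rate-weighted
    cycle_target = cfg.inter_notification_wait_s + m_nlat + m_dur
    wait_mean = max(120.0, cycle_target - (mu_nlat + mu_dur))

    sleep = _generate_sleep(cfg, pid, rng)
    sleep_starts = np.array([s.start for s in sleep])
    sleep_ends = np.array([s.end for s in sleep])

    def in_sleep(t: float) -> float | None:
        i = np.searchsorted(sleep_starts, t, side="right") - 1
        if i >= 0 and t < sleep_ends[i]:
            return float(sleep_ends[i])
        return None

    span_end = cfg.start_epoch + cfg.span_days * DAY
    notif_packages = SOCIAL_PACKAGES + COMM_PACKAGES
    phone_status = [PhoneStatusEvent(pid, cfg.start_epoch + 6.0 * HOUR, PhoneState.BOOTED)]
    app_events = []
    light = []
    steps = []
    sessions = []  # (start, end), generator-internal

    cursor = float(sleep_ends[0]) if sleep_starts[0] < cfg.start_epoch + 7 * HOUR else cfg.start_epoch + 8.0 * HOUR
    # notification-driven phone-use cycles; the stop rule depends only on the
    # notification time, never on the drawn latency/duration, so the retained
    # draws are unbiased samples of their target distributions
    while True:
        t = cursor + rng.exponential(wait_mean)
        wake_at = in_sleep(t)
        while wake_at is not None:
            t = wake_at + rng.exponential(wait_mean)
            wake_at = in_sleep(t)
        if t >= span_end:
            break
        package = notif_packages[rng.integers(len(notif_packages))]
        category = AppCategory.SOCIAL if package.startswith("app.social") else AppCategory.COMMUNICATION
        app_events.append(AppEvent(pid, t, package, category, AppEventType.OTHER))
        latency = float(sample_moment_matched(mu_nlat, sd_nlat_w, 1, rng)[0])
        unlock = t + latency
        duration = float(sample_moment_matched(mu_dur, sd_dur_w, 1, rng)[0])
        end = unlock + duration
        phone_status.append(PhoneStatusEvent(pid, unlock, PhoneState.UNLOCKED))
        phone_status.append(PhoneStatusEvent(pid, end, PhoneState.STANDBY))
        app_events.append(AppEvent(pid, unlock + 1.0, package, category, AppEventType.FOREGROUND))
        sessions.append((unlock, end))

        # ambient light trace: balanced deviations whose within-session sample
        # SD equals the drawn session-level SD exactly
        # the sensor samples at unlock and then periodically; even short
        # sessions get two samples, so every session yields an SD observation
        session_sd = float(sample_moment_matched(mu_light, sd_light_w, 1, rng)[0])
        n_read = max(int(duration // cfg.light_sampling_interval_s), 2)
        if (n_read - 1) * cfg.light_sampling_interval_s < duration:
            times = unlock + np.arange(n_read) * cfg.light_sampling_interval_s
        else:
            times = unlock + np.linspace(0.0, duration / 2.0, n_read)
        dev = _exact_sd_deviations(n_read, session_sd, rng)
        base = cfg.ambient_light_base_lux + float(np.max(np.abs(dev)))
        for tt, d in zip(times, dev):
            light.append(LightReading(pid, float(tt), float(base + d)))

        # step trace: session total split over minute records inside [start, end)
        total = int(round(float(sample_moment_matched(mu_steps, sd_steps_w, 1, rng)[0])))
        n_rec = max(int(duration // 60.0), 1)
        alloc = rng.multinomial(total, np.full(n_rec, 1.0 / n_rec))
        for k, c in enumerate(alloc):
            steps.append(StepRecord(pid, unlock + 60.0 * k, int(c)))
        cursor = end

    # nighttime notifications (delivered during sleep; the pipeline excludes them)
    for s in sleep:
        for _ in range(rng.poisson(cfg.night_notifications_per_day)):
            t = rng.uniform(s.start, s.end)
            package = notif_packages[rng.integers(len(notif_packages))]
            category = AppCategory.SOCIAL if package.startswith("app.social") else AppCategory.COMMUNICATION
            app_events.append(AppEvent(pid, t, package, category, AppEventType.OTHER))

    # walking steps outside sessions (exercise the containment join)
    s_starts = np.array([a for a, _ in sessions])
    s_ends = np.array([b for _, b in sessions])
    for d in range(cfg.span_days):
        day0 = cfg.start_epoch + d * DAY
        for t in rng.uniform(day0 + 9 * HOUR, day0 + 21 * HOUR, size=cfg.walking_records_per_day):
            i = np.searchsorted(s_starts, t, side="right") - 1
            if i >= 0 and t < s_ends[i]:
                continue  # would fall inside a session and contaminate its total
            steps.append(StepRecord(pid, float(t), int(rng.poisson(cfg.walking_steps_mean))))

    # app-event background: burn-in day absorbs pre-installed packages, then a
    # Poisson number of first-seen ("new") packages per day
    for j, package in enumerate(BASE_PACKAGES + notif_packages):
        t = cfg.start_epoch + 8.0 * HOUR + j * 60.0
        app_events.append(AppEvent(pid, t, package, default_category_map()[package], AppEventType.FOREGROUND))
    new_idx = 0
    for d in range(1, cfg.span_days):
        for _ in range(rng.poisson(targets.new_apps_per_day)):
            t = cfg.start_epoch + d * DAY + rng.uniform(9.0, 21.0) * HOUR
            app_events.append(
                AppEvent(pid, t, f"app.new.{pid}.{new_idx}", AppCategory.OTHER_CATEGORY, AppEventType.FOREGROUND)
            )
            new_idx += 1

    phone_status.sort(key=lambda e: e.timestamp)
    app_events.sort(key=lambda e: e.timestamp)
    light.sort(key=lambda e: e.timestamp)
    steps.sort(key=lambda e: e.timestamp)
    return phone_status, app_events, light, steps, sleep


def generate_participant(
    config: CohortConfig,
    group: Group,
    participant_id: str,
    rng: np.random.Generator,
    include_passive: bool = True,
    include_questionnaires: bool = True,
    strata: dict | None = None,
) -> ParticipantStreams:
    """All raw streams for one participant, mutually consistent.

    ``strata`` optionally maps the :data:`STRATIFIED_KEYS` feature names to a
    ``(index, n)`` slice of the between-participant distribution; cohort-level
    generation uses it to spread participant means evenly.
    """
    targets = config.targets[group]
    questionnaires = (
        _generate_questionnaires(config, targets, participant_id, rng, strata)
        if include_questionnaires
        else []
    )
    if include_passive:
        phone_status, app_events, light, steps, sleep = _generate_passive(
            config, targets, participant_id, rng, strata
        )
    else:
        phone_status, app_events, light, steps, sleep = [], [], [], [], []
    return ParticipantStreams(
        participant_id=participant_id,
        group=group,
        enrollment_epoch=config.start_epoch,
        phone_status=phone_status,
        app_events=app_events,
        light=light,
        steps=steps,
        sleep=sleep,
        questionnaires=questionnaires,
    )


@dataclass
class Cohort:
    config: CohortConfig
    manifest: list
    streams: dict  # participant_id -> ParticipantStreams
    category_map: dict


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    include_passive: bool = True,
    include_questionnaires: bool = True,
) -> Cohort:
    """Generate the full two-group cohort; optionally write it to a directory.

    Deterministic given ``config.seed`` (one spawned RNG stream per
    participant). Directory layout::

        out_dir/
          manifest.csv  category_map.csv  config.yaml
          <participant_id>/{phone_status,app_event,light,steps,sleep,questionnaire}.csv
    """
    ss = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_per_group
    children = ss.spawn(n_total + 1)
    enrollment_date = datetime.fromtimestamp(config.start_epoch, tz=timezone.utc).date().isoformat()

    # independent stratum permutations per group and per feature, so each
    # group's participant means tile their between-participant distribution
    strata_rng = np.random.default_rng(children[-1])
    n = config.n_per_group
    perms = {
        group: {key: strata_rng.permutation(n) for key in STRATIFIED_KEYS}
        for group in (Group.ADHD, Group.COMPARISON)
    }

    manifest = []
    streams = {}
    pids = [(Group.ADHD, i, f"A{i + 1:02d}") for i in range(n)] + [
        (Group.COMPARISON, i, f"C{i + 1:02d}") for i in range(n)
    ]
    for (group, idx, pid), child in zip(pids, children):
        rng = np.random.default_rng(child)
        strata = (
            {key: (int(perms[group][key][idx]), n) for key in STRATIFIED_KEYS}
            if config.stratify_participants
            else None
        )
        streams[pid] = generate_participant(
            config, group, pid, rng, include_passive=include_passive,
            include_questionnaires=include_questionnaires, strata=strata,
        )
        manifest.append(ManifestEntry(pid, group, enrollment_date))

    cohort = Cohort(config, manifest, streams, default_category_map())
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {out_dir} is not empty (pass overwrite=True)")
        out_dir.mkdir(parents=True, exist_ok=True)
        write_manifest(manifest, out_dir / "manifest.csv")
        write_category_map(cohort.category_map, out_dir / "category_map.csv")
        config.to_yaml(out_dir / "config.yaml")
        for pid, ps in streams.items():
            pdir = out_dir / pid
            write_stream(ps.phone_status, pdir / "phone_status.csv", StreamKind.PHONE_STATUS)
            write_stream(ps.app_events, pdir / "app_event.csv", StreamKind.APP_EVENT)
            write_stream(ps.light, pdir / "light.csv", StreamKind.LIGHT)
            write_stream(ps.steps, pdir / "steps.csv", StreamKind.STEPS)
            write_stream(ps.sleep, pdir / "sleep.csv", StreamKind.SLEEP)
            write_stream(ps.questionnaires, pdir / "questionnaire.csv", StreamKind.QUESTIONNAIRE)
    return cohort


def load_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`generate_cohort`."""
    from .events import read_category_map, read_manifest, read_stream

    in_dir = Path(in_dir)
    manifest = read_manifest(in_dir / "manifest.csv")
    category_map = read_category_map(in_dir / "category_map.csv")
    config = CohortConfig.from_yaml(in_dir / "config.yaml")
    streams = {}
    for entry in manifest:
        pdir = in_dir / entry.participant_id
        streams[entry.participant_id] = ParticipantStreams(
            participant_id=entry.participant_id,
            group=entry.group,
            enrollment_epoch=config.start_epoch,
            phone_status=read_stream(pdir / "phone_status.csv", StreamKind.PHONE_STATUS),
            app_events=read_stream(pdir / "app_event.csv", StreamKind.APP_EVENT),
            light=read_stream(pdir / "light.csv", StreamKind.LIGHT),
            steps=read_stream(pdir / "steps.csv", StreamKind.STEPS),
            sleep=read_stream(pdir / "sleep.csv", StreamKind.SLEEP),
            questionnaires=read_stream(pdir / "questionnaire.csv", StreamKind.QUESTIONNAIRE),
        )
    return Cohort(config, manifest, streams, category_map)
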