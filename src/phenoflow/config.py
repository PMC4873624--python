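"""Study configuration: the file-and-code replacement for a study portal.

A :class:`StudyConfig` captures everything that customizes a study — which
passive sensor streams are collected and on what duty cycles, the survey
battery and its schedules, app text, emergency contacts, and the study
public key — in one canonical JSON document. Storing this file alongside
the collected raw data is what makes a study reproducible: a validation
study re-runs with the exact same settings.

Validation is deliberately separate from parsing: :func:`load_config`
raises :class:`ConfigFormatError` only for unreadable/unparseable files,
while :func:`validate_config` returns a list of human-readable violations
so a study coordinator sees every problem at once.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import random
import re
from enum import Enum
from pathlib import Path
from zoneinfo import ZoneInfo

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "StreamName",
    "QuestionType",
    "SensorSetting",
    "SurveyQuestion",
    "SurveySchedule",
    "Survey",
    "StudyConfig",
    "ConfigFormatError",
    "ConfigValidationError",
    "validate_config",
    "expand_schedule",
    "generate_participant_id",
    "default_config",
    "load_config",
    "save_config",
    "config_digest",
]


class ConfigFormatError(Exception):
    """The config file could not be read or parsed (distinct from invalid)."""


class ConfigValidationError(Exception):
    """A config failed invariant validation; carries the violation list."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class StreamName(str, Enum):
    gps = "gps"
    accelerometer = "accelerometer"
    calls = "calls"
    texts = "texts"
    wifi = "wifi"
    bluetooth = "bluetooth"
    power_state = "power_state"
    audio = "audio"


#: streams that sample on a duty cycle (nominal_rate applies)
SAMPLED_STREAMS = {StreamName.gps, StreamName.accelerometer}
#: streams that scan on a duty cycle without a sampling rate
SCANNED_STREAMS = {StreamName.wifi, StreamName.bluetooth}


class QuestionType(str, Enum):
    checkbox = "checkbox"
    radio = "radio"
    slider = "slider"
    free_response = "free_response"


class SensorSetting(BaseModel):
    model_config = ConfigDict(frozen=True)

    stream_name: StreamName
    enabled: bool = True
    on_duration: float = 60.0  # seconds per duty cycle the sensor is on
    off_duration: float = 0.0  # seconds per duty cycle the sensor is off
    nominal_rate: float = 1.0  # Hz, samplers only; event streams ignore it

    @property
    def cycle_seconds(self) -> float:
        return self.on_duration + self.off_duration


class SurveyQuestion(BaseModel):
    model_config = ConfigDict(frozen=True)

    question_id: str
    qtype: QuestionType
    text: str
    options: list[str] = Field(default_factory=list)
    slider_min: int = 0
    slider_max: int = 10


class SurveySchedule(BaseModel):
    model_config = ConfigDict(frozen=True)

    period_days: int = 1  # 1 = daily; 14 = biweekly read as fortnightly
    prompt_time: str = "19:00"  # local HH:MM in the study timezone
    anchor: dt.date = dt.date(2024, 1, 1)  # study start date


class Survey(BaseModel):
    model_config = ConfigDict(frozen=True)

    survey_id: str
    questions: list[SurveyQuestion]
    schedule: SurveySchedule


class StudyConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_id: str
    timezone: str = "UTC"
    sensor_settings: list[SensorSetting]
    surveys: list[Survey] = Field(default_factory=list)
    audio_max_duration: float = 240.0  # seconds
    audio_prompt_time: str = "19:30"  # local HH:MM daily voice-diary prompt
    app_texts: dict[str, str] = Field(default_factory=dict)
    emergency_contacts: list[str] = Field(default_factory=list)
    public_key_ref: str | None = None
    config_version: str = "1"

    def sensor(self, stream: StreamName | str) -> SensorSetting | None:
        stream = StreamName(stream)
        for s in self.sensor_settings:
            if s.stream_name == stream:
                return s
        return None

    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)


_TIME_RE = re.compile(r"^([01]\d|2[0-3]):([0-5]\d)$")


def _check_time(label: str, value: str, out: list[str]) -> None:
    if not _TIME_RE.match(value):
        out.append(f"{label}: {value!r} is not a valid HH:MM time of day")


def validate_config(cfg: StudyConfig) -> list[str]:
    """Return every invariant violation in ``cfg`` (empty list = valid)."""
    v: list[str] = []
    if not cfg.study_id:
        v.append("study_id: must be non-empty")
    try:
        ZoneInfo(cfg.timezone)
    except Exception:
        v.append(f"timezone: unknown timezone {cfg.timezone!r}")

    seen_streams: set[StreamName] = set()
    for s in cfg.sensor_settings:
        name = s.stream_name.value
        if s.stream_name in seen_streams:
            v.append(f"sensor_settings.{name}: duplicate stream_name")
        seen_streams.add(s.stream_name)
        if s.on_duration <= 0:
            v.append(f"sensor_settings.{name}.on_duration: must be > 0")
        if s.off_duration < 0:
            v.append(f"sensor_settings.{name}.off_duration: must be >= 0")
        if s.on_duration + s.off_duration <= 0:
            v.append(f"sensor_settings.{name}: on_duration + off_duration must be > 0")
        if s.stream_name in SAMPLED_STREAMS and s.nominal_rate <= 0:
            v.append(f"sensor_settings.{name}.nominal_rate: must be > 0")

    seen_surveys: set[str] = set()
    for survey in cfg.surveys:
        sid = survey.survey_id
        if sid in seen_surveys:
            v.append(f"surveys.{sid}: duplicate survey_id")
        seen_surveys.add(sid)
        if survey.schedule.period_days < 1:
            v.append(f"surveys.{sid}.schedule.period_days: must be >= 1")
        _check_time(f"surveys.{sid}.schedule.prompt_time", survey.schedule.prompt_time, v)
        for q in survey.questions:
            qid = f"surveys.{sid}.questions.{q.question_id}"
            if q.qtype in (QuestionType.checkbox, QuestionType.radio):
                if len(q.options) < 2:
                    v.append(f"{qid}.options: {q.qtype.value} needs >= 2 options")
            if q.qtype == QuestionType.slider and q.slider_min >= q.slider_max:
                v.append(f"{qid}: slider_min must be < slider_max")
            if q.qtype == QuestionType.free_response and q.options:
                v.append(f"{qid}.options: free_response takes no options")

    if cfg.audio_max_duration <= 0:
        v.append("audio_max_duration: must be > 0")
    _check_time("audio_prompt_time", cfg.audio_prompt_time, v)
    return v


def require_valid(cfg: StudyConfig) -> None:
    """Raise :class:`ConfigValidationError` if ``cfg`` has violations.

    Downstream modules (simulator, transport) call this so an invalid
    config is refused everywhere, not just at authoring time.
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigValidationError(violations)


def expand_schedule(
    schedule: SurveySchedule,
    window_start: dt.date,
    window_end: dt.date,
    tz: str | ZoneInfo = "UTC",
) -> list[dt.datetime]:
    """All prompt instants of ``schedule`` inside [window_start, window_end).

    Prompts occur every ``period_days`` days from the anchor date at
    ``prompt_time`` in the study timezone; the returned datetimes are UTC,
    ascending. The window is a half-open date interval, so an empty window
    (start == end) yields no prompts.
    """
    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    tzinfo = ZoneInfo(tz) if isinstance(tz, str) else tz
    hh, mm = (int(p) for p in schedule.prompt_time.split(":"))
    period = schedule.period_days

    delta = (window_start - schedule.anchor).days
    k = max(0, -(-delta // period))  # first period index with date >= window_start
    out: list[dt.datetime] = []
    while True:
        day = schedule.anchor + dt.timedelta(days=k * period)
        if day >= window_end:
            break
        local = dt.datetime(day.year, day.month, day.day, hh, mm, tzinfo=tzinfo)
        out.append(local.astimezone(dt.timezone.utc))
        k += 1
    return out


_ID_ALPHABET = "abcdefghijklmnopqrstuvwxyz0123456789"
_ID_LENGTH = 8


def generate_participant_id(study: StudyConfig, rng_seed: int) -> str:
    """Deterministic 8-character participant ID for (study, seed).

    The ID carries no information about the subject; it is the only link
    between a person and their data, held outside the platform.
    """
    digest = hashlib.sha256(f"{study.study_id}:{rng_seed}".encode()).digest()
    rng = random.Random(int.from_bytes(digest[:8], "big"))
    return "".join(rng.choice(_ID_ALPHABET) for _ in range(_ID_LENGTH))


def default_config(study_id: str = "demo-study") -> StudyConfig:
    """A fully specified default study.

    Passive defaults: GPS on 60 s / off 540 s at 1 Hz in motion;
    accelerometer on 60 s / off 60 s at 20 Hz; Bluetooth scanned for
    1 min every 5 min; Wi-Fi recorded instantaneously every 5 min.
    The survey battery mirrors a typical deployment: a short daily
    check-in plus a longer fortnightly battery, and a daily voice diary.
    """
    slider = lambda qid, text: SurveyQuestion(  # noqa: E731
        question_id=qid, qtype=QuestionType.slider, text=text,
        slider_min=0, slider_max=10,
    )
    daily = Survey(
        survey_id="daily_checkin",
        schedule=SurveySchedule(period_days=1, prompt_time="19:00"),
        questions=[
            slider("mood", "How is your mood right now? (0 worst - 10 best)"),
            SurveyQuestion(
                question_id="sleep_quality", qtype=QuestionType.radio,
                text="How did you sleep last night?",
                options=["very poorly", "poorly", "fine", "well", "very well"],
            ),
            SurveyQuestion(
                question_id="symptoms_today", qtype=QuestionType.checkbox,
                text="Which of these did you notice today?",
                options=["low energy", "trouble focusing", "restlessness",
                         "social withdrawal", "none of these"],
            ),
            SurveyQuestion(
                question_id="notes", qtype=QuestionType.free_response,
                text="Anything else you want to note?",
            ),
        ],
    )
    fortnightly = Survey(
        survey_id="fortnightly_battery",
        schedule=SurveySchedule(period_days=14, prompt_time="18:00"),
        questions=[
            slider("overall_wellbeing", "Overall wellbeing over the last two weeks"),
            slider("anxiety", "How anxious have you felt over the last two weeks?"),
            slider("sleep_overall", "Sleep quality over the last two weeks"),
        ],
    )
    return StudyConfig(
        study_id=study_id,
        timezone="UTC",
        sensor_settings=[
            SensorSetting(stream_name=StreamName.gps, on_duration=60, off_duration=540, nominal_rate=1.0),
            SensorSetting(stream_name=StreamName.accelerometer, on_duration=60, off_duration=60, nominal_rate=20.0),
            SensorSetting(stream_name=StreamName.calls, on_duration=86400, off_duration=0),
            SensorSetting(stream_name=StreamName.texts, on_duration=86400, off_duration=0),
            SensorSetting(stream_name=StreamName.wifi, on_duration=1, off_duration=299),
            SensorSetting(stream_name=StreamName.bluetooth, on_duration=60, off_duration=240),
            SensorSetting(stream_name=StreamName.power_state, on_duration=86400, off_duration=0),
            SensorSetting(stream_name=StreamName.audio, on_duration=86400, off_duration=0),
        ],
        surveys=[daily, fortnightly],
        audio_max_duration=240.0,
        app_texts={
            "welcome": "Thank you for taking part in this study.",
            "audio_prompt": "Please record a short voice diary about your day.",
            "about": "This app collects sensor and usage data for research.",
        },
        emergency_contacts=["+1-617-555-0100"],
        public_key_ref=None,
        config_version="1",
    )


def _to_canonical_json(cfg: StudyConfig) -> str:
    data = json.loads(cfg.model_dump_json())
    return json.dumps(data, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    """Write canonical JSON (sorted keys, 2-space indent, UTF-8)."""
    Path(path).write_text(_to_canonical_json(cfg), encoding="utf-8")


def load_config(path: str | Path) -> StudyConfig:
    """Parse a config file; raises :class:`ConfigFormatError` if unreadable."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigFormatError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigFormatError(f"config file {path} is not valid JSON: {exc}") from exc
    try:
        return StudyConfig.model_validate(data)
    except Exception as exc:
        raise ConfigFormatError(f"config file {path} has wrong structure: {exc}") from exc


def config_digest(cfg: StudyConfig) -> str:
    """SHA-256 of the canonical serialization, for manifests and audit."""
    return hashlib.sha256(_to_canonical_json(cfg).encode("utf-8")).hexdigest()
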