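"""Derived per-participant metrics from ingested streams.

These are the summaries the platform surfaces directly, upstream of any
statistical modeling: survey response latency (notification to first
interaction), the previous-week series of numerically quantifiable survey
answers, a coarse nightly sleep proxy from screen events, per-stream daily
coverage as a data-quality measure, and daily communication counts.

All summaries are pure functions of ingested records plus the study
config, so recomputation is deterministic and re-analysis reproduces the
original numbers exactly.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import QuestionType, StreamName, StudyConfig
from .simulator import DAY_SECONDS, duty_cycle_windows, _hhmm_seconds

__all__ = [
    "survey_latency",
    "weekly_numeric_series",
    "sleep_proxy",
    "stream_coverage",
    "daily_comm_counts",
    "SummaryReport",
    "build_report",
]

WEEK_MS = 7 * 24 * 3600 * 1000


def survey_latency(responses: pd.DataFrame) -> pd.DataFrame:
    """Seconds from survey notification to first interaction, per response.

    One row per (survey_id, notification_time) prompt. Records whose start
    precedes their notification are physically impossible; they are
    flagged and excluded rather than clipped.
    """
    cols = ["survey_id", "notification_time", "latency_seconds", "flagged"]
    if responses.empty:
        return pd.DataFrame(columns=cols)
    prompts = responses.groupby(["survey_id", "notification_time"], as_index=False).agg(
        start_time=("start_time", "min")
    )
    latency = (prompts["start_time"] - prompts["notification_time"]) / 1000.0
    out = pd.DataFrame(
        {
            "survey_id": prompts["survey_id"],
            "notification_time": prompts["notification_time"],
            "latency_seconds": latency.where(latency >= 0),
            "flagged": latency < 0,
        }
    )
    return out[cols]


def _radio_index(cfg: StudyConfig, survey_id: str, question_id: str, answer: str) -> float:
    for survey in cfg.surveys:
        if survey.survey_id != survey_id:
            continue
        for q in survey.questions:
            if q.question_id == question_id and answer in q.options:
                return float(q.options.index(answer))
    return float("nan")


def weekly_numeric_series(
    responses: pd.DataFrame, cfg: StudyConfig, reference_time_ms: int
) -> dict[str, pd.DataFrame]:
    """Numeric answers from the rolling 168 h before ``reference_time_ms``.

    Slider answers are used as-is; radio answers map to their 0-based
    option index. Checkbox and free-response questions have no natural
    scalar and are excluded. Keyed by "survey_id/question_id".
    """
    out: dict[str, pd.DataFrame] = {}
    if responses.empty:
        return out
    window = responses[
        (responses["start_time"] >= reference_time_ms - WEEK_MS)
        & (responses["start_time"] < reference_time_ms)
    ]
    numeric = window[window["qtype"].isin([QuestionType.slider.value, QuestionType.radio.value])]
    for (sid, qid), group in numeric.groupby(["survey_id", "question_id"]):
        values = [
            float(row.answer)
            if row.qtype == QuestionType.slider.value
            else _radio_index(cfg, sid, qid, row.answer)
            for row in group.itertuples()
        ]
        series = pd.DataFrame(
            {"time": group["start_time"].to_numpy(), "value": values}
        ).sort_values("time", kind="stable").reset_index(drop=True)
        out[f"{sid}/{qid}"] = series
    return out


def sleep_proxy(
    power_state: pd.DataFrame,
    night_window: tuple[str, str] = ("22:00", "10:00"),
    tz: str = "UTC",
) -> pd.DataFrame:
    """Nightly sleep duration and quality proxies from screen events.

    For each night window (possibly spanning midnight), the sleep-duration
    proxy is the longest gap in hours between consecutive screen-use
    events (screen_on or screen_touch), bounded by the window edges; a
    night with no events yields the full window length. The quality proxy
    is the number of screen-use episodes (screen_on events) in the window.
    """
    tzinfo = ZoneInfo(tz)
    w0 = _hhmm_seconds(night_window[0])
    w1 = _hhmm_seconds(night_window[1])
    use = power_state[power_state["event"].isin(["screen_on", "screen_touch"])] if len(
        power_state
    ) else power_state

    if len(power_state):
        stamps = pd.to_datetime(power_state["timestamp"], unit="ms", utc=True).dt.tz_convert(tzinfo)
        dates = sorted(stamps.dt.date.unique())
    else:
        dates = []

    rows = []
    for date in dates:
        start_local = dt.datetime.combine(date, dt.time(w0 // 3600, (w0 % 3600) // 60), tzinfo=tzinfo)
        span = (w1 - w0) if w1 > w0 else (DAY_SECONDS - w0 + w1)
        start_ms = int(start_local.astimezone(dt.timezone.utc).timestamp() * 1000)
        end_ms = start_ms + span * 1000
        if len(use):
            in_win = use[(use["timestamp"] >= start_ms) & (use["timestamp"] < end_ms)]
            events = np.sort(in_win["timestamp"].to_numpy())
        else:
            in_win = use
            events = np.array([], dtype=np.int64)
        edges = np.concatenate(([start_ms], events, [end_ms]))
        longest_gap_h = float(np.max(np.diff(edges))) / 3_600_000.0
        episodes = int((in_win["event"] == "screen_on").sum()) if len(events) else 0
        rows.append(
            {
                "night": date.isoformat(),
                "sleep_hours": longest_gap_h,
                "use_episodes": episodes,
            }
        )
    return pd.DataFrame(rows, columns=["night", "sleep_hours", "use_episodes"])


def stream_coverage(
    records: pd.DataFrame,
    cfg: StudyConfig,
    stream: StreamName | str,
    day: dt.date,
) -> float | None:
    """Fraction of the day's expected on-windows containing >= 1 record.

    Returns None for a disabled stream: "turned off" is different from
    "expected but missing", and a dashboard must not show it as 0.
    """
    stream = StreamName(stream)
    setting = cfg.sensor(stream)
    if setting is None or not setting.enabled:
        return None
    tzinfo = cfg.tzinfo()
    day_start = dt.datetime.combine(day, dt.time(0), tzinfo=tzinfo)
    day_start_ms = int(day_start.astimezone(dt.timezone.utc).timestamp() * 1000)
    windows = duty_cycle_windows(setting.on_duration, setting.off_duration, DAY_SECONDS)
    if not windows:
        return None
    ts = records["timestamp"].to_numpy() if len(records) else np.array([], dtype=np.int64)
    hit = 0
    for w0, w1 in windows:
        lo = day_start_ms + int(w0 * 1000)
        hi = day_start_ms + int(w1 * 1000)
        if np.any((ts >= lo) & (ts < hi)):
            hit += 1
    return hit / len(windows)


def daily_comm_counts(
    calls: pd.DataFrame, texts: pd.DataFrame, tz: str = "UTC"
) -> pd.DataFrame:
    """Calls and texts per local calendar day (a social-activity marker)."""
    tzinfo = ZoneInfo(tz)

    def per_day(df: pd.DataFrame, label: str) -> pd.Series:
        if df is None or df.empty:
            return pd.Series(dtype=int, name=label)
        days = (
            pd.to_datetime(df["timestamp"], unit="ms", utc=True)
            .dt.tz_convert(tzinfo)
            .dt.date.astype(str)
        )
        return days.value_counts().sort_index().rename(label)

    out = pd.concat([per_day(calls, "calls"), per_day(texts, "texts")], axis=1)
    out = out.fillna(0).astype(int)
    out.index.name = "day"
    return out.reset_index()


@dataclass
class SummaryReport:
    """Per-participant derived metrics, serializable to JSON."""

    participant_id: str
    latency: pd.DataFrame
    weekly_series: dict[str, pd.DataFrame]
    sleep: pd.DataFrame
    coverage: dict[str, dict[str, float]]  # stream -> day -> fraction
    comm_counts: pd.DataFrame
    generated_from: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "survey_latency": self.latency.to_dict(orient="records"),
            "weekly_numeric_series": {
                k: v.to_dict(orient="records") for k, v in sorted(self.weekly_series.items())
            },
            "sleep_proxy": self.sleep.to_dict(orient="records"),
            "stream_coverage": self.coverage,
            "daily_comm_counts": self.comm_counts.to_dict(orient="records"),
            "generated_from": self.generated_from,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def build_report(
    server,
    cfg: StudyConfig,
    participant_id: str,
    night_window: tuple[str, str] = ("22:00", "10:00"),
) -> SummaryReport:
    """Assemble the full summary report from a server's ingested store."""
    responses = server.load_records(participant_id, "survey_responses")
    power = server.load_records(participant_id, "power_state")
    calls = server.load_records(participant_id, "calls")
    texts = server.load_records(participant_id, "texts")

    all_ts = [
        df["timestamp"].max()
        for df in (power, calls, texts)
        if len(df) and "timestamp" in df.columns
    ]
    if len(responses):
        all_ts.append(responses["end_time"].max())
    reference = int(max(all_ts)) + 1 if all_ts else 0

    coverage: dict[str, dict[str, float]] = {}
    days: set[dt.date] = set()
    tzinfo = cfg.tzinfo()
    for df in (power, calls, texts):
        if len(df):
            local = pd.to_datetime(df["timestamp"], unit="ms", utc=True).dt.tz_convert(tzinfo)
            days.update(local.dt.date.unique())
    for stream in ("gps", "accelerometer", "wifi", "bluetooth", "power_state"):
        setting = cfg.sensor(stream)
        if setting is None or not setting.enabled:
            continue
        records = server.load_records(participant_id, stream)
        if len(records):
            local = pd.to_datetime(records["timestamp"], unit="ms", utc=True).dt.tz_convert(tzinfo)
            days.update(local.dt.date.unique())
        per_day = {}
        for day in sorted(days):
            frac = stream_coverage(records, cfg, stream, day)
            if frac is not None:
                per_day[day.isoformat()] = round(frac, 4)
        if per_day:
            coverage[stream] = per_day

    return SummaryReport(
        participant_id=participant_id,
        latency=survey_latency(responses),
        weekly_series=weekly_numeric_series(responses, cfg, reference),
        sleep=sleep_proxy(power, night_window, cfg.timezone),
        coverage=coverage,
        comm_counts=daily_comm_counts(calls, texts, cfg.timezone),
        generated_from={"reference_time_ms": reference},
    )
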