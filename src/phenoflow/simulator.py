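"""Synthetic smartphone: a scripted subject emitting raw data streams.

The simulator stands in for the phone app's data collection engine. A
:class:`BehaviorProfile` scripts one subject's day — where they are and
when (home/work anchors with transits), who they call and text, which
Wi-Fi networks and Bluetooth devices surround them, how often they touch
the screen, and how quickly they respond to survey prompts. From the
profile and a :class:`~phenoflow.config.StudyConfig`, :func:`simulate_period`
emits each enabled stream with its documented schema and duty-cycled
sampling behavior, one CSV per stream per hour.

The generator is fully seeded: identical (config, profile, seed) produce
byte-identical output trees, which is what makes downstream transport and
summary tests exact. The behavioral model is deliberately parametric —
fixed anchors, constant-speed great-circle transits, Poisson communication
— realistic enough to exercise schemas, duty cycles, and summary recovery,
not a human-mobility model.
"""

from __future__ import annotations

import datetime as dt
import io
import json
import math
import struct
import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import privacy, streams
from .config import (
    QuestionType,
    StreamName,
    StudyConfig,
    Survey,
    expand_schedule,
    require_valid,
)

__all__ = [
    "AnchorLocation",
    "RoutineSegment",
    "Contact",
    "WirelessDevice",
    "BehaviorProfile",
    "ProfileError",
    "default_profile",
    "validate_profile",
    "duty_cycle_windows",
    "sample_gps",
    "sample_accelerometer",
    "scan_wireless",
    "generate_comm_events",
    "take_survey",
    "record_audio",
    "simulate_period",
    "SimulationResult",
    "count_scalar_observations",
    "GPS_NOISE_SD_M",
    "GPS_STATIONARY_KEEP_P",
]

DAY_SECONDS = 86400
EARTH_RADIUS_M = 6_371_000.0
METERS_PER_DEG_LAT = 111_320.0

#: default isotropic GPS noise (meters per horizontal axis); sized so the
#: 90th-percentile horizontal error sigma*sqrt(2 ln 10) ~ 15.0 m stays
#: inside the 30-50 ft accuracy envelope typical of phone GPS fixes
GPS_NOISE_SD_M = 7.0
#: probability a stationary-period GPS tick survives OS throttling emulation
GPS_STATIONARY_KEEP_P = 0.5
#: mean Bluetooth detections of a present device per 60 s scan window
BT_DETECTIONS_PER_WINDOW = 3.0

ACCEL_RATE_MIN_HZ = 5.0
ACCEL_RATE_MAX_HZ = 100.0
GRAVITY = 9.81


class ProfileError(Exception):
    """The behavior profile is internally inconsistent."""


class AnchorLocation(BaseModel):
    model_config = ConfigDict(frozen=True)
    label: str
    latitude: float
    longitude: float


class RoutineSegment(BaseModel):
    model_config = ConfigDict(frozen=True)
    kind: str  # "stay" | "transit"
    start: str  # local HH:MM
    end: str  # local HH:MM, "24:00" allowed
    location: str | None = None  # stay
    from_location: str | None = None  # transit
    to_location: str | None = None  # transit
    activity: str = "rest"  # rest | walking | transit


class Contact(BaseModel):
    model_config = ConfigDict(frozen=True)
    number: str
    call_rate: float = 1.0  # calls/day exchanged with this contact
    text_rate: float = 5.0  # texts/day


class WirelessDevice(BaseModel):
    model_config = ConfigDict(frozen=True)
    mac: str
    windows: list[tuple[str, str]]  # local (start, end) presence windows
    rssi_base: int = -60  # dBm


class BehaviorProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    anchor_locations: list[AnchorLocation]
    daily_routine: list[RoutineSegment]
    contact_pool: list[Contact] = Field(default_factory=list)
    bluetooth_environment: list[WirelessDevice] = Field(default_factory=list)
    wifi_environment: list[WirelessDevice] = Field(default_factory=list)
    screen_sessions_per_day: float = 60.0
    night_window: tuple[str, str] = ("22:00", "10:00")  # analysis window
    quiet_hours: tuple[str, str] = ("23:30", "07:30")  # scripted no-use sleep
    survey_latency_log_mu: float = 5.0  # log-seconds; median exp(mu)
    survey_latency_log_sigma: float = 0.5
    audio_accept_probability: float = 0.9
    rng_seed: int = 0


def _hhmm_seconds(value: str) -> int:
    if value == "24:00":
        return DAY_SECONDS
    hh, mm = value.split(":")
    return int(hh) * 3600 + int(mm) * 60


def validate_profile(profile: BehaviorProfile) -> None:
    """Check that routine segments tile 24 h without gap or overlap."""
    labels = {a.label for a in profile.anchor_locations}
    segs = sorted(profile.daily_routine, key=lambda s: _hhmm_seconds(s.start))
    if not segs:
        raise ProfileError("daily_routine is empty")
    cursor = 0
    for seg in segs:
        s, e = _hhmm_seconds(seg.start), _hhmm_seconds(seg.end)
        if s != cursor:
            raise ProfileError(
                f"routine segments must tile the day: gap/overlap at {seg.start}"
            )
        if e <= s:
            raise ProfileError(f"segment {seg.start}-{seg.end} has nonpositive length")
        refs = [seg.location] if seg.kind == "stay" else [seg.from_location, seg.to_location]
        for ref in refs:
            if ref not in labels:
                raise ProfileError(f"segment references unknown anchor {ref!r}")
        cursor = e
    if cursor != DAY_SECONDS:
        raise ProfileError("routine segments must cover the full day up to 24:00")
    for c in profile.contact_pool:
        if c.call_rate < 0 or c.text_rate < 0:
            raise ProfileError(f"contact {c.number}: rates must be >= 0")


def default_profile(rng_seed: int = 0) -> BehaviorProfile:
    """A plausible urban weekday: home, a 30-min walking commute, work."""
    return BehaviorProfile(
        anchor_locations=[
            AnchorLocation(label="home", latitude=42.3601, longitude=-71.0589),
            AnchorLocation(label="work", latitude=42.3736, longitude=-71.1097),
        ],
        daily_routine=[
            RoutineSegment(kind="stay", start="00:00", end="08:00", location="home", activity="rest"),
            RoutineSegment(kind="transit", start="08:00", end="08:30", from_location="home", to_location="work", activity="walking"),
            RoutineSegment(kind="stay", start="08:30", end="17:00", location="work", activity="rest"),
            RoutineSegment(kind="transit", start="17:00", end="17:30", from_location="work", to_location="home", activity="walking"),
            RoutineSegment(kind="stay", start="17:30", end="24:00", location="home", activity="rest"),
        ],
        contact_pool=[
            Contact(number="+16175550101", call_rate=1.5, text_rate=10.0),
            Contact(number="+16175550102", call_rate=0.8, text_rate=6.0),
            Contact(number="+16175550103", call_rate=0.4, text_rate=3.0),
            Contact(number="+16175550104", call_rate=0.2, text_rate=1.5),
        ],
        bluetooth_environment=[
            WirelessDevice(mac="aa:bb:cc:00:00:01", windows=[("00:00", "08:30"), ("17:00", "24:00")], rssi_base=-55),
            WirelessDevice(mac="aa:bb:cc:00:00:02", windows=[("09:00", "17:00")], rssi_base=-65),
            WirelessDevice(mac="aa:bb:cc:00:00:03", windows=[("12:00", "13:00")], rssi_base=-75),
        ],
        wifi_environment=[
            WirelessDevice(mac="10:20:30:40:50:01", windows=[("00:00", "08:30"), ("17:00", "24:00")], rssi_base=-45),
            WirelessDevice(mac="10:20:30:40:50:02", windows=[("00:00", "24:00")], rssi_base=-80),
            WirelessDevice(mac="10:20:30:40:50:03", windows=[("08:30", "17:00")], rssi_base=-50),
            WirelessDevice(mac="10:20:30:40:50:04", windows=[("08:30", "17:00")], rssi_base=-70),
        ],
        screen_sessions_per_day=60.0,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Ground truth trajectory


def _slerp(a_lat, a_lon, b_lat, b_lon, frac):
    """Great-circle interpolation between two points, fraction in [0, 1]."""

    def unit(lat, lon):
        la, lo = math.radians(lat), math.radians(lon)
        return np.array(
            [math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)]
        )

    u, v = unit(a_lat, a_lon), unit(b_lat, b_lon)
    omega = math.acos(max(-1.0, min(1.0, float(np.dot(u, v)))))
    if omega < 1e-9:
        p = u
    else:
        p = (math.sin((1 - frac) * omega) * u + math.sin(frac * omega) * v) / math.sin(omega)
    lat = math.degrees(math.asin(max(-1.0, min(1.0, p[2]))))
    lon = math.degrees(math.atan2(p[1], p[0]))
    return lat, lon


def make_position_fn(
    profile: BehaviorProfile,
) -> Callable[[float], tuple[float, float, bool, str]]:
    """Map local second-of-day -> (lat, lon, in_motion, activity)."""
    anchors = {a.label: a for a in profile.anchor_locations}
    segs = sorted(profile.daily_routine, key=lambda s: _hhmm_seconds(s.start))
    bounds = [(_hhmm_seconds(s.start), _hhmm_seconds(s.end), s) for s in segs]

    def position(sec: float) -> tuple[float, float, bool, str]:
        sec = sec % DAY_SECONDS
        for s, e, seg in bounds:
            if s <= sec < e:
                if seg.kind == "stay":
                    a = anchors[seg.location]
                    return a.latitude, a.longitude, False, seg.activity
                a, b = anchors[seg.from_location], anchors[seg.to_location]
                frac = (sec - s) / (e - s)
                lat, lon = _slerp(a.latitude, a.longitude, b.latitude, b.longitude, frac)
                return lat, lon, True, seg.activity
        raise ProfileError(f"no routine segment covers second {sec}")

    return position


def duty_cycle_windows(on: float, off: float, total: float) -> list[tuple[float, float]]:
    """On-windows [(start, end), ...] of an on/off duty cycle over [0, total)."""
    cycle = on + off
    out = []
    t = 0.0
    while t < total:
        out.append((t, min(t + on, total)))
        t += cycle
    return out


# ---------------------------------------------------------------------------
# Passive stream samplers


def sample_gps(
    position_fn: Callable[[float], tuple[float, float, bool, str]],
    on_windows: list[tuple[float, float]],
    rng: np.random.Generator,
    rate_in_motion: float = 1.0,
    noise_sd: float = GPS_NOISE_SD_M,
    stationary_keep_p: float = GPS_STATIONARY_KEEP_P,
    day_start_ms: int = 0,
) -> pd.DataFrame:
    """GPS fixes inside on-windows: 1 Hz nominal while in motion.

    Stationary ticks are thinned with ``stationary_keep_p`` to emulate the
    operating system suppressing queries for a phone it infers is not
    moving. Horizontal noise is isotropic Gaussian with ``noise_sd`` meters
    per axis around the ground-truth position.
    """
    rows: list[tuple[int, float, float]] = []
    for w0, w1 in on_windows:
        t = math.ceil(w0)
        while t < w1:
            lat, lon, moving, _ = position_fn(t)
            if moving or rng.random() < stationary_keep_p:
                rows.append((t, lat, lon))
            t += 1.0 / rate_in_motion
    if not rows:
        return pd.DataFrame(columns=list(streams.SCHEMAS["gps"].columns))
    arr = np.array(rows)
    n = len(arr)
    lat = arr[:, 1]
    dn = rng.normal(0.0, noise_sd, n)
    de = rng.normal(0.0, noise_sd, n)
    lat_noisy = lat + dn / METERS_PER_DEG_LAT
    lon_noisy = arr[:, 2] + de / (METERS_PER_DEG_LAT * np.cos(np.radians(lat)))
    accuracy = np.round(rng.uniform(5.0, 15.0, n), 1)
    return pd.DataFrame(
        {
            "timestamp": day_start_ms + (arr[:, 0] * 1000).astype(np.int64),
            "latitude": lat_noisy,
            "longitude": lon_noisy,
            "accuracy": accuracy,
        }
    )


def sample_accelerometer(
    activity_fn: Callable[[float], str],
    on_windows: list[tuple[float, float]],
    rng: np.random.Generator,
    rate: float = 20.0,
    noise_sd: float = 0.05,
    day_start_ms: int = 0,
) -> pd.DataFrame:
    """Tri-axial acceleration (m/s^2) sampled at ``rate`` Hz in on-windows.

    At rest the signal is gravity on the z axis plus sensor noise; walking
    superimposes a ~1.9 Hz periodic vertical component (step cadence);
    vehicle transit adds broadband vibration.
    """
    if not (ACCEL_RATE_MIN_HZ <= rate <= ACCEL_RATE_MAX_HZ):
        raise ValueError(
            f"accelerometer rate {rate} Hz outside supported "
            f"[{ACCEL_RATE_MIN_HZ:g}, {ACCEL_RATE_MAX_HZ:g}] Hz"
        )
    parts = []
    for w0, w1 in on_windows:
        n = int(round((w1 - w0) * rate))
        if n == 0:
            continue
        t = w0 + np.arange(n) / rate
        activity = activity_fn((w0 + w1) / 2.0)
        x = np.zeros(n)
        y = np.zeros(n)
        z = np.full(n, GRAVITY)
        if activity == "walking":
            z = z + 1.5 * np.sin(2 * np.pi * 1.9 * t)
            x = x + 0.3 * np.sin(2 * np.pi * 0.95 * t)
        elif activity == "transit":
            x = x + rng.normal(0, 0.4, n)
            y = y + rng.normal(0, 0.4, n)
        if noise_sd > 0:
            x = x + rng.normal(0, noise_sd, n)
            y = y + rng.normal(0, noise_sd, n)
            z = z + rng.normal(0, noise_sd, n)
        parts.append(
            pd.DataFrame(
                {
                    "timestamp": day_start_ms + (t * 1000).astype(np.int64),
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=list(streams.SCHEMAS["accelerometer"].columns))
    return pd.concat(parts, ignore_index=True)


def _presence_intervals(device: WirelessDevice) -> list[tuple[int, int]]:
    return [(_hhmm_seconds(a), _hhmm_seconds(b)) for a, b in device.windows]


def scan_wireless(
    kind: str,
    environment: list[WirelessDevice],
    on_windows: list[tuple[float, float]],
    rng: np.random.Generator,
    day_start_ms: int = 0,
    study_salt: bytes | None = None,
) -> pd.DataFrame:
    """Wi-Fi or Bluetooth scan records over one day.

    Wi-Fi: one instantaneous batch at the start of each on-window listing
    every present network. Bluetooth: Poisson-thinned detections of each
    present device spread across the 60 s on-window.
    """
    if kind not in ("wifi", "bluetooth"):
        raise ValueError("kind must be 'wifi' or 'bluetooth'")
    hashed = {d.mac: privacy.hash_identifier(d.mac, study_salt) for d in environment}
    rows: list[tuple[int, str, int]] = []
    for w0, w1 in on_windows:
        for dev in environment:
            present = [
                (max(w0, s), min(w1, e))
                for s, e in _presence_intervals(dev)
                if s < w1 and e > w0
            ]
            if kind == "wifi":
                # instantaneous snapshot at scan time w0
                if any(s <= w0 < e for s, e in _presence_intervals(dev)):
                    rssi = int(np.clip(dev.rssi_base + rng.normal(0, 4), -100, -1))
                    rows.append((int(w0), dev.mac, rssi))
            else:
                for s, e in present:
                    n = rng.poisson(BT_DETECTIONS_PER_WINDOW * (e - s) / max(w1 - w0, 1e-9))
                    for t in sorted(rng.uniform(s, e, n)):
                        rssi = int(np.clip(dev.rssi_base + rng.normal(0, 6), -100, -1))
                        rows.append((int(t), dev.mac, rssi))
    if not rows:
        return pd.DataFrame(columns=list(streams.SCHEMAS[kind].columns))
    rows.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(
        {
            "timestamp": [day_start_ms + r[0] * 1000 for r in rows],
            "hashed_mac": [hashed[r[1]] for r in rows],
            "rssi": [r[2] for r in rows],
        }
    )


def generate_comm_events(
    contact_pool: list[Contact],
    n_days: int,
    rng: np.random.Generator,
    period_start_ms: int = 0,
    study_salt: bytes | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call and text logs over ``n_days`` as homogeneous Poisson processes.

    Phone numbers appear only as surrogate keys. Answered-call durations
    are log-normal (median ~90 s), missed calls have duration 0, and text
    lengths are geometric with mean ~40 characters.
    """
    total_seconds = n_days * DAY_SECONDS
    calls: list[tuple[int, str, str, int]] = []
    texts: list[tuple[int, str, str, int]] = []
    for contact in contact_pool:
        key = privacy.hash_identifier(contact.number, study_salt)
        n_calls = rng.poisson(contact.call_rate * n_days)
        for t in rng.uniform(0, total_seconds, n_calls):
            ctype = rng.choice(streams.CALL_TYPES, p=[0.45, 0.45, 0.10])
            dur = 0 if ctype == "missed" else max(1, int(rng.lognormal(math.log(90), 1.0)))
            calls.append((int(t) * 1000 + period_start_ms, key, str(ctype), dur))
        n_texts = rng.poisson(contact.text_rate * n_days)
        for t in rng.uniform(0, total_seconds, n_texts):
            direction = str(rng.choice(streams.TEXT_DIRECTIONS))
            length = int(rng.geometric(1.0 / 40.0))
            texts.append((int(t) * 1000 + period_start_ms, direction, key, length))
    calls.sort()
    texts.sort()
    call_df = pd.DataFrame(calls, columns=list(streams.SCHEMAS["calls"].columns))
    text_df = pd.DataFrame(texts, columns=list(streams.SCHEMAS["texts"].columns))
    return call_df, text_df


def _interval_complement_seconds(quiet: tuple[str, str]) -> list[tuple[int, int]]:
    q0, q1 = _hhmm_seconds(quiet[0]), _hhmm_seconds(quiet[1])
    if q0 < q1:  # quiet inside the day
        return [(0, q0), (q1, DAY_SECONDS)]
    # quiet wraps midnight: active span is [q1, q0)
    return [(q1, q0)]


def generate_power_state(
    profile: BehaviorProfile,
    rng: np.random.Generator,
    day_start_ms: int = 0,
) -> pd.DataFrame:
    """One day of screen and power events.

    Screen sessions arrive at the profile's daily rate during non-quiet
    hours; each contributes an alternating screen_on/screen_off pair with
    Poisson screen_touch events in between. The charger connects near the
    start of quiet hours and disconnects near the end.
    """
    active = _interval_complement_seconds(profile.quiet_hours)
    active_total = sum(e - s for s, e in active)
    n_sessions = rng.poisson(profile.screen_sessions_per_day)
    offsets = np.sort(rng.uniform(0, active_total, n_sessions))

    def to_day_second(offset: float) -> float:
        for s, e in active:
            if offset < e - s:
                return s + offset
            offset -= e - s
        return active[-1][1] - 1e-3

    starts = np.array([to_day_second(o) for o in offsets])
    events: list[tuple[float, str]] = []
    prev_end = -1.0
    for start in starts:
        if start <= prev_end:
            continue  # keep on/off strictly alternating
        dur = float(np.clip(rng.lognormal(math.log(90), 0.8), 10, 1800))
        end = min(start + dur, DAY_SECONDS - 1e-3)
        if end <= start:
            continue
        events.append((start, "screen_on"))
        for t in sorted(rng.uniform(start, end, rng.poisson(max(dur / 10, 1)))):
            events.append((float(t), "screen_touch"))
        events.append((end, "screen_off"))
        prev_end = end

    q0 = _hhmm_seconds(profile.quiet_hours[0])
    q1 = _hhmm_seconds(profile.quiet_hours[1])
    events.append((max(0.0, q0 + float(rng.normal(0, 300))) % DAY_SECONDS, "power_connected"))
    events.append((max(0.0, q1 + float(rng.normal(0, 300))) % DAY_SECONDS, "power_disconnected"))
    events.sort(key=lambda ev: ev[0])
    return pd.DataFrame(
        {
            "timestamp": [day_start_ms + int(t * 1000) for t, _ in events],
            "event": [e for _, e in events],
        }
    )


# ---------------------------------------------------------------------------
# Active data


_FREE_RESPONSES = ("ok", "fine day", "tired", "busy at work", "nothing to add", "slept badly")


def take_survey(
    survey: Survey,
    prompt_time_ms: int,
    profile: BehaviorProfile,
    position_fn: Callable[[float], tuple[float, float, bool, str]],
    rng: np.random.Generator,
    local_second_of_prompt: float,
) -> pd.DataFrame:
    """Simulated survey response: one row per question.

    The subject starts the survey a log-normal latency after the
    notification, answers each question type-correctly, and the record
    carries the ground-truth location at the moment the survey was started.
    """
    latency = float(rng.lognormal(profile.survey_latency_log_mu, profile.survey_latency_log_sigma))
    start_ms = prompt_time_ms + int(latency * 1000)
    lat, lon, _, _ = position_fn(local_second_of_prompt + latency)
    t = start_ms
    rows = []
    for q in survey.questions:
        t += int(rng.uniform(2, 15) * 1000)  # seconds spent on this question
        if q.qtype == QuestionType.checkbox:
            picks = [o for o in q.options if rng.random() < 0.4]
            answer = ";".join(picks)
        elif q.qtype == QuestionType.radio:
            answer = str(rng.choice(q.options))
        elif q.qtype == QuestionType.slider:
            answer = str(int(rng.integers(q.slider_min, q.slider_max + 1)))
        else:
            answer = str(rng.choice(_FREE_RESPONSES))
        rows.append(
            {
                "survey_id": survey.survey_id,
                "question_id": q.question_id,
                "qtype": q.qtype.value,
                "answer": answer,
                "notification_time": prompt_time_ms,
                "start_time": start_ms,
                "end_time": t,
                "latitude": lat,
                "longitude": lon,
            }
        )
    df = pd.DataFrame(rows, columns=list(streams.SCHEMAS["survey_responses"].columns))
    return df


def _synthesize_wav(duration: float, rng: np.random.Generator, sample_rate: int = 16000) -> bytes:
    """Seeded tone-plus-noise waveform as 16-bit PCM mono WAV bytes."""
    n = int(duration * sample_rate)
    t = np.arange(n) / sample_rate
    freq = float(rng.uniform(180, 260))
    envelope = 0.5 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
    signal = 0.3 * envelope * np.sin(2 * np.pi * freq * t) + 0.02 * rng.normal(0, 1, n)
    pcm = np.clip(signal * 32767, -32768, 32767).astype("<i2")
    buf = io.BytesIO()
    with wave.open(buf, "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(sample_rate)
        w.writeframes(pcm.tobytes())
    return buf.getvalue()


def record_audio(
    prompt_time_ms: int,
    max_duration: float,
    accept_probability: float,
    rng: np.random.Generator,
    pub: privacy.RSAPublicKey,
    out_dir: Path | None,
    requested_duration: float | None = None,
) -> dict | None:
    """One voice-diary attempt: synthesize, maybe accept, encrypt-on-accept.

    The recording terminates at ``max_duration`` even if the subject would
    have spoken longer. A discarded recording leaves no artifact at all;
    an accepted one exists only as an envelope-encrypted blob the device
    cannot reopen.
    """
    if max_duration <= 0:
        raise ValueError("max_duration must be > 0")
    if requested_duration is None:
        requested_duration = float(rng.uniform(10, max_duration * 1.2))
    duration = min(requested_duration, max_duration)
    accepted = bool(rng.random() < accept_probability)
    if not accepted:
        return None
    wav = _synthesize_wav(duration, rng)
    blob = privacy.encrypt_envelope(wav, pub, rng=rng)
    file_ref = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        file_ref = out_dir / f"{prompt_time_ms}.bin"
        file_ref.write_bytes(blob.to_bytes())
    return {
        "timestamp": prompt_time_ms,
        "duration": round(duration, 3),
        "file_ref": str(file_ref) if file_ref else None,
        "accepted": True,
        "blob": blob,
    }


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SimulationResult:
    participant_id: str
    start: dt.date
    n_days: int
    frames: dict[str, pd.DataFrame]
    audio: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    out_dir: Path | None = None

    def hourly_chunks(self):
        """Yield (stream, hour_iso, frame) for every nonempty hour."""
        for stream, df in sorted(self.frames.items()):
            if df.empty:
                continue
            hours = pd.to_datetime(
                df["timestamp" if "timestamp" in df.columns else "notification_time"],
                unit="ms",
                utc=True,
            ).dt.strftime("%Y-%m-%dT%H")
            for hour, sub in df.groupby(hours, sort=True):
                yield stream, str(hour), sub.reset_index(drop=True)


_STREAM_RNG_TAG = {
    "gps": 1,
    "accelerometer": 2,
    "comm": 3,
    "wifi": 4,
    "bluetooth": 5,
    "power_state": 6,
    "surveys": 7,
    "audio": 8,
}


def _stream_rng(seed: int, tag: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM_RNG_TAG[tag], extra]))


def count_scalar_observations(frames: dict[str, pd.DataFrame]) -> int:
    """Numeric cells across passive-stream rows (the data-volume measure)."""
    passive = ("gps", "accelerometer", "calls", "texts", "wifi", "bluetooth", "power_state")
    total = 0
    for stream in passive:
        df = frames.get(stream)
        if df is None or df.empty:
            continue
        numeric = df.select_dtypes(include=[np.number])
        total += int(numeric.shape[0] * numeric.shape[1])
    return total


def simulate_period(
    cfg: StudyConfig,
    profile: BehaviorProfile,
    start: dt.date,
    n_days: int,
    participant_id: str = "participant",
    out_dir: str | Path | None = None,
    pub: privacy.RSAPublicKey | None = None,
    study_salt: bytes | None = None,
) -> SimulationResult:
    """Run the device for ``n_days`` from ``start`` and emit all streams.

    Refuses invalid configs and inconsistent profiles. Output is one CSV
    per stream per UTC hour under ``out_dir/<participant>/<stream>/``
    (empty hours omitted) plus a manifest; audio requires ``pub`` because
    accepted recordings are encrypted the moment they exist.
    """
    require_valid(cfg)
    validate_profile(profile)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")

    tz = cfg.tzinfo()
    position_fn = make_position_fn(profile)
    activity_fn = lambda sec: position_fn(sec)[3]  # noqa: E731
    seed = profile.rng_seed
    frames: dict[str, list[pd.DataFrame]] = {}

    def enabled(stream: StreamName) -> bool:
        s = cfg.sensor(stream)
        return s is not None and s.enabled

    day_start_ms: list[int] = []
    for d in range(n_days):
        local_midnight = dt.datetime.combine(start + dt.timedelta(days=d), dt.time(0), tzinfo=tz)
        day_start_ms.append(int(local_midnight.astimezone(dt.timezone.utc).timestamp() * 1000))

    for d in range(n_days):
        ms0 = day_start_ms[d]
        if enabled(StreamName.gps):
            s = cfg.sensor(StreamName.gps)
            windows = duty_cycle_windows(s.on_duration, s.off_duration, DAY_SECONDS)
            frames.setdefault("gps", []).append(
                sample_gps(
                    position_fn, windows, _stream_rng(seed, "gps", d),
                    rate_in_motion=s.nominal_rate, day_start_ms=ms0,
                )
            )
        if enabled(StreamName.accelerometer):
            s = cfg.sensor(StreamName.accelerometer)
            windows = duty_cycle_windows(s.on_duration, s.off_duration, DAY_SECONDS)
            frames.setdefault("accelerometer", []).append(
                sample_accelerometer(
                    activity_fn, windows, _stream_rng(seed, "accelerometer", d),
                    rate=s.nominal_rate, day_start_ms=ms0,
                )
            )
        if enabled(StreamName.wifi):
            s = cfg.sensor(StreamName.wifi)
            windows = duty_cycle_windows(s.on_duration, s.off_duration, DAY_SECONDS)
            frames.setdefault("wifi", []).append(
                scan_wireless(
                    "wifi", profile.wifi_environment, windows,
                    _stream_rng(seed, "wifi", d), day_start_ms=ms0, study_salt=study_salt,
                )
            )
        if enabled(StreamName.bluetooth):
            s = cfg.sensor(StreamName.bluetooth)
            windows = duty_cycle_windows(s.on_duration, s.off_duration, DAY_SECONDS)
            frames.setdefault("bluetooth", []).append(
                scan_wireless(
                    "bluetooth", profile.bluetooth_environment, windows,
                    _stream_rng(seed, "bluetooth", d), day_start_ms=ms0, study_salt=study_salt,
                )
            )
        if enabled(StreamName.power_state):
            frames.setdefault("power_state", []).append(
                generate_power_state(profile, _stream_rng(seed, "power_state", d), day_start_ms=ms0)
            )

    if enabled(StreamName.calls) or enabled(StreamName.texts):
        call_df, text_df = generate_comm_events(
            profile.contact_pool, n_days, _stream_rng(seed, "comm"),
            period_start_ms=day_start_ms[0], study_salt=study_salt,
        )
        if enabled(StreamName.calls):
            frames["calls"] = [call_df]
        if enabled(StreamName.texts):
            frames["texts"] = [text_df]

    window_end = start + dt.timedelta(days=n_days)
    survey_frames: list[pd.DataFrame] = []
    rng_sv = _stream_rng(seed, "surveys")
    for survey in cfg.surveys:
        for prompt in expand_schedule(survey.schedule, start, window_end, tz):
            prompt_ms = int(prompt.timestamp() * 1000)
            local = prompt.astimezone(tz)
            local_sec = local.hour * 3600 + local.minute * 60 + local.second
            survey_frames.append(
                take_survey(survey, prompt_ms, profile, position_fn, rng_sv, local_sec)
            )
    if survey_frames:
        frames["survey_responses"] = survey_frames

    out_path = Path(out_dir) if out_dir is not None else None
    audio_metas: list[dict] = []
    if enabled(StreamName.audio) and pub is not None:
        rng_audio = _stream_rng(seed, "audio")
        hh, mm = (int(p) for p in cfg.audio_prompt_time.split(":"))
        audio_dir = out_path / participant_id / "audio" if out_path else None
        for d in range(n_days):
            prompt_ms = day_start_ms[d] + (hh * 3600 + mm * 60) * 1000
            meta = record_audio(
                prompt_ms, cfg.audio_max_duration, profile.audio_accept_probability,
                rng_audio, pub, audio_dir,
            )
            if meta is not None:
                audio_metas.append(meta)

    merged = {
        name: pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        for name, parts in frames.items()
    }
    for name, df in merged.items():
        sort_col = "timestamp" if "timestamp" in df.columns else "notification_time"
        if not df.empty:
            merged[name] = df.sort_values(sort_col, kind="stable").reset_index(drop=True)

    result = SimulationResult(
        participant_id=participant_id,
        start=start,
        n_days=n_days,
        frames=merged,
        audio=audio_metas,
    )

    manifest = {
        "participant_id": participant_id,
        "study_id": cfg.study_id,
        "start": start.isoformat(),
        "n_days": n_days,
        "rng_seed": seed,
        "files": {},
        "audio": [
            {
                "timestamp": meta["timestamp"],
                "duration": meta["duration"],
                "accepted": meta["accepted"],
                # relative so a run is comparable across machines/directories
                "file_ref": str(Path(meta["file_ref"]).relative_to(out_path))
                if meta["file_ref"] and out_path
                else meta["file_ref"],
            }
            for meta in audio_metas
        ],
    }
    if out_path is not None:
        for stream, hour, sub in result.hourly_chunks():
            rel = Path(participant_id) / stream / f"{hour}.csv"
            target = out_path / rel
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_bytes(streams.to_csv_bytes(sub, stream))
            manifest["files"][str(rel)] = int(len(sub))
        (out_path / participant_id / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        result.out_dir = out_path
    result.manifest = manifest
    return result
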