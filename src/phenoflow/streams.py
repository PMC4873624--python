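"""Raw data stream schemas: columns, serialization, and row validation.

Every stream is a CSV with a fixed header, UTF-8, comma-separated, RFC 4180
quoting, timestamps as UTC epoch milliseconds. The same schema table drives
the simulator's writers and the server's ingest validation, so the two
cannot drift apart.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

__all__ = ["StreamSchema", "SCHEMAS", "to_csv_bytes", "from_csv_bytes", "validate_frame"]

CALL_TYPES = ("incoming", "outgoing", "missed")
TEXT_DIRECTIONS = ("sent", "received")
POWER_EVENTS = (
    "screen_on",
    "screen_off",
    "power_connected",
    "power_disconnected",
    "shutdown",
    "restart",
    "boot",
    "screen_touch",
)

_HEX64 = re.compile(r"^[0-9a-f]{64}$")

RowCheck = Callable[[pd.DataFrame], list[str]]


def _monotone_ts(df: pd.DataFrame) -> list[str]:
    ts = df["timestamp"].to_numpy()
    bad = [i for i in range(1, len(ts)) if ts[i] < ts[i - 1]]
    return [f"row {i}: timestamp decreases" for i in bad]


def _enum_check(column: str, allowed: tuple[str, ...]) -> RowCheck:
    def check(df: pd.DataFrame) -> list[str]:
        mask = ~df[column].isin(allowed)
        return [
            f"row {i}: {column} {df[column].iloc[i]!r} not in {allowed}"
            for i in mask.to_numpy().nonzero()[0]
        ]

    return check


def _range_check(column: str, lo: float, hi: float) -> RowCheck:
    def check(df: pd.DataFrame) -> list[str]:
        vals = df[column]
        mask = (vals < lo) | (vals > hi) | vals.isna()
        return [
            f"row {i}: {column} {vals.iloc[i]} outside [{lo}, {hi}]"
            for i in mask.to_numpy().nonzero()[0]
        ]

    return check


def _surrogate_check(column: str) -> RowCheck:
    def check(df: pd.DataFrame) -> list[str]:
        return [
            f"row {i}: {column} is not a 64-hex surrogate key"
            for i, v in enumerate(df[column])
            if not (isinstance(v, str) and _HEX64.match(v))
        ]

    return check


def _missed_zero_duration(df: pd.DataFrame) -> list[str]:
    mask = (df["call_type"] == "missed") & (df["duration"] != 0)
    return [f"row {i}: missed call with nonzero duration" for i in mask.to_numpy().nonzero()[0]]


def _nonneg(column: str) -> RowCheck:
    def check(df: pd.DataFrame) -> list[str]:
        mask = df[column] < 0
        return [f"row {i}: {column} must be >= 0" for i in mask.to_numpy().nonzero()[0]]

    return check


def _min_value(column: str, lo: float) -> RowCheck:
    def check(df: pd.DataFrame) -> list[str]:
        mask = df[column] < lo
        return [f"row {i}: {column} must be >= {lo}" for i in mask.to_numpy().nonzero()[0]]

    return check


def _survey_time_order(df: pd.DataFrame) -> list[str]:
    mask = ~(
        (df["notification_time"] <= df["start_time"])
        & (df["start_time"] <= df["end_time"])
    )
    return [
        f"row {i}: notification_time <= start_time <= end_time violated"
        for i in mask.to_numpy().nonzero()[0]
    ]


@dataclass(frozen=True)
class StreamSchema:
    stream: str
    columns: tuple[str, ...]
    float_format: str | None = None
    checks: tuple[RowCheck, ...] = field(default_factory=tuple)


SCHEMAS: dict[str, StreamSchema] = {
    s.stream: s
    for s in [
        StreamSchema(
            "gps",
            ("timestamp", "latitude", "longitude", "accuracy"),
            float_format="%.6f",
            checks=(
                _monotone_ts,
                _range_check("latitude", -90, 90),
                _range_check("longitude", -180, 180),
                _nonneg("accuracy"),
            ),
        ),
        StreamSchema(
            "accelerometer",
            ("timestamp", "x", "y", "z"),
            float_format="%.5f",
            checks=(_monotone_ts,),
        ),
        StreamSchema(
            "calls",
            ("timestamp", "hashed_number", "call_type", "duration"),
            checks=(
                _monotone_ts,
                _surrogate_check("hashed_number"),
                _enum_check("call_type", CALL_TYPES),
                _nonneg("duration"),
                _missed_zero_duration,
            ),
        ),
        StreamSchema(
            "texts",
            ("timestamp", "direction", "hashed_number", "message_length"),
            checks=(
                _monotone_ts,
                _enum_check("direction", TEXT_DIRECTIONS),
                _surrogate_check("hashed_number"),
                _min_value("message_length", 1),
            ),
        ),
        StreamSchema(
            "wifi",
            ("timestamp", "hashed_mac", "rssi"),
            checks=(_monotone_ts, _surrogate_check("hashed_mac"), _range_check("rssi", -100, 0)),
        ),
        StreamSchema(
            "bluetooth",
            ("timestamp", "hashed_mac", "rssi"),
            checks=(_monotone_ts, _surrogate_check("hashed_mac"), _range_check("rssi", -100, 0)),
        ),
        StreamSchema(
            "power_state",
            ("timestamp", "event"),
            checks=(_monotone_ts, _enum_check("event", POWER_EVENTS)),
        ),
        StreamSchema(
            "survey_responses",
            (
                "survey_id",
                "question_id",
                "qtype",
                "answer",
                "notification_time",
                "start_time",
                "end_time",
                "latitude",
                "longitude",
            ),
            float_format="%.6f",
            checks=(_survey_time_order,),
        ),
    ]
}


def to_csv_bytes(df: pd.DataFrame, stream: str) -> bytes:
    """Serialize records in the stream's canonical column order."""
    schema = SCHEMAS[stream]
    buf = io.StringIO()
    df.loc[:, list(schema.columns)].to_csv(
        buf, index=False, float_format=schema.float_format, lineterminator="\n"
    )
    return buf.getvalue().encode("utf-8")


def from_csv_bytes(data: bytes, stream: str) -> pd.DataFrame:
    """Parse a stream CSV, enforcing the exact documented header."""
    schema = SCHEMAS[stream]
    df = pd.read_csv(io.BytesIO(data))
    if tuple(df.columns) != schema.columns:
        raise ValueError(
            f"{stream}: header {tuple(df.columns)} does not match schema {schema.columns}"
        )
    return df


def validate_frame(df: pd.DataFrame, stream: str) -> list[str]:
    """All schema violations in ``df`` ('row N: reason'), empty if clean."""
    schema = SCHEMAS[stream]
    if tuple(df.columns) != schema.columns:
        return [f"header mismatch: {tuple(df.columns)} != {schema.columns}"]
    problems: list[str] = []
    if len(df):
        for check in schema.checks:
            problems.extend(check(df))
    return problems
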