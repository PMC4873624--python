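"""Store-and-forward transport: encrypt-on-write buffering and server ingest.

The device side never stores plaintext: records are serialized to their
stream CSV and envelope-encrypted in one step (:func:`buffer_write`), and
the resulting chunk sits in the buffer until a simulated Wi-Fi window
allows upload. A chunk is deleted from the buffer only after the server
acknowledges it, so delivery is at-least-once; the server deduplicates on
(participant, stream, period, content digest), making storage exactly-once.
Delays in connectivity therefore postpone transfer but never lose or
degrade data.

On ingest the server decrypts, verifies the plaintext digest, validates
every row against the stream schema, re-encrypts under the study master
key, and records the outcome in an append-only ledger. Anything that fails
is quarantined with its reason rather than silently dropped.

The "server" is an in-process filesystem endpoint with injectable upload
faults; there is no network stack.
"""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import privacy, streams

__all__ = [
    "BufferedChunk",
    "DeviceBuffer",
    "WifiAvailabilitySchedule",
    "IngestLedger",
    "Server",
    "TransportError",
    "IntegrityError",
    "SchemaValidationError",
    "buffer_write",
    "run_transfer",
    "ingest_chunk",
]


class TransportError(Exception):
    pass


class IntegrityError(TransportError):
    """Decryption or digest verification failed for a chunk."""


class SchemaValidationError(TransportError):
    """Decrypted records violate the stream schema; carries row reasons."""

    def __init__(self, reasons: list[str]):
        self.reasons = reasons
        super().__init__("; ".join(reasons[:5]))


@dataclass(frozen=True)
class BufferedChunk:
    participant_id: str
    stream_name: str
    period_start: str  # UTC hour, e.g. "2024-01-01T13"
    blob: privacy.EncryptedBlob
    content_digest: str  # SHA-256 hex of the plaintext CSV
    created_at: int  # UTC epoch ms

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.participant_id, self.stream_name, self.period_start, self.content_digest)

    def to_json_bytes(self) -> bytes:
        doc = {
            "participant_id": self.participant_id,
            "stream_name": self.stream_name,
            "period_start": self.period_start,
            "content_digest": self.content_digest,
            "created_at": self.created_at,
            "blob": base64.b64encode(self.blob.to_bytes()).decode("ascii"),
        }
        return (json.dumps(doc, sort_keys=True) + "\n").encode("utf-8")

    @classmethod
    def from_json_bytes(cls, data: bytes) -> "BufferedChunk":
        doc = json.loads(data.decode("utf-8"))
        return cls(
            participant_id=doc["participant_id"],
            stream_name=doc["stream_name"],
            period_start=doc["period_start"],
            blob=privacy.EncryptedBlob.from_bytes(base64.b64decode(doc["blob"])),
            content_digest=doc["content_digest"],
            created_at=doc["created_at"],
        )


def buffer_write(
    records: pd.DataFrame,
    participant_id: str,
    stream_name: str,
    period_start: str,
    pub: privacy.RSAPublicKey,
    created_at: int = 0,
    rng=None,
) -> BufferedChunk | None:
    """Serialize records and encrypt them in one step; empty input -> None.

    The plaintext CSV exists only transiently in memory: the chunk that
    reaches disk holds ciphertext plus a digest of what was encrypted.
    """
    if records is None or len(records) == 0:
        return None
    plaintext = streams.to_csv_bytes(records, stream_name)
    digest = hashlib.sha256(plaintext).hexdigest()
    blob = privacy.encrypt_envelope(plaintext, pub, rng=rng)
    return BufferedChunk(participant_id, stream_name, period_start, blob, digest, created_at)


class DeviceBuffer:
    """Filesystem buffer of encrypted chunks awaiting upload."""

    def __init__(self, root: str | Path, capacity: int | None = None):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.capacity = capacity
        self.refused: list[tuple[str, str, str]] = []

    def _path(self, chunk: BufferedChunk) -> Path:
        return self.root / chunk.participant_id / chunk.stream_name / f"{chunk.period_start}.chunk"

    def put(self, chunk: BufferedChunk | None) -> bool:
        """Store a chunk; refuses (and records the refusal) past capacity."""
        if chunk is None:
            return False
        if self.capacity is not None and len(self.list()) >= self.capacity:
            self.refused.append((chunk.participant_id, chunk.stream_name, chunk.period_start))
            return False
        path = self._path(chunk)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".tmp")
        tmp.write_bytes(chunk.to_json_bytes())
        tmp.rename(path)  # atomic: no partial chunk is ever visible
        return True

    def list(self) -> list[Path]:
        return sorted(self.root.rglob("*.chunk"))

    def load(self, path: Path) -> BufferedChunk:
        return BufferedChunk.from_json_bytes(path.read_bytes())

    def delete(self, path: Path) -> None:
        path.unlink()


@dataclass(frozen=True)
class WifiAvailabilitySchedule:
    """Sorted, non-overlapping UTC ms intervals when upload is possible."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = None
        for start, end in self.intervals:
            if end <= start:
                raise ValueError("schedule interval must have end > start")
            if prev_end is not None and start < prev_end:
                raise ValueError("schedule intervals must be sorted and non-overlapping")
            prev_end = end

    def available(self, t_ms: int) -> bool:
        return any(s <= t_ms < e for s, e in self.intervals)

    @classmethod
    def from_json(cls, path: str | Path) -> "WifiAvailabilitySchedule":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(tuple((int(s), int(e)) for s, e in doc["intervals"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"intervals": [list(i) for i in self.intervals]}, indent=2) + "\n",
            encoding="utf-8",
        )


class IngestLedger:
    """Append-only record of chunk ingest outcomes, persisted as JSON.

    A key's status never regresses: once "stored", later duplicate
    submissions are appended as events but the status stays "stored".
    """

    _RANK = {"quarantined": 1, "stored": 2}

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.entries: dict[str, dict] = {}
        self.events: list[dict] = []
        if self.path.exists():
            doc = json.loads(self.path.read_text(encoding="utf-8"))
            self.entries = doc.get("entries", {})
            self.events = doc.get("events", [])

    @staticmethod
    def key_of(chunk: BufferedChunk) -> str:
        return "|".join(chunk.key)

    def status(self, chunk: BufferedChunk) -> str | None:
        entry = self.entries.get(self.key_of(chunk))
        return entry["status"] if entry else None

    def record(self, chunk: BufferedChunk, status: str, reason: str | None = None) -> None:
        key = self.key_of(chunk)
        self.events.append({"key": key, "status": status, "reason": reason})
        current = self.entries.get(key)
        base_status = status.split(":")[0]
        if current is None:
            self.entries[key] = {"status": base_status, "reason": reason}
        else:
            old_rank = self._RANK.get(current["status"], 0)
            if self._RANK.get(base_status, 0) > old_rank:
                self.entries[key] = {"status": base_status, "reason": reason}
        self._save()

    def _save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(
            json.dumps({"entries": self.entries, "events": self.events}, indent=2, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )


def ingest_chunk(
    chunk: BufferedChunk,
    priv: privacy.RSAPrivateKey,
    master: bytes,
    ledger: IngestLedger,
    store_root: str | Path,
    study_id: str = "study",
) -> pd.DataFrame:
    """Decrypt, verify, validate, and re-encrypt one chunk into the store.

    Raises :class:`IntegrityError` on decryption/digest failure and
    :class:`SchemaValidationError` (listing row numbers) on invalid rows;
    callers decide whether to quarantine. On success returns the validated
    records and writes the master-key-encrypted record to
    ``<study>/<participant>/<stream>/<hour>.bin``.
    """
    try:
        plaintext = privacy.decrypt_envelope(chunk.blob, priv)
    except privacy.DecryptionError as exc:
        raise IntegrityError(f"decryption failed: {exc}") from exc
    digest = hashlib.sha256(plaintext).hexdigest()
    if digest != chunk.content_digest:
        raise IntegrityError("content digest mismatch after decryption")
    try:
        df = streams.from_csv_bytes(plaintext, chunk.stream_name)
    except (ValueError, KeyError) as exc:
        raise SchemaValidationError([str(exc)]) from exc
    problems = streams.validate_frame(df, chunk.stream_name)
    if problems:
        raise SchemaValidationError(problems)

    if ledger.status(chunk) == "stored":
        ledger.record(chunk, "duplicate")
        return df

    record = privacy.encrypt_with_master(plaintext, master)
    target = (
        Path(store_root)
        / study_id
        / chunk.participant_id
        / chunk.stream_name
        / f"{chunk.period_start}.bin"
    )
    target.parent.mkdir(parents=True, exist_ok=True)
    target.write_bytes(record.to_bytes())
    ledger.record(chunk, "stored")
    return df


class Server:
    """In-process study server: inbox, ingest pipeline, at-rest store.

    ``failure_rate`` injects upload faults: an attempted receive can be
    dropped before storage or stored with the acknowledgment lost, in
    which case the device retries and dedup makes storage exactly-once.
    """

    def __init__(
        self,
        root: str | Path,
        priv: privacy.RSAPrivateKey,
        master: bytes,
        study_id: str = "study",
        failure_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        self.root = Path(root)
        self.priv = priv
        self.master = master
        self.study_id = study_id
        self.failure_rate = failure_rate
        self.rng = rng if rng is not None else np.random.default_rng()
        self.inbox: list[BufferedChunk] = []
        self.ledger = IngestLedger(self.root / "ledger.json")
        self.quarantine_dir = self.root / "quarantine"
        (self.root / "inbox").mkdir(parents=True, exist_ok=True)

    def receive(self, chunk: BufferedChunk) -> bool:
        """Accept an upload; returns whether the device sees an ack."""
        if self.failure_rate > 0 and self.rng.random() < self.failure_rate:
            if self.rng.random() < 0.5:
                return False  # dropped in flight: nothing stored
            self._store_inbox(chunk)
            return False  # stored but the acknowledgment was lost
        self._store_inbox(chunk)
        return True

    def _store_inbox(self, chunk: BufferedChunk) -> None:
        name = "_".join(chunk.key[:3]) + f"_{chunk.content_digest[:12]}.chunk"
        (self.root / "inbox" / name).write_bytes(chunk.to_json_bytes())
        self.inbox.append(chunk)

    def ingest_all(self) -> dict[str, int]:
        """Run the ingest pipeline over the inbox; returns outcome counts."""
        counts = {"stored": 0, "duplicate": 0, "quarantined": 0}
        for chunk in self.inbox:
            before = self.ledger.status(chunk)
            try:
                ingest_chunk(chunk, self.priv, self.master, self.ledger,
                             self.root / "store", self.study_id)
                counts["duplicate" if before == "stored" else "stored"] += 1
            except TransportError as exc:
                reason = f"{type(exc).__name__}: {exc}"
                self.ledger.record(chunk, "quarantined", reason)
                self.quarantine_dir.mkdir(parents=True, exist_ok=True)
                qname = "_".join(chunk.key[:3]) + f"_{chunk.content_digest[:12]}.json"
                (self.quarantine_dir / qname).write_text(
                    json.dumps({"key": list(chunk.key), "reason": reason}, indent=2) + "\n",
                    encoding="utf-8",
                )
                counts["quarantined"] += 1
        self.inbox = []
        return counts

    def load_records(self, participant_id: str, stream_name: str) -> pd.DataFrame:
        """Decrypt and concatenate all stored records of one stream."""
        base = self.root / "store" / self.study_id / participant_id / stream_name
        frames = []
        if base.exists():
            for path in sorted(base.glob("*.bin")):
                record = privacy.StorageRecord.from_bytes(path.read_bytes())
                plaintext = privacy.decrypt_with_master(record, self.master)
                frames.append(streams.from_csv_bytes(plaintext, stream_name))
        if not frames:
            return pd.DataFrame(columns=list(streams.SCHEMAS[stream_name].columns))
        df = pd.concat(frames, ignore_index=True)
        sort_col = "timestamp" if "timestamp" in df.columns else "notification_time"
        return df.sort_values(sort_col, kind="stable").reset_index(drop=True)


def run_transfer(
    buffer: DeviceBuffer,
    schedule: WifiAvailabilitySchedule,
    server: Server,
    start_ms: int,
    end_ms: int,
    attempt_interval_ms: int = 600_000,
) -> list[dict]:
    """Drive the upload loop over simulated time.

    Every ``attempt_interval_ms`` the device checks for Wi-Fi; inside an
    availability window it attempts each buffered chunk and deletes a
    chunk only after the server acknowledges it. Unacknowledged chunks are
    retried on later passes, so no record can exist in zero places.
    """
    log: list[dict] = []
    t = start_ms
    while t < end_ms:
        pending = buffer.list()
        if not pending:
            break
        if schedule.available(t):
            for path in pending:
                chunk = buffer.load(path)
                acked = server.receive(chunk)
                log.append(
                    {
                        "time": t,
                        "chunk": "|".join(chunk.key[:3]),
                        "status": "uploaded" if acked else "retry",
                    }
                )
                if acked:
                    buffer.delete(path)
        t += attempt_interval_ms
    return log
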