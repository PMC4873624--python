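"""Store-and-forward transport: encrypt-on-write, conservation, ingest."""

import hashlib
import json
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoflow import privacy, streams, transport
from phenoflow.transport import (
    BufferedChunk,
    DeviceBuffer,
    IngestLedger,
    IntegrityError,
    SchemaValidationError,
    Server,
    WifiAvailabilitySchedule,
    buffer_write,
    ingest_chunk,
    run_transfer,
)


def gps_frame(n: int, t0: int = 1_700_000_000_000, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "timestamp": t0 + np.arange(n) * 1000,
            "latitude": 42.36 + rng.normal(0, 1e-4, n),
            "longitude": -71.05 + rng.normal(0, 1e-4, n),
            "accuracy": np.round(rng.uniform(5, 15, n), 1),
        }
    )


class TestBufferWrite:
    def test_buffer_directory_holds_no_plaintext(self, keypair, tmp_path):
        buf = DeviceBuffer(tmp_path)
        df = gps_frame(50)
        buf.put(buffer_write(df, "p1", "gps", "2024-01-01T00", keypair.public_part))
        for path in tmp_path.rglob("*"):
            if path.is_file():
                raw = path.read_bytes()
                assert b"timestamp,latitude" not in raw
                assert b"42.36" not in raw

    def test_empty_record_list_produces_no_chunk(self, keypair):
        assert buffer_write(gps_frame(0), "p1", "gps", "h", keypair.public_part) is None

    def test_content_digest_matches_serialized_records(self, keypair):
        df = gps_frame(10)
        chunk = buffer_write(df, "p1", "gps", "h", keypair.public_part)
        assert chunk.content_digest == hashlib.sha256(streams.to_csv_bytes(df, "gps")).hexdigest()

    def test_chunk_json_roundtrip(self, keypair):
        chunk = buffer_write(gps_frame(5), "p1", "gps", "h", keypair.public_part, created_at=123)
        assert BufferedChunk.from_json_bytes(chunk.to_json_bytes()) == chunk

    def test_capacity_cap_refuses_and_records(self, keypair, tmp_path):
        buf = DeviceBuffer(tmp_path, capacity=2)
        for i in range(3):
            buf.put(buffer_write(gps_frame(5, seed=i), "p1", "gps", f"h{i}", keypair.public_part))
        assert len(buf.list()) == 2
        assert len(buf.refused) == 1


class TestTransfer:
    def make_buffer(self, tmp_path, keypair, n_chunks=5):
        buf = DeviceBuffer(tmp_path / "buffer")
        for i in range(n_chunks):
            buf.put(
                buffer_write(
                    gps_frame(20, t0=1_700_000_000_000 + i * 3_600_000, seed=i),
                    "p1", "gps", f"2024-01-01T{i:02d}", keypair.public_part,
                )
            )
        return buf

    def test_no_wifi_for_days_then_connectivity_delivers_everything(
        self, keypair, master_key, tmp_path
    ):
        """Three days without Wi-Fi postpone upload but lose nothing."""
        buf = self.make_buffer(tmp_path, keypair)
        day_ms = 86_400_000
        schedule = WifiAvailabilitySchedule(((3 * day_ms, 3 * day_ms + 3_600_000),))
        server = Server(tmp_path / "server", keypair.private_part, master_key)
        log = run_transfer(buf, schedule, server, 0, 4 * day_ms)
        assert buf.list() == []
        assert server.ingest_all()["stored"] == 5
        # nothing was uploaded before connectivity existed
        assert all(e["time"] >= 3 * day_ms for e in log if e["status"] == "uploaded")

    def test_chunk_survives_until_acknowledged(self, keypair, master_key, tmp_path):
        """With the ack always failing, the buffer never shrinks."""
        buf = self.make_buffer(tmp_path, keypair, n_chunks=2)
        server = Server(
            tmp_path / "server", keypair.private_part, master_key,
            failure_rate=1.0, rng=np.random.default_rng(0),
        )
        run_transfer(buf, WifiAvailabilitySchedule(((0, 10**9),)), server, 0, 3_600_000)
        assert len(buf.list()) == 2

    def test_duplicate_upload_stored_once_ledger_notes_duplicate(
        self, keypair, master_key, tmp_path
    ):
        chunk = buffer_write(gps_frame(10), "p1", "gps", "2024-01-01T00", keypair.public_part)
        server = Server(tmp_path / "server", keypair.private_part, master_key)
        server.receive(chunk)
        server.receive(chunk)
        counts = server.ingest_all()
        assert counts == {"stored": 1, "duplicate": 1, "quarantined": 0}
        stored = list((tmp_path / "server" / "store").rglob("*.bin"))
        assert len(stored) == 1

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_windows=st.integers(1, 4))
    def test_conservation_under_faults_and_random_schedules(
        self, keypair, master_key, tmp_path_factory, seed, n_windows
    ):
        """Generated multiset == ingested multiset for any connectivity
        pattern and a 30% injected upload failure rate."""
        tmp_path = tmp_path_factory.mktemp("conserve")
        rng = np.random.default_rng(seed)
        frames = {f"2024-01-01T{i:02d}": gps_frame(10, seed=seed + i) for i in range(4)}
        buf = DeviceBuffer(tmp_path / "buffer")
        for hour, df in frames.items():
            buf.put(buffer_write(df, "p1", "gps", hour, keypair.public_part))
        # windows span >= 20 retry ticks each, so a 30% per-attempt failure
        # rate still delivers everything with overwhelming probability
        horizon = 100 * 600_000
        starts = np.sort(rng.integers(0, horizon // 2, n_windows))
        intervals, cursor = [], 0
        for s in starts:
            s = max(int(s), cursor)
            e = s + int(rng.integers(20, 40)) * 600_000
            intervals.append((s, e))
            cursor = e + 600_000
        schedule = WifiAvailabilitySchedule(tuple(intervals))
        server = Server(
            tmp_path / "server", keypair.private_part, master_key,
            failure_rate=0.3, rng=rng,
        )
        run_transfer(buf, schedule, server, 0, horizon)
        assert buf.list() == [], "connectivity existed but chunks were left behind"
        server.ingest_all()
        ingested = server.load_records("p1", "gps")
        expected = pd.concat(frames.values(), ignore_index=True).sort_values("timestamp")
        got = Counter(map(tuple, np.round(ingested.to_numpy(), 6).tolist()))
        want = Counter(map(tuple, np.round(expected.to_numpy(), 6).tolist()))
        assert got == want


class TestIngest:
    def test_valid_chunk_accepted_row_count_preserved(self, keypair, master_key, tmp_path):
        df = gps_frame(37)
        chunk = buffer_write(df, "p1", "gps", "2024-01-01T00", keypair.public_part)
        ledger = IngestLedger(tmp_path / "ledger.json")
        out = ingest_chunk(chunk, keypair.private_part, master_key, ledger, tmp_path / "store")
        assert len(out) == 37
        assert ledger.status(chunk) == "stored"

    def test_unknown_call_type_reported_with_row_number(self, keypair, master_key, tmp_path):
        df = pd.DataFrame(
            {
                "timestamp": [1000, 2000, 3000],
                "hashed_number": [hashlib.sha256(b"x").hexdigest()] * 3,
                "call_type": ["incoming", "dropped", "outgoing"],
                "duration": [10, 5, 20],
            }
        )
        chunk = buffer_write(df, "p1", "calls", "h", keypair.public_part)
        with pytest.raises(SchemaValidationError) as exc:
            ingest_chunk(chunk, keypair.private_part, master_key,
                         IngestLedger(tmp_path / "l.json"), tmp_path / "store")
        assert any("row 1" in r for r in exc.value.reasons)

    def test_tampered_ciphertext_quarantined_with_reason(self, keypair, master_key, tmp_path):
        chunk = buffer_write(gps_frame(10), "p1", "gps", "h", keypair.public_part)
        ct = bytearray(chunk.blob.ciphertext)
        ct[3] ^= 0x40
        tampered = BufferedChunk(
            chunk.participant_id, chunk.stream_name, chunk.period_start,
            privacy.EncryptedBlob(
                chunk.blob.wrapped_key, chunk.blob.iv, bytes(ct),
                chunk.blob.tag, chunk.blob.payload_length,
            ),
            chunk.content_digest, chunk.created_at,
        )
        server = Server(tmp_path / "server", keypair.private_part, master_key)
        server.receive(tampered)
        assert server.ingest_all()["quarantined"] == 1
        (qfile,) = (tmp_path / "server" / "quarantine").glob("*.json")
        assert "IntegrityError" in json.loads(qfile.read_text())["reason"]

    def test_digest_mismatch_is_integrity_error(self, keypair, master_key, tmp_path):
        chunk = buffer_write(gps_frame(10), "p1", "gps", "h", keypair.public_part)
        lying = BufferedChunk(
            chunk.participant_id, chunk.stream_name, chunk.period_start,
            chunk.blob, "0" * 64, chunk.created_at,
        )
        with pytest.raises(IntegrityError):
            ingest_chunk(lying, keypair.private_part, master_key,
                         IngestLedger(tmp_path / "l.json"), tmp_path / "store")

    def test_store_is_master_key_encrypted_not_rsa(self, keypair, master_key, tmp_path):
        chunk = buffer_write(gps_frame(10), "p1", "gps", "h", keypair.public_part)
        ingest_chunk(chunk, keypair.private_part, master_key,
                     IngestLedger(tmp_path / "l.json"), tmp_path / "store")
        (binfile,) = (tmp_path / "store").rglob("*.bin")
        record = privacy.StorageRecord.from_bytes(binfile.read_bytes())
        assert privacy.decrypt_with_master(record, master_key)  # master opens it
        with pytest.raises(privacy.DecryptionError):
            privacy.decrypt_with_master(record, bytes(32))  # another key does not

    def test_ledger_status_never_regresses(self, keypair, master_key, tmp_path):
        chunk = buffer_write(gps_frame(5), "p1", "gps", "h", keypair.public_part)
        ledger = IngestLedger(tmp_path / "ledger.json")
        ingest_chunk(chunk, keypair.private_part, master_key, ledger, tmp_path / "store")
        assert ledger.status(chunk) == "stored"
        ledger.record(chunk, "quarantined", "late corruption report")
        assert ledger.status(chunk) == "stored"
        assert len(ledger.events) == 2
        reloaded = IngestLedger(tmp_path / "ledger.json")
        assert reloaded.status(chunk) == "stored"
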