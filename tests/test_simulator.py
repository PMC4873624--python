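"""Device simulator: duty cycles, schemas, rates, privacy, determinism."""

import datetime as dt
import io
import math
import re
import wave
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phenoflow import privacy, simulator, streams
from phenoflow.config import StreamName
from phenoflow.simulator import (
    BehaviorProfile,
    ProfileError,
    duty_cycle_windows,
    generate_comm_events,
    make_position_fn,
    record_audio,
    sample_accelerometer,
    sample_gps,
    scan_wireless,
    simulate_period,
    take_survey,
    validate_profile,
)

START = dt.date(2024, 1, 1)


def tree_bytes(root: Path) -> dict[str, bytes]:
    return {str(p.relative_to(root)): p.read_bytes() for p in sorted(root.rglob("*")) if p.is_file()}


class TestProfile:
    def test_default_profile_is_consistent(self, profile):
        validate_profile(profile)

    def test_overlapping_segments_rejected(self, profile):
        seg = profile.daily_routine[1].model_copy(update={"start": "07:00"})
        bad = profile.model_copy(
            update={"daily_routine": [profile.daily_routine[0], seg] + list(profile.daily_routine[2:])}
        )
        with pytest.raises(ProfileError):
            validate_profile(bad)

    def test_day_must_be_fully_tiled(self, profile):
        bad = profile.model_copy(update={"daily_routine": list(profile.daily_routine[:-1])})
        with pytest.raises(ProfileError):
            validate_profile(bad)


class TestGps:
    def test_one_hz_during_in_motion_window(self):
        pos = lambda s: (42.36 + s * 1e-5, -71.05, True, "walking")
        df = sample_gps(pos, [(0.0, 60.0)], np.random.default_rng(0))
        assert abs(len(df) - 60) <= 1

    def test_zero_noise_stationary_pins_to_anchor(self):
        pos = lambda s: (42.36, -71.05, False, "rest")
        df = sample_gps(
            pos, [(0.0, 120.0)], np.random.default_rng(0), noise_sd=0.0, stationary_keep_p=1.0
        )
        assert (df["latitude"] == 42.36).all()
        assert (df["longitude"] == -71.05).all()

    def test_default_noise_inside_50ft_envelope(self):
        """90th-percentile horizontal error of the default noise model stays
        under 15.24 m (50 ft) over 10,000 fixes."""
        anchor = (42.3601, -71.0589)
        pos = lambda s: (*anchor, False, "rest")
        df = sample_gps(pos, [(0.0, 10_000.0)], np.random.default_rng(4), stationary_keep_p=1.0)
        lat = np.radians(df["latitude"].to_numpy())
        lon = np.radians(df["longitude"].to_numpy())
        la0, lo0 = map(math.radians, anchor)
        err = 2 * 6_371_000 * np.arcsin(
            np.sqrt(
                np.sin((lat - la0) / 2) ** 2
                + np.cos(la0) * np.cos(lat) * np.sin((lon - lo0) / 2) ** 2
            )
        )
        assert np.percentile(err, 90) <= 15.24

    def test_stationary_thinning_reduces_density(self):
        pos = lambda s: (42.36, -71.05, False, "rest")
        df = sample_gps(pos, [(0.0, 2000.0)], np.random.default_rng(1), stationary_keep_p=0.5)
        assert 800 <= len(df) <= 1200  # Binomial(2000, 0.5) within ~4.5 sigma


class TestAccelerometer:
    @pytest.mark.parametrize("rate,window", [(5.0, 60.0), (10.0, 60.0), (100.0, 10.0)])
    def test_count_is_rate_times_window(self, rate, window):
        df = sample_accelerometer(lambda s: "rest", [(0.0, window)], np.random.default_rng(0), rate=rate)
        assert abs(len(df) - rate * window) <= 1

    def test_rest_with_zero_noise_is_pure_gravity(self):
        df = sample_accelerometer(
            lambda s: "rest", [(0.0, 30.0)], np.random.default_rng(0), rate=10.0, noise_sd=0.0
        )
        mags = np.sqrt(df["x"] ** 2 + df["y"] ** 2 + df["z"] ** 2)
        assert (mags == 9.81).all()

    def test_walking_adds_step_cadence_on_vertical_axis(self):
        df = sample_accelerometer(
            lambda s: "walking", [(0.0, 60.0)], np.random.default_rng(0), rate=20.0, noise_sd=0.0
        )
        z = df["z"].to_numpy() - df["z"].mean()
        freqs = np.fft.rfftfreq(len(z), d=1 / 20.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(z)))]
        assert 1.5 <= peak <= 2.5

    @pytest.mark.parametrize("rate", [4.0, 101.0, 200.0, 0.0])
    def test_rates_outside_envelope_rejected(self, rate):
        with pytest.raises(ValueError):
            sample_accelerometer(lambda s: "rest", [(0.0, 10.0)], np.random.default_rng(0), rate=rate)


class TestWireless:
    def test_wifi_default_cycle_gives_12_batches_per_hour(self, profile):
        windows = duty_cycle_windows(1, 299, 3600)
        df = scan_wireless("wifi", profile.wifi_environment, windows, np.random.default_rng(0))
        assert df["timestamp"].nunique() == 12

    def test_empty_environment_yields_no_records(self):
        windows = duty_cycle_windows(60, 240, 3600)
        df = scan_wireless("bluetooth", [], windows, np.random.default_rng(0))
        assert df.empty

    def test_presence_window_gates_detections(self):
        dev = simulator.WirelessDevice(mac="aa:bb:cc:dd:ee:01", windows=[("10:00", "10:05")])
        windows = duty_cycle_windows(60, 240, simulator.DAY_SECONDS)
        df = scan_wireless("bluetooth", [dev], windows, np.random.default_rng(0))
        assert len(df) > 0
        secs = df["timestamp"] // 1000
        assert secs.between(10 * 3600, 10 * 3600 + 5 * 60).all()

    def test_rssi_is_negative_dbm(self, profile):
        windows = duty_cycle_windows(60, 240, 7200)
        df = scan_wireless("bluetooth", profile.bluetooth_environment, windows, np.random.default_rng(0))
        assert df["rssi"].between(-100, 0).all()


class TestCommEvents:
    def test_zero_rates_give_empty_logs(self):
        pool = [simulator.Contact(number="+16175550000", call_rate=0.0, text_rate=0.0)]
        calls, texts = generate_comm_events(pool, 30, np.random.default_rng(0))
        assert calls.empty and texts.empty

    def test_poisson_count_recovery_over_100_days(self):
        pool = [simulator.Contact(number="+16175550000", call_rate=2.0, text_rate=0.0)]
        calls, _ = generate_comm_events(pool, 100, np.random.default_rng(12))
        assert abs(len(calls) - 200) <= 3 * math.sqrt(200)

    def test_missed_calls_have_zero_duration_and_others_positive(self):
        pool = [simulator.Contact(number="+16175550000", call_rate=20.0, text_rate=0.0)]
        calls, _ = generate_comm_events(pool, 30, np.random.default_rng(3))
        missed = calls[calls["call_type"] == "missed"]
        taken = calls[calls["call_type"] != "missed"]
        assert (missed["duration"] == 0).all()
        assert (taken["duration"] >= 1).all()

    def test_raw_numbers_never_appear_in_output(self):
        pool = [simulator.Contact(number="+16175551234", call_rate=5.0, text_rate=5.0)]
        calls, texts = generate_comm_events(pool, 30, np.random.default_rng(0))
        blob = streams.to_csv_bytes(calls, "calls") + streams.to_csv_bytes(texts, "texts")
        assert b"6175551234" not in blob
        assert privacy.hash_identifier("+16175551234").encode() in blob


class TestSurveys:
    def test_answers_are_type_valid(self, default_cfg, profile):
        pos = make_position_fn(profile)
        survey = default_cfg.surveys[0]
        rng = np.random.default_rng(0)
        for _ in range(50):
            df = take_survey(survey, 1_700_000_000_000, profile, pos, rng, 68_400)
            by_q = {q.question_id: q for q in survey.questions}
            for row in df.itertuples():
                q = by_q[row.question_id]
                if q.qtype.value == "slider":
                    assert q.slider_min <= int(row.answer) <= q.slider_max
                elif q.qtype.value == "radio":
                    assert row.answer in q.options
                elif q.qtype.value == "checkbox":
                    assert all(p in q.options for p in row.answer.split(";") if p)
                assert row.notification_time <= row.start_time <= row.end_time

    def test_degenerate_latency_starts_at_notification(self, default_cfg, profile):
        instant = profile.model_copy(
            update={"survey_latency_log_mu": -50.0, "survey_latency_log_sigma": 0.0}
        )
        pos = make_position_fn(instant)
        df = take_survey(
            default_cfg.surveys[0], 1_700_000_000_000, instant, pos, np.random.default_rng(0), 0
        )
        assert (df["start_time"] == df["notification_time"]).all()

    def test_lognormal_latency_median_recovered(self, default_cfg, profile):
        pos = make_position_fn(profile)
        rng = np.random.default_rng(5)
        lat = [
            (
                take_survey(default_cfg.surveys[0], 0, profile, pos, rng, 0)["start_time"].iloc[0]
            )
            / 1000.0
            for _ in range(1000)
        ]
        median = np.median(lat)
        assert abs(median - math.exp(5)) / math.exp(5) < 0.10


class TestAudio:
    def test_zero_accept_probability_leaves_no_artifact(self, keypair, tmp_path):
        out = tmp_path / "audio"
        meta = record_audio(0, 30.0, 0.0, np.random.default_rng(0), keypair.public_part, out)
        assert meta is None
        assert not out.exists() or not any(out.iterdir())

    def test_long_request_truncated_at_max(self, keypair, tmp_path):
        meta = record_audio(
            0, 10.0, 1.0, np.random.default_rng(0), keypair.public_part, tmp_path,
            requested_duration=60.0,
        )
        assert meta["duration"] == 10.0

    def test_accepted_recording_decrypts_to_valid_wav(self, keypair, tmp_path):
        meta = record_audio(
            0, 20.0, 1.0, np.random.default_rng(1), keypair.public_part, tmp_path,
            requested_duration=3.0,
        )
        data = privacy.decrypt_envelope(
            privacy.EncryptedBlob.from_bytes(Path(meta["file_ref"]).read_bytes()),
            keypair.private_part,
        )
        with wave.open(io.BytesIO(data)) as w:
            assert w.getframerate() == 16000
            assert w.getnchannels() == 1
            assert abs(w.getnframes() / 16000 - 3.0) < 0.01


class TestSimulatePeriod:
    def test_same_seed_twice_gives_byte_identical_trees(self, light_cfg, profile, keypair, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for out in (a, b):
            simulate_period(
                light_cfg, profile, START, 1, participant_id="p1", out_dir=out,
                pub=keypair.public_part,
            )
        ta, tb = tree_bytes(a), tree_bytes(b)
        assert list(ta) == list(tb)
        assert all(ta[k] == tb[k] for k in ta)

    def test_different_seed_changes_output(self, light_cfg, profile, keypair, tmp_path):
        other = profile.model_copy(update={"rng_seed": profile.rng_seed + 1})
        r1 = simulate_period(light_cfg, profile, START, 1, pub=keypair.public_part)
        r2 = simulate_period(light_cfg, other, START, 1, pub=keypair.public_part)
        assert not r1.frames["gps"].equals(r2.frames["gps"])

    def test_all_streams_disabled_leaves_only_surveys(self, light_cfg, profile, tmp_path):
        cfg = light_cfg.model_copy(
            update={
                "sensor_settings": [
                    s.model_copy(update={"enabled": False}) for s in light_cfg.sensor_settings
                ]
            }
        )
        result = simulate_period(cfg, profile, START, 1, out_dir=tmp_path, participant_id="p1")
        assert set(result.frames) == {"survey_responses"}

    def test_one_day_defaults_populates_all_passive_streams(self, light_cfg, profile, keypair):
        result = simulate_period(light_cfg, profile, START, 1, pub=keypair.public_part)
        for stream in ("gps", "accelerometer", "wifi", "bluetooth", "power_state", "texts"):
            assert len(result.frames[stream]) > 0, stream

    def test_invalid_config_is_refused(self, light_cfg, profile):
        bad = light_cfg.model_copy(
            update={
                "sensor_settings": list(light_cfg.sensor_settings)
                + [light_cfg.sensor_settings[0]]
            }
        )
        from phenoflow.config import ConfigValidationError

        with pytest.raises(ConfigValidationError):
            simulate_period(bad, profile, START, 1)

    def test_duty_cycle_containment_exhaustive(self, light_cfg, profile, keypair):
        """No sampled record falls inside an off-window."""
        result = simulate_period(light_cfg, profile, START, 1, pub=keypair.public_part)
        day0 = result.frames["gps"]["timestamp"].min() // 86_400_000 * 86_400_000
        for stream in ("gps", "accelerometer", "wifi", "bluetooth"):
            setting = light_cfg.sensor(stream)
            cycle = setting.on_duration + setting.off_duration
            sec = (result.frames[stream]["timestamp"] - day0) / 1000.0 % 86400
            phase = sec % cycle
            assert (phase < setting.on_duration).all(), stream

    def test_emitted_files_match_documented_schemas_exactly(
        self, light_cfg, profile, keypair, tmp_path
    ):
        simulate_period(
            light_cfg, profile, START, 1, participant_id="p1", out_dir=tmp_path,
            pub=keypair.public_part,
        )
        for csv in tmp_path.rglob("*.csv"):
            stream = csv.parent.name
            header = csv.read_text().splitlines()[0]
            assert tuple(header.split(",")) == streams.SCHEMAS[stream].columns
            assert streams.validate_frame(streams.from_csv_bytes(csv.read_bytes(), stream), stream) == []

    def test_outputs_contain_no_raw_identifiers(self, light_cfg, profile, keypair, tmp_path):
        simulate_period(
            light_cfg, profile, START, 1, participant_id="p1", out_dir=tmp_path,
            pub=keypair.public_part,
        )
        raw_ids = {re.sub(r"\D", "", c.number) for c in profile.contact_pool}
        raw_ids |= {d.mac.replace(":", "").upper() for d in profile.wifi_environment}
        raw_ids |= {d.mac.replace(":", "").upper() for d in profile.bluetooth_environment}
        for csv in tmp_path.rglob("*.csv"):
            text = csv.read_text().upper()
            for ident in raw_ids:
                assert ident not in text, f"{ident} leaked into {csv}"

    def test_power_state_screen_events_strictly_alternate(self, light_cfg, profile):
        result = simulate_period(light_cfg, profile, START, 2)
        df = result.frames["power_state"]
        onoff = df[df["event"].isin(["screen_on", "screen_off"])]["event"].tolist()
        assert all(a != b for a, b in zip(onoff, onoff[1:]))
        assert onoff[0] == "screen_on"
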