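# phenoflow

A desk-scale re-creation of the data path of a smartphone **digital
phenotyping** platform — the kind of system used in psychiatric and
neurological research to quantify a patient's lived behavior
moment-by-moment from their own phone, rather than from episodic clinic
visits. Digital phenotyping couples *passive* data streams that need no
subject involvement (GPS trajectories, accelerometer traces, call and text
metadata, Wi-Fi/Bluetooth proximity scans, screen and power events) with
*active* data the subject supplies (in-situ surveys, voice diaries), and it
lives or dies by two engineering properties: raw research-quality data with
fully specified sampling settings, and privacy protection strong enough to
carry clinical populations.

phenoflow implements that whole path as an ordinary Python package, with a
simulated phone in place of a real one:

1. **Study configuration** (`phenoflow.config`) — a canonical JSON document
   fixes every study setting: which streams are collected, their duty
   cycles (on/off seconds) and sampling rates, the survey battery and its
   schedules, app text, and emergency contacts. Storing this file next to
   the raw data is what makes a study exactly repeatable.
2. **Privacy layer** (`phenoflow.privacy`) — direct identifiers (phone
   numbers, MAC addresses) are replaced by deterministic one-way SHA-256
   surrogate keys, so social structure survives but identities do not.
   Payloads are envelope-encrypted: a fresh AES-256 key per chunk (CTR +
   HMAC-SHA256, encrypt-then-MAC), wrapped under the study's 2048-bit RSA
   public key (OAEP). The device holds only the public half — it cannot
   read its own buffer — and the server re-encrypts at rest under a study
   master key.
3. **Device simulator** (`phenoflow.simulator`) — a scripted subject
   (anchors, commutes, contacts, wireless surroundings, screen habits,
   survey latency) emits every stream with its documented schema: GPS at
   1 Hz while in motion with a noise model inside the 30–50 ft accuracy
   envelope, accelerometer at 5–100 Hz in m/s², duty-cycled wireless scans,
   Poisson communication logs, alternating screen events, type-valid survey
   answers, and encrypted WAV voice diaries. Fully seeded: identical inputs
   give byte-identical output trees.
4. **Store-and-forward transport** (`phenoflow.transport`) — records are
   encrypted the moment they are serialized, buffered on the device, and
   uploaded only inside Wi-Fi availability windows; a chunk is deleted only
   after server acknowledgment, and the server deduplicates on content
   digest, so delivery is at-least-once and storage exactly-once even under
   injected upload faults. Ingest verifies digests, validates every row
   against the stream schema, quarantines anything suspect, and re-encrypts
   the rest.
5. **Summaries** (`phenoflow.summaries`) — the derived metrics surfaced per
   participant: survey response latency (notification → first interaction),
   the previous-week series of numerically quantifiable answers, a nightly
   sleep proxy (longest screen-quiet gap in the night window), per-stream
   daily coverage, and daily call/text counts.

Under the default settings a single simulated subject produces over
3 × 10⁶ scalar observations per day across the passive streams.

## Worked example

```bash
phenoflow run-all --workdir demo --days 2 --seed 7
```

runs the full path — key generation, two simulated days, encrypt-and-buffer,
transfer, ingest, summarize — and logs:

```
INFO phenoflow: pipeline complete for 35ydah73: {'stored': 263, 'duplicate': 0,
'quarantined': 0}; report at demo/report.json
```

263 hour-chunks were ingested with nothing quarantined. `demo/report.json`
then contains, for participant `35ydah73`:

* `survey_latency`: `[108.6, 59.3, 113.7]` seconds — the three survey
  prompts of the two days were each taken one to two minutes after
  notification (the profile draws latencies log-normal with median ≈148 s).
* `sleep_proxy`: `8.72` h for the first night — the scripted subject is
  quiet 23:30–07:30, and the longest screen-free gap in the 22:00–10:00
  window recovers that, plus the ordinary overshoot before the first and
  after the last use. (The last night of a run reads long because its
  window extends past the end of the data.)
* `stream_coverage`: `1.0` for gps and accelerometer on both days — every
  expected duty-cycle on-window contained data.
* `daily_comm_counts`: 3 calls / 21 texts, then 4 / 18 — Poisson draws
  around the profile's contact rates.

Re-running with the same seed reproduces `report.json` byte for byte.

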