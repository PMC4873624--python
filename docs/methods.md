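# Methods

This note documents the models, parameter choices, and numerical decisions
behind phenoflow, and what its synthetic data can and cannot show.

## Study configuration

A study is one canonical JSON document (UTF-8, sorted keys, explicit
`config_version`). JSON was chosen over a database-backed portal because
diff-ability is the point: two studies are comparable, and a validation
study provably identical, by comparing files. Parsing and validation are
separated — a malformed file is a *format* error, while a well-formed file
with bad settings yields a complete list of violations naming each field —
so study coordinators see every problem in one pass. Every downstream
module re-validates the config before using it.

Survey schedules are period-based: every `period_days` days from an anchor
date at a local `prompt_time` in the study's declared IANA timezone, stored
as UTC epoch milliseconds. "Biweekly" batteries are expressed as
`period_days=14` (fortnightly); a twice-weekly reading would be two daily
surveys with different anchors, which the schema also supports. The
expansion window is a half-open date interval, which makes "30-day window
starting at the anchor → 30 daily prompts" exact.

Participant IDs are 8 lowercase alphanumerics drawn from an RNG seeded by
SHA-256(study_id, seed): deterministic per (study, seed), ~2.8 × 10¹²
possible values, and carrying no information about the subject.

## Privacy layer

**Surrogate keys.** Phone numbers are canonicalized to their digits and MAC
addresses to 12 uppercase hex digits before SHA-256, so formatting cannot
split one identity into two surrogates. The default is unsalted, keeping
the mapping stable across time and studies (a surrogate seen in month 1
matches month 6, which the communication-network summaries rely on). An
optional per-study salt exists because the unsalted phone-number space is
small enough to dictionary-attack; deployments that fear that trade
cross-study linkability for it.

**Envelope encryption.** Each chunk gets a fresh 32-byte AES key, 32-byte
HMAC key, and 16-byte IV; the payload is AES-256-CTR encrypted and
authenticated with HMAC-SHA256 (encrypt-then-MAC over magic, version, IV,
ciphertext), and the two symmetric keys are wrapped together under
RSA-2048 OAEP-SHA256. An authenticated mode is non-negotiable here: ingest
must distinguish transport corruption from success, and tamper detection
falls out for free. CTR+HMAC was chosen as the authenticated construction
because both primitives have published test vectors the implementation is
pinned to (FIPS-197, SP 800-38A) and HMAC runs at C speed in the standard
library. One AES key covers one buffered chunk (an hour of one stream);
keys never exist outside the blob that wraps them. Supported RSA sizes are
2048/3072/4096 — 1024 is refused as below modern floor. Server-side at-rest
encryption derives separate encryption and MAC subkeys from the 32-byte
study master key via HMAC, so two studies' stores are mutually opaque.

The AES core is numpy-vectorized over blocks (table-driven SubBytes /
ShiftRows / MixColumns), which sustains roughly 5 MB/s — ample for
desk-scale volumes. `encrypt_envelope` accepts an optional seeded RNG used
*only* by the simulator so that simulated device trees are byte-identical
across reruns; production callers leave it unset and get system entropy.

## Device simulator

The behavior profile is the generative model of one subject:

* **Mobility** — labeled anchors (home, work) and a daily routine that
  tiles 24 h with stay and transit segments; transits interpolate along the
  great circle at constant speed. The default is an urban weekday with a
  30-minute walking commute each way. No road networks or heavy-tailed
  exploration: mobility realism is out of scope, duty-cycle and noise
  behavior are in scope.
* **GPS** — 1 Hz nominal while in motion. Stationary ticks survive with
  probability 0.5, emulating the OS suppressing queries for a phone it
  infers is not moving. Noise is isotropic Gaussian with σ = 7 m per
  horizontal axis, chosen so the 90th-percentile radial error
  (σ√(2 ln 10) ≈ 15.0 m ≈ 49 ft) sits just inside the 30–50 ft accuracy
  envelope typical of phone GPS. An `accuracy` column (the receiver's
  self-reported estimate) is included as an extension.
* **Accelerometer** — 5–100 Hz accepted, default 20 Hz on a 60 s on / 60 s
  off duty cycle. At rest: gravity on z plus σ = 0.05 m/s² sensor noise
  (zero noise gives magnitude exactly 9.81, which the unit tests exploit).
  Walking adds a 1.9 Hz vertical cadence of amplitude 1.5 m/s²; vehicle
  transit adds broadband vibration. These are minimal parametric
  signatures, not biomechanics.
* **Wireless** — Wi-Fi: an instantaneous snapshot of all present networks
  every 300 s. Bluetooth: a 60 s scan every 300 s, with detections of each
  present device Poisson-thinned at mean 3 per window. RSSI is the device's
  base level plus Gaussian jitter, clipped to [−100, −1] dBm.
* **Communication** — per-contact homogeneous Poisson calls and texts;
  call type 45/45/10 incoming/outgoing/missed, answered durations
  log-normal (median 90 s), missed durations exactly 0, text lengths
  geometric with mean 40 characters. Only surrogate keys ever reach an
  output file; no content field exists in either schema.
* **Screen/power** — screen sessions arrive at 60/day (a typical unlock
  rate) during non-quiet hours; the profile's quiet hours (23:30–07:30
  default) script the no-use period the sleep proxy should recover. Each
  session is an alternating on/off pair with Poisson touch events between;
  the charger connects near the start of quiet hours.
* **Surveys** — response latency is log-normal in seconds (default μ = 5,
  σ = 0.5 log-s, median ≈ 148 s). Answers are type-valid draws: checkbox
  subsets, one radio option, integer sliders within bounds, short
  free-text. The record carries the ground-truth location at the start
  instant.
* **Audio** — a daily voice-diary prompt; the synthesized waveform (seeded
  tone + noise, 16 kHz 16-bit mono WAV) is truncated at the configured
  maximum duration, accepted with probability 0.9, and encrypted the
  moment it is accepted: a discarded take leaves no file, an accepted one
  exists only as an envelope blob the device cannot reopen.

All randomness flows from per-(stream, day) children of one seed, so a run
is reproducible stream-by-stream and byte-identical end to end. Files are
one CSV per stream per UTC hour (`<participant>/<stream>/<ISO hour>.csv`),
timestamps UTC epoch milliseconds, floats at fixed precision.

What passing tests show: schemas, units, duty-cycle containment, privacy
of outputs, and that the summary algorithms recover the planted behavioral
parameters. What they do not show: performance on real human mobility,
real-device sensor artifacts (clock drift, dropped buffers, temperature
bias), or adversarial data.

## Transport

The device buffer holds only ciphertext: serialization and encryption are
one operation, and chunk files are written atomically (write-then-rename)
so no partial chunk is visible. Upload attempts tick every 10 simulated
minutes; inside a Wi-Fi window each pending chunk is offered, and it is
deleted only on acknowledgment. Injected faults take two forms — dropped
before storage, or stored with the ack lost — exercising both halves of
the at-least-once argument. The server deduplicates on (participant,
stream, period, content digest), so retries converge to exactly-once
storage. The ingest pipeline is decrypt → digest verify → header and
row-level schema validation (enums, ranges, monotone timestamps,
missed-call/zero-duration coupling) → re-encrypt under the master key →
append-only ledger update; failures quarantine the chunk with its reason.
Ledger statuses never regress: a chunk once stored stays stored, later
events notwithstanding. Buffer capacity is unbounded by default, with an
optional cap that refuses new chunks and records the refusal.

## Summaries

* **Latency** — survey "taken" means *started* (first interaction), not
  completed; latency = start − notification in seconds, one value per
  prompt. Physically impossible orderings (start before notification) are
  flagged and excluded, not clipped.
* **Previous-week series** — a rolling 168 h window before the reference
  instant (not calendar days, so the series is invariant to when in the
  day it is computed). Sliders contribute their value; radio answers their
  0-based option index; checkbox and free-response have no scalar and are
  excluded.
* **Sleep proxy** — per night window (default 22:00–10:00 local,
  deliberately wider than any plausible sleep period), duration = the
  longest gap between consecutive screen-use events (screen_on or
  screen_touch; screen_off is not use), bounded by the window edges; an
  event-free night yields the full window. Quality = count of use episodes
  in the window. The proxy is antitone in added events by construction.
  The last night of a dataset reads long because its window extends past
  the data; consumers should treat edge nights as censored.
* **Coverage** — fraction of a day's expected duty-cycle on-windows
  containing at least one record. A disabled stream reports as absent,
  never 0: "off by design" and "expected but missing" must not be
  conflated in a data-quality display.

All summaries are pure functions of ingested records plus config.

## Problem sizes

The test suite simulates single days under either the full default
configuration (one day ≈ 3.5 × 10⁶ scalar observations, used for the
data-volume check) or a thinned configuration (accelerometer 5 Hz, on 60 s
/ off 540 s) where only schema and logic are at stake. The acceptance
script uses a 600 s transit for the sampling-rate measurement and 10⁴
stationary fixes for the error percentile; at these sizes the percentile
estimate is stable to well under a foot across seeds.

## Known limitations

No real network stack, TLS, or cloud storage; the server is in-process.
No key rotation or HSM; private keys are PEM files. The RSA/AES
implementations are correctness-oriented (vector-pinned, constant-time
comparisons for tags) but have not been hardened against local
side-channel observers, which is acceptable for a simulation toolkit and
would not be for a production client. Survey content (validated clinical
scales) is deliberately out of scope: schedules and response mechanics are
modeled, item text is not. iOS/Android platform differences (e.g. absent
call/text logs on iOS) are not modeled — the simulator emits the richer
stream set.
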