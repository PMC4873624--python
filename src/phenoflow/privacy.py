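"""Identifier pseudonymization and envelope encryption.

Two privacy mechanisms protect participant data end to end:

* **Surrogate keys** — phone numbers and Wi-Fi/Bluetooth MAC addresses are
  replaced by their SHA-256 digest after canonicalization. The mapping is
  deterministic (the same number always yields the same surrogate, so
  communication networks remain analyzable) and one-way. An optional
  per-study salt is available for deployments worried about dictionary
  attacks on the phone-number space; the default is unsalted so surrogate
  keys are comparable across studies.

* **Envelope encryption** — each payload is encrypted under a fresh random
  AES-256 key (CTR mode) authenticated with HMAC-SHA256, and the symmetric
  keys are wrapped with the study's 2048-bit RSA public key (OAEP). The
  device holds only the public half: it can produce envelopes but can never
  reopen them, so a lost or stolen phone reveals nothing. The study server
  holds the private half, decrypts on ingest, and re-encrypts at rest under
  a study master key.
"""

from __future__ import annotations

import hashlib
import hmac
import re
import secrets
import struct
from dataclasses import dataclass

from . import _aes, _rsa
from ._rsa import (
    RSAPrivateKey,
    RSAPublicKey,
    private_key_from_pem,
    private_key_to_pem,
    public_key_from_pem,
    public_key_to_pem,
)

__all__ = [
    "SurrogateKey",
    "canonicalize_identifier",
    "hash_identifier",
    "KeyPair",
    "generate_keypair",
    "EncryptedBlob",
    "StorageRecord",
    "encrypt_envelope",
    "decrypt_envelope",
    "encrypt_with_master",
    "decrypt_with_master",
    "reencrypt_with_master",
    "generate_master_key",
    "DecryptionError",
    "RSAPublicKey",
    "RSAPrivateKey",
    "public_key_to_pem",
    "private_key_to_pem",
    "public_key_from_pem",
    "private_key_from_pem",
]

SurrogateKey = str  # 64 lowercase hex characters (256-bit digest)

_SUPPORTED_RSA_BITS = (2048, 3072, 4096)
_MAC_RE = re.compile(r"^[0-9A-Fa-f]{2}([:\-]?[0-9A-Fa-f]{2}){5}$")

_ENVELOPE_MAGIC = b"PFE1"
_STORAGE_MAGIC = b"PFM1"
_VERSION = 1


class DecryptionError(Exception):
    """Authenticated decryption failed: wrong key or tampered ciphertext."""


def canonicalize_identifier(raw: str) -> str:
    """Normalize a phone number or MAC address before hashing.

    MAC addresses (six hex octets, optionally ``:``/``-`` separated) become
    12 uppercase hex digits; anything else is treated as a phone number and
    reduced to its digits (so formatting and separators do not change the
    surrogate key).
    """
    raw = raw.strip()
    if _MAC_RE.match(raw):
        canon = re.sub(r"[:\-]", "", raw).upper()
    else:
        canon = re.sub(r"\D", "", raw)
    if not canon:
        raise ValueError(f"identifier {raw!r} is empty after canonicalization")
    return canon


def hash_identifier(raw: str, study_salt: bytes | None = None) -> SurrogateKey:
    """One-way SHA-256 surrogate key for a phone number or MAC address."""
    canon = canonicalize_identifier(raw)
    h = hashlib.sha256()
    if study_salt:
        h.update(study_salt)
    h.update(canon.encode("ascii"))
    return h.hexdigest()


@dataclass(frozen=True)
class KeyPair:
    public_part: RSAPublicKey
    private_part: RSAPrivateKey


def generate_keypair(bits: int = 2048, rng=None) -> KeyPair:
    """Generate a study RSA keypair (2048-bit modulus by default)."""
    if bits not in _SUPPORTED_RSA_BITS:
        raise ValueError(f"unsupported RSA size {bits}; choose one of {_SUPPORTED_RSA_BITS}")
    priv = _rsa.generate_rsa_keypair(bits, rng=rng)
    return KeyPair(public_part=priv.public_key(), private_part=priv)


# ---------------------------------------------------------------------------
# Envelope containers


def _pack_fields(magic: bytes, *fields: bytes) -> bytes:
    out = [magic, bytes([_VERSION])]
    for f in fields:
        out.append(struct.pack(">I", len(f)))
        out.append(f)
    return b"".join(out)


def _unpack_fields(data: bytes, magic: bytes, n_fields: int) -> list[bytes]:
    if data[:4] != magic:
        raise ValueError("bad container magic")
    if data[4] != _VERSION:
        raise ValueError(f"unsupported container version {data[4]}")
    pos = 5
    fields = []
    for _ in range(n_fields):
        (length,) = struct.unpack_from(">I", data, pos)
        pos += 4
        fields.append(data[pos : pos + length])
        pos += length
    if pos != len(data):
        raise ValueError("trailing bytes in container")
    return fields


@dataclass(frozen=True)
class EncryptedBlob:
    """Device-side envelope: RSA-wrapped symmetric keys + IV + ciphertext."""

    wrapped_key: bytes
    iv: bytes
    ciphertext: bytes
    tag: bytes
    payload_length: int

    def to_bytes(self) -> bytes:
        return _pack_fields(
            _ENVELOPE_MAGIC,
            self.wrapped_key,
            self.iv,
            self.ciphertext,
            self.tag,
            struct.pack(">Q", self.payload_length),
        )

    @classmethod
    def from_bytes(cls, data: bytes) -> "EncryptedBlob":
        wrapped, iv, ct, tag, plen = _unpack_fields(data, _ENVELOPE_MAGIC, 5)
        return cls(wrapped, iv, ct, tag, struct.unpack(">Q", plen)[0])


@dataclass(frozen=True)
class StorageRecord:
    """Server-side at-rest record, encrypted under the study master key."""

    iv: bytes
    ciphertext: bytes
    tag: bytes
    payload_length: int

    def to_bytes(self) -> bytes:
        return _pack_fields(
            _STORAGE_MAGIC, self.iv, self.ciphertext, self.tag,
            struct.pack(">Q", self.payload_length),
        )

    @classmethod
    def from_bytes(cls, data: bytes) -> "StorageRecord":
        iv, ct, tag, plen = _unpack_fields(data, _STORAGE_MAGIC, 4)
        return cls(iv, ct, tag, struct.unpack(">Q", plen)[0])


def _mac(key: bytes, magic: bytes, iv: bytes, ct: bytes) -> bytes:
    return hmac.new(key, magic + bytes([_VERSION]) + iv + ct, hashlib.sha256).digest()


def _token_bytes(rng, n: int) -> bytes:
    if rng is None:
        return secrets.token_bytes(n)
    if hasattr(rng, "bytes"):  # numpy Generator
        return rng.bytes(n)
    return rng.randbytes(n)  # random.Random


def encrypt_envelope(plaintext: bytes, pub: RSAPublicKey, rng=None) -> EncryptedBlob:
    """Encrypt ``plaintext`` under a fresh AES key wrapped with ``pub``.

    A new AES-256 key, HMAC key, and IV are drawn per call and exist only
    inside the returned blob's RSA-wrapped header: nothing reusable is
    retained device-side. ``rng`` (a numpy Generator or ``random.Random``)
    overrides system entropy only so the device simulator can produce
    byte-identical runs; real deployments leave it unset.
    """
    if not isinstance(pub, RSAPublicKey):
        raise TypeError("pub must be an RSAPublicKey")
    aes_key = _token_bytes(rng, 32)
    mac_key = _token_bytes(rng, 32)
    iv = _token_bytes(rng, 16)
    ct = _aes.ctr_keystream_xor(aes_key, iv, plaintext)
    tag = _mac(mac_key, _ENVELOPE_MAGIC, iv, ct)
    wrapped = _rsa.oaep_encrypt(pub, aes_key + mac_key, seed=_token_bytes(rng, 32))
    return EncryptedBlob(wrapped, iv, ct, tag, len(plaintext))


def decrypt_envelope(blob: EncryptedBlob, priv: RSAPrivateKey) -> bytes:
    """Recover the plaintext; raises :class:`DecryptionError` on any failure."""
    try:
        keys = _rsa.oaep_decrypt(priv, blob.wrapped_key)
    except _rsa.OAEPError as exc:
        raise DecryptionError("key unwrap failed") from exc
    if len(keys) != 64:
        raise DecryptionError("unexpected wrapped key length")
    aes_key, mac_key = keys[:32], keys[32:]
    expected = _mac(mac_key, _ENVELOPE_MAGIC, blob.iv, blob.ciphertext)
    if not hmac.compare_digest(expected, blob.tag):
        raise DecryptionError("authentication tag mismatch")
    pt = _aes.ctr_keystream_xor(aes_key, blob.iv, blob.ciphertext)
    if len(pt) != blob.payload_length:
        raise DecryptionError("payload length mismatch")
    return pt


def generate_master_key() -> bytes:
    """Fresh 32-byte study master key for at-rest storage."""
    return secrets.token_bytes(32)


def _master_subkeys(master: bytes) -> tuple[bytes, bytes]:
    if len(master) != 32:
        raise ValueError("master key must be 32 bytes")
    enc = hmac.new(master, b"phenoflow-storage-enc", hashlib.sha256).digest()
    mac = hmac.new(master, b"phenoflow-storage-mac", hashlib.sha256).digest()
    return enc, mac


def encrypt_with_master(plaintext: bytes, master: bytes) -> StorageRecord:
    enc_key, mac_key = _master_subkeys(master)
    iv = secrets.token_bytes(16)
    ct = _aes.ctr_keystream_xor(enc_key, iv, plaintext)
    return StorageRecord(iv, ct, _mac(mac_key, _STORAGE_MAGIC, iv, ct), len(plaintext))


def decrypt_with_master(record: StorageRecord, master: bytes) -> bytes:
    enc_key, mac_key = _master_subkeys(master)
    expected = _mac(mac_key, _STORAGE_MAGIC, record.iv, record.ciphertext)
    if not hmac.compare_digest(expected, record.tag):
        raise DecryptionError("storage authentication tag mismatch")
    pt = _aes.ctr_keystream_xor(enc_key, record.iv, record.ciphertext)
    if len(pt) != record.payload_length:
        raise DecryptionError("payload length mismatch")
    return pt


def reencrypt_with_master(
    blob: EncryptedBlob, priv: RSAPrivateKey, master: bytes
) -> StorageRecord:
    """Server-side re-encryption: open the device envelope, seal at rest."""
    return encrypt_with_master(decrypt_envelope(blob, priv), master)
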