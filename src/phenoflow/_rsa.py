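"""RSA key generation, OAEP padding, and PEM serialization.

Key generation uses Miller-Rabin probable primes from system entropy (or a
caller-supplied RNG for reproducible tests). Encryption is RSAES-OAEP with
SHA-256 and MGF1-SHA256, suitable for wrapping symmetric keys. Keys
serialize to the interoperable formats: SubjectPublicKeyInfo ("PUBLIC KEY")
and PKCS#8 ("PRIVATE KEY") PEM, via a minimal DER codec.
"""

from __future__ import annotations

import base64
import hashlib
import math
import secrets
from dataclasses import dataclass

__all__ = [
    "RSAPublicKey",
    "RSAPrivateKey",
    "generate_rsa_keypair",
    "oaep_encrypt",
    "oaep_decrypt",
    "OAEPError",
    "public_key_to_pem",
    "private_key_to_pem",
    "public_key_from_pem",
    "private_key_from_pem",
]

_HLEN = 32  # SHA-256


class OAEPError(ValueError):
    """Raised when OAEP decryption fails (wrong key, corrupt ciphertext)."""


@dataclass(frozen=True)
class RSAPublicKey:
    n: int
    e: int

    @property
    def bit_length(self) -> int:
        return self.n.bit_length()

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8


@dataclass(frozen=True)
class RSAPrivateKey:
    n: int
    e: int
    d: int
    p: int
    q: int
    dp: int
    dq: int
    qinv: int

    @property
    def bit_length(self) -> int:
        return self.n.bit_length()

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8

    def public_key(self) -> RSAPublicKey:
        return RSAPublicKey(self.n, self.e)

    def decrypt_int(self, c: int) -> int:
        # CRT speedup
        m1 = pow(c % self.p, self.dp, self.p)
        m2 = pow(c % self.q, self.dq, self.q)
        h = (self.qinv * (m1 - m2)) % self.p
        return m2 + h * self.q


def _sieve(limit: int) -> list[int]:
    flags = bytearray([1]) * limit
    flags[0:2] = b"\x00\x00"
    for i in range(2, int(limit**0.5) + 1):
        if flags[i]:
            flags[i * i :: i] = b"\x00" * len(flags[i * i :: i])
    return [i for i in range(limit) if flags[i]]


_SMALL_PRIMES = _sieve(2000)


def _is_probable_prime(n: int, rng, rounds: int = 40) -> bool:
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d = n - 1
    r = 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for _ in range(rounds):
        a = rng.randrange(2, n - 2)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = pow(x, 2, n)
            if x == n - 1:
                break
        else:
            return False
    return True


def _gen_prime(bits: int, e: int, rng) -> int:
    while True:
        # top two bits set so the product of two such primes has exactly 2*bits
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | (1 << (bits - 2)) | 1
        if math.gcd(e, cand - 1) != 1:
            continue
        if _is_probable_prime(cand, rng):
            return cand


def generate_rsa_keypair(bits: int = 2048, rng=None) -> RSAPrivateKey:
    """Generate an RSA private key with modulus of exactly ``bits`` bits.

    ``rng`` defaults to system entropy; pass a seeded ``random.Random``
    only for reproducible test fixtures.
    """
    if rng is None:
        rng = secrets.SystemRandom()
    e = 65537
    while True:
        p = _gen_prime(bits // 2, e, rng)
        q = _gen_prime(bits // 2, e, rng)
        if p == q:
            continue
        n = p * q
        if n.bit_length() != bits:
            continue
        lam = (p - 1) * (q - 1) // math.gcd(p - 1, q - 1)
        d = pow(e, -1, lam)
        if p < q:
            p, q = q, p
        return RSAPrivateKey(
            n=n,
            e=e,
            d=d,
            p=p,
            q=q,
            dp=d % (p - 1),
            dq=d % (q - 1),
            qinv=pow(q, -1, p),
        )


def _mgf1(seed: bytes, length: int) -> bytes:
    out = b""
    for counter in range((length + _HLEN - 1) // _HLEN):
        out += hashlib.sha256(seed + counter.to_bytes(4, "big")).digest()
    return out[:length]


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def oaep_encrypt(
    pub: RSAPublicKey, message: bytes, label: bytes = b"", seed: bytes | None = None
) -> bytes:
    k = pub.byte_length
    if len(message) > k - 2 * _HLEN - 2:
        raise ValueError("message too long for RSA-OAEP with this key")
    lhash = hashlib.sha256(label).digest()
    ps = b"\x00" * (k - len(message) - 2 * _HLEN - 2)
    db = lhash + ps + b"\x01" + message
    if seed is None:
        seed = secrets.token_bytes(_HLEN)
    elif len(seed) != _HLEN:
        raise ValueError("OAEP seed must be 32 bytes")
    masked_db = _xor(db, _mgf1(seed, k - _HLEN - 1))
    masked_seed = _xor(seed, _mgf1(masked_db, _HLEN))
    em = b"\x00" + masked_seed + masked_db
    c = pow(int.from_bytes(em, "big"), pub.e, pub.n)
    return c.to_bytes(k, "big")


def oaep_decrypt(priv: RSAPrivateKey, ciphertext: bytes, label: bytes = b"") -> bytes:
    k = priv.byte_length
    if len(ciphertext) != k:
        raise OAEPError("ciphertext length mismatch")
    c = int.from_bytes(ciphertext, "big")
    if c >= priv.n:
        raise OAEPError("ciphertext out of range")
    em = priv.decrypt_int(c).to_bytes(k, "big")
    lhash = hashlib.sha256(label).digest()
    masked_seed, masked_db = em[1 : 1 + _HLEN], em[1 + _HLEN :]
    seed = _xor(masked_seed, _mgf1(masked_db, _HLEN))
    db = _xor(masked_db, _mgf1(seed, k - _HLEN - 1))
    # single failure path: do not reveal which check failed
    ok = em[0] == 0 and db[:_HLEN] == lhash
    idx = db.find(b"\x01", _HLEN)
    if not ok or idx < 0 or any(db[_HLEN:idx]):
        raise OAEPError("OAEP decoding failed")
    return db[idx + 1 :]


# ---------------------------------------------------------------------------
# DER / PEM


def _der_len(n: int) -> bytes:
    if n < 0x80:
        return bytes([n])
    body = n.to_bytes((n.bit_length() + 7) // 8, "big")
    return bytes([0x80 | len(body)]) + body


def _der_int(v: int) -> bytes:
    body = v.to_bytes((v.bit_length() + 8) // 8, "big") or b"\x00"
    return b"\x02" + _der_len(len(body)) + body


def _der_seq(*parts: bytes) -> bytes:
    body = b"".join(parts)
    return b"\x30" + _der_len(len(body)) + body


# AlgorithmIdentifier for rsaEncryption (OID 1.2.840.113549.1.1.1) with NULL params
_RSA_ALG_ID = _der_seq(bytes.fromhex("06092a864886f70d010101"), b"\x05\x00")


class _DerReader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def _read_len(self) -> int:
        first = self.data[self.pos]
        self.pos += 1
        if first < 0x80:
            return first
        nbytes = first & 0x7F
        val = int.from_bytes(self.data[self.pos : self.pos + nbytes], "big")
        self.pos += nbytes
        return val

    def expect(self, tag: int) -> bytes:
        if self.pos >= len(self.data) or self.data[self.pos] != tag:
            raise ValueError(f"DER: expected tag 0x{tag:02x}")
        self.pos += 1
        length = self._read_len()
        body = self.data[self.pos : self.pos + length]
        self.pos += length
        return body

    def read_int(self) -> int:
        return int.from_bytes(self.expect(0x02), "big")


def _pem_wrap(label: str, der: bytes) -> str:
    b64 = base64.b64encode(der).decode()
    lines = [b64[i : i + 64] for i in range(0, len(b64), 64)]
    return f"-----BEGIN {label}-----\n" + "\n".join(lines) + f"\n-----END {label}-----\n"


def _pem_unwrap(pem: str, label: str) -> bytes:
    begin, end = f"-----BEGIN {label}-----", f"-----END {label}-----"
    if begin not in pem or end not in pem:
        raise ValueError(f"not a {label} PEM")
    body = pem.split(begin, 1)[1].split(end, 1)[0]
    return base64.b64decode("".join(body.split()))


def public_key_to_pem(pub: RSAPublicKey) -> str:
    rsa_pub = _der_seq(_der_int(pub.n), _der_int(pub.e))
    spki = _der_seq(
        _RSA_ALG_ID,
        b"\x03" + _der_len(len(rsa_pub) + 1) + b"\x00" + rsa_pub,
    )
    return _pem_wrap("PUBLIC KEY", spki)


def private_key_to_pem(priv: RSAPrivateKey) -> str:
    rsa_priv = _der_seq(
        _der_int(0),
        _der_int(priv.n),
        _der_int(priv.e),
        _der_int(priv.d),
        _der_int(priv.p),
        _der_int(priv.q),
        _der_int(priv.dp),
        _der_int(priv.dq),
        _der_int(priv.qinv),
    )
    pkcs8 = _der_seq(
        _der_int(0),
        _RSA_ALG_ID,
        b"\x04" + _der_len(len(rsa_priv)) + rsa_priv,
    )
    return _pem_wrap("PRIVATE KEY", pkcs8)


def public_key_from_pem(pem: str) -> RSAPublicKey:
    spki = _DerReader(_pem_unwrap(pem, "PUBLIC KEY")).expect(0x30)
    r = _DerReader(spki)
    r.expect(0x30)  # algorithm identifier
    bitstring = r.expect(0x03)
    inner = _DerReader(bitstring[1:])  # skip unused-bits byte
    seq = _DerReader(inner.expect(0x30))
    return RSAPublicKey(n=seq.read_int(), e=seq.read_int())


def private_key_from_pem(pem: str) -> RSAPrivateKey:
    pkcs8 = _DerReader(_pem_unwrap(pem, "PRIVATE KEY")).expect(0x30)
    r = _DerReader(pkcs8)
    r.read_int()  # version
    r.expect(0x30)  # algorithm identifier
    rsa_der = r.expect(0x04)
    s = _DerReader(_DerReader(rsa_der).expect(0x30))
    s.read_int()  # version
    vals = [s.read_int() for _ in range(8)]
    return RSAPrivateKey(*vals)
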