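"""AES-256 block cipher and CTR keystream, vectorized with numpy.

Implements the Rijndael forward cipher only: CTR mode needs no inverse
cipher, and the envelope layer authenticates with HMAC before decrypting,
so the same keystream routine serves both directions.

Tables are derived at import time from GF(2^8) arithmetic rather than
transcribed, and the implementation is pinned to the FIPS-197 and
SP 800-38A published test vectors in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["expand_key", "encrypt_blocks", "ctr_keystream_xor"]


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # log/antilog tables over GF(2^8) with generator 0x03
    exp = np.zeros(256, dtype=np.uint8)
    log = np.zeros(256, dtype=np.int32)
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        # multiply by 0x03 = x * 2 ^ x
        x ^= (x << 1) ^ (0x1B if x & 0x80 else 0)
        x &= 0xFF
    exp[255] = exp[0]

    sbox = np.zeros(256, dtype=np.uint8)
    for b in range(256):
        inv = 0 if b == 0 else int(exp[255 - log[b]])
        s = inv
        for shift in (1, 2, 3, 4):
            s ^= ((inv << shift) | (inv >> (8 - shift))) & 0xFF
        sbox[b] = s ^ 0x63

    mul2 = np.array(
        [((b << 1) ^ (0x1B if b & 0x80 else 0)) & 0xFF for b in range(256)],
        dtype=np.uint8,
    )
    mul3 = mul2 ^ np.arange(256, dtype=np.uint8)
    return sbox, mul2, mul3


_SBOX, _MUL2, _MUL3 = _build_tables()

# ShiftRows as a permutation of the 16 byte positions (column-major state):
# byte at (row r, col c) lives at index 4c + r and moves from column (c + r) mod 4.
_SHIFT = np.array([4 * ((c + r) % 4) + r for c in range(4) for r in range(4)])

_RCON = (0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40)


def expand_key(key: bytes) -> np.ndarray:
    """Expand a 32-byte key into 15 round keys, shape (15, 16) uint8."""
    if len(key) != 32:
        raise ValueError("AES-256 key must be 32 bytes")
    words = [list(key[4 * i : 4 * i + 4]) for i in range(8)]
    for i in range(8, 60):
        t = list(words[i - 1])
        if i % 8 == 0:
            t = t[1:] + t[:1]
            t = [int(_SBOX[b]) for b in t]
            t[0] ^= _RCON[i // 8 - 1]
        elif i % 8 == 4:
            t = [int(_SBOX[b]) for b in t]
        words.append([a ^ b for a, b in zip(words[i - 8], t)])
    flat = [b for w in words for b in w]
    return np.array(flat, dtype=np.uint8).reshape(15, 16)


def _mix_columns(state: np.ndarray) -> np.ndarray:
    s = state.reshape(-1, 4, 4)
    a, b, c, d = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    return np.stack(
        [
            _MUL2[a] ^ _MUL3[b] ^ c ^ d,
            a ^ _MUL2[b] ^ _MUL3[c] ^ d,
            a ^ b ^ _MUL2[c] ^ _MUL3[d],
            _MUL3[a] ^ b ^ c ^ _MUL2[d],
        ],
        axis=-1,
    ).reshape(-1, 16)


def encrypt_blocks(round_keys: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Encrypt an (n, 16) uint8 array of blocks under expanded round keys."""
    state = blocks ^ round_keys[0]
    for r in range(1, 14):
        state = _SBOX[state][:, _SHIFT]
        state = _mix_columns(state)
        state ^= round_keys[r]
    state = _SBOX[state][:, _SHIFT]
    return state ^ round_keys[14]


def ctr_keystream_xor(key: bytes, iv: bytes, data: bytes) -> bytes:
    """XOR ``data`` with the AES-256-CTR keystream for (key, iv).

    The counter block is the 16-byte IV whose last 4 bytes increment as a
    big-endian 32-bit counter (wrapping), i.e. a 12-byte nonce plus a block
    counter seeded from the IV tail. Encryption and decryption are the same
    operation.
    """
    if len(iv) != 16:
        raise ValueError("IV must be 16 bytes")
    if not data:
        return b""
    n = (len(data) + 15) // 16
    rk = expand_key(key)
    ctr0 = int.from_bytes(iv[12:16], "big")
    ctr = (ctr0 + np.arange(n, dtype=np.uint64)) & np.uint64(0xFFFFFFFF)
    blocks = np.empty((n, 16), dtype=np.uint8)
    blocks[:, :12] = np.frombuffer(iv[:12], dtype=np.uint8)
    for j in range(4):
        blocks[:, 12 + j] = (ctr >> np.uint64(8 * (3 - j))).astype(np.uint64) & np.uint64(0xFF)
    stream = encrypt_blocks(rk, blocks).reshape(-1)[: len(data)]
    buf = np.frombuffer(data, dtype=np.uint8) ^ stream
    return buf.tobytes()
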