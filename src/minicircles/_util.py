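"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit base codes; anything else (N) maps to 255 and poisons k-mers.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def at_fraction(seq: str) -> float:
    """Fraction of A+T over sequence length (0 for empty input)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("A") + s.count("T")) / len(s)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention of printed percentage tables."""
    factor = 10.0**ndigits
    scaled = x * factor
    return (np.floor(scaled + 0.5) if scaled >= 0 else np.ceil(scaled - 0.5)) / factor


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit encode every k-mer of ``seq`` as int64; k-mers touching a non-ACGT
    base come out negative so callers can mask them."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes == 255
    vals = np.zeros(n, dtype=np.int64)
    poison = np.zeros(n, dtype=bool)
    for i in range(k):
        vals = (vals << 2) | codes[i : i + n]
        poison |= bad[i : i + n]
    vals[poison] = -1
    return vals


def wrap_substring(seq: str, start: int, length: int) -> str:
    """Substring of a circular sequence, 0-based start, wrapping past the end."""
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    out = seq[start:]
    length -= n - start
    while length > n:
        out += seq
        length -= n
    return out + seq[:length]
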