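"""Deterministic seed derivation.

One master seed fans out to per-component seeds via a splitmix64-style
mix of the master value with a label hash, so that every random stage
(fold assignment, embedding init, negative sampling, data synthesis) is
independently and reproducibly seeded.  Derived seeds are kept below
2**31 so they fit any downstream RNG API.
"""

from __future__ import annotations


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def derive_seed(master: int, *labels) -> int:
    """Derive a sub-seed from a master seed and a label path."""
    state = _splitmix64(master & 0xFFFFFFFFFFFFFFFF)
    for label in labels:
        h = 0xCBF29CE484222325  # FNV-1a over the label's string form
        for byte in str(label).encode():
            h = ((h ^ byte) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
        state = _splitmix64(state ^ h)
    return state % (2 ** 31)
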