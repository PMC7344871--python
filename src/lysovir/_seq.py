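"""Low-level nucleotide encoding helpers shared across modules.

Bases are encoded A=0, C=1, G=2, T=3; any other character (N, ambiguity
codes) maps to 4 and never matches anything.
"""
from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement table in code space; N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    return float(np.count_nonzero((codes == 1) | (codes == 2)) / codes.size)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. random DNA with the given expected GC content."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return decode(codes)
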