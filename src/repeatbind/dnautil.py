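"""Small DNA helpers shared across modules.

Sequences are plain Python strings of ACGT (N tolerated where noted);
numeric work uses 2-bit integer codes in numpy arrays (A=0, C=1, G=2, T=3,
anything else = 255).
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (255 for non-ACGT)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability `rate`."""
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hit = rng.random(len(codes)) < rate
    # substitution to one of the three other bases
    codes[hit] = (codes[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return decode(codes)
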