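"""Low-level nucleotide sequence utilities shared across the package.

Sequences are plain Python strings over {A,C,G,T,N} at API boundaries and
numpy uint8 code arrays (A=0, C=1, G=2, T=3, N/other=4) in hot paths.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string."""
    return _DECODE[np.minimum(codes, N_CODE)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with the requested expected GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def run_length_at(seq: str, pos: int) -> int:
    """Length of the maximal homopolymer run containing position ``pos``."""
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    n = len(seq)
    while j + 1 < n and seq[j + 1] == base:
        j += 1
    return j - i + 1
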