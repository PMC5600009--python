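"""Small DNA sequence helpers shared across modules."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# A,C,G,T -> 0,1,2,3; everything else -> 4 (never matches)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c < 4 else "N" for c in codes)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
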