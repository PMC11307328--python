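"""Small nucleotide-sequence helpers used throughout the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (ambiguity codes map to N-like behaviour)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Strand-insensitive canonical form: lexicographic min of seq and its
    reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform ACGT string of the given length."""
    idx = rng.integers(0, 4, size=length)
    return "".join(ALPHABET[i] for i in idx)


def as_bytes(seq: str) -> np.ndarray:
    """Sequence as a uint8 numpy array for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
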