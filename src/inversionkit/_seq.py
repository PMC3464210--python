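"""Small shared sequence helpers."""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA, deterministic under the generator's state."""
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")
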