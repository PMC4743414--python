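"""Small shared helpers: alphabet encoding, rounding and RNG conventions."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# index 4 is reserved for N / any unrecognised character
N_INDEX = 4

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA into integer codes A=0 C=1 G=2 T=3, anything else 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, N_INDEX, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Percentages in report tables are pinned to this convention.
    """
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def percent(k: int, n: int) -> int:
    """``round_half_away(100 * k / n)``; raises on an empty denominator."""
    if n <= 0:
        raise ValueError("percentage of an empty set is undefined")
    return round_half_away(100.0 * k / n)


def keyed_rng(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, stream name).

    Each generator call owns one stream, so adding a new generator never
    perturbs the output of existing ones for a given seed.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *name.encode("ascii")])
    return np.random.default_rng(ss)
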