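"""Small shared helpers: sequence arithmetic, rounding, RNG plumbing."""

from __future__ import annotations

import math

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_RC)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a DNA string for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def round_sigfigs(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq: str, rng: np.random.Generator, n_subs: int) -> str:
    """Introduce ``n_subs`` random substitutions at distinct positions."""
    if n_subs <= 0:
        return seq
    n_subs = min(n_subs, len(seq))
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)
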