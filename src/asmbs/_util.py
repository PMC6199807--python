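"""Small shared helpers: DNA string ops, logit helpers, seeded RNG spawning."""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str) -> str:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def expit(x):
    return _expit(np.asarray(x, dtype=float))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one integer seed.

    Uses SeedSequence spawning so that child streams are statistically
    independent and stable across runs.
    """
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(child) for child in ss.spawn(n)]
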