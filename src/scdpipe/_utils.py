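"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np


def nearest_rank_percentile(values, pct: float) -> float:
    """Nearest-rank (type-1) percentile.

    Returns the smallest observed value such that at least ``pct`` per cent
    of the observations are less than or equal to it.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("percentile of empty sample")
    if not 0 < pct <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {pct}")
    rank = math.ceil(pct / 100.0 * n)  # 1-based
    return float(arr[rank - 1])


def expand_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed, deterministically.

    Stable across runs and platforms; result is a valid 31-bit seed.
    """
    rng = np.random.SeedSequence([seed, abs(hash_stage(stage))])
    return int(rng.generate_state(1)[0] % (2**31 - 1))


def hash_stage(stage: str) -> int:
    # stable (non-salted) string hash: FNV-1a 32-bit
    h = 0x811C9DC5
    for byte in stage.encode():
        h = ((h ^ byte) * 0x01000193) & 0xFFFFFFFF
    return h
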