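"""Seeding and small shared helpers."""

from __future__ import annotations

import numpy as np


def derive_seed(*parts: int) -> int:
    """Deterministically derive an independent child seed from integer parts.

    Built on :class:`numpy.random.SeedSequence`, so distinct part tuples give
    statistically independent streams and adding new tuples never perturbs
    existing ones.  The result fits in 31 bits.
    """
    for q in parts:
        if int(q) < 0:
            raise ValueError("seed parts must be non-negative integers")
    state = np.random.SeedSequence(tuple(int(q) for q in parts)).generate_state(1)
    return int(state[0] % (2**31))


def check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite entries")
    return arr
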