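"""Shared numeric helpers: deterministic rounding and seed derivation."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Every count computation in the package (split sizes, flip quotas,
    positive-class counts) goes through this one rule so results do not
    depend on the platform's default banker's rounding.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed from a master seed and an integer key path.

    Built on :class:`numpy.random.SeedSequence` spawn keys, which are stable
    across platforms and numpy versions, so any single cell of a large
    experiment can be reproduced in isolation from ``(master_seed, key)``.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0])
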