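"""Small shared helpers: deterministic rounding and RNG plumbing."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal, e.g. 88.85 -> 88.9.

    Python's built-in ``round`` is banker's rounding; percentages reported by
    the pipeline use the conventional half-up rule instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def make_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
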