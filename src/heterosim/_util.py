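"""Small shared helpers: printed-style rounding and seed plumbing."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching the printed-table style.

    Python's built-in ``round`` is banker's rounding; summary tables here
    follow the half-up convention (48.35 -> 48.4).
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def spawn_rng(seed: int | np.random.Generator | None, stream: int = 0) -> np.random.Generator:
    """Derive an independent Generator for one randomness stream.

    Every stochastic routine accepts a single integer seed; distinct
    ``stream`` offsets keep, e.g., count sampling and target-table sampling
    decoupled so adding one does not perturb the other.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    ss = np.random.SeedSequence(0 if seed is None else int(seed))
    children = ss.spawn(stream + 1)
    return np.random.default_rng(children[stream])
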