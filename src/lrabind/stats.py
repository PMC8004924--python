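"""Small statistical helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["mean_sd", "block_standard_error", "round_half_up"]


def mean_sd(values) -> tuple[float, float]:
    """Cross-run mean and sample standard deviation (n-1 denominator).

    A single value yields sd 0.0 (callers flag single-run aggregates
    explicitly rather than propagating NaN through report tables).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    mean = float(arr.mean())
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return mean, sd


def block_standard_error(series, n_blocks: int = 20) -> float:
    """Standard error of the mean of a correlated series by block averaging.

    The series is cut into ``n_blocks`` contiguous blocks; the spread of
    block means estimates the error of the overall mean while absorbing
    autocorrelation on scales shorter than a block.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 2 * n_blocks:
        n_blocks = max(2, arr.size // 2)
    usable = (arr.size // n_blocks) * n_blocks
    blocks = arr[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (away from zero on ties), for report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
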