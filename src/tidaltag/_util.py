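"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x) -> int | np.ndarray:
    """Round to nearest integer with ties going up (report-table convention).

    numpy's default rounds half to even, which is wrong for summary tables
    that were produced with conventional half-up rounding.
    """
    if np.isscalar(x):
        return int(math.floor(x + 0.5))
    x = np.asarray(x, dtype=float)
    return np.floor(x + 0.5).astype(int)


def child_seed(seed: int, *salt: int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
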