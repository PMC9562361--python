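"""Deterministic integer allocation of cells to proportions."""

from __future__ import annotations

import math

import numpy as np


def largest_remainder(n: int, proportions) -> np.ndarray:
    """Split ``n`` items into integer counts proportional to ``proportions``.

    Uses the largest-remainder (Hamilton) method: floor every quota, then
    hand the leftover units to the largest fractional parts.  Ties in the
    fractional part are broken by position, so the first-listed category
    wins — this makes the allocation fully deterministic.

    Parameters
    ----------
    n
        Total number of items (non-negative).
    proportions
        Non-negative weights summing to 1 (within 1e-9).

    Returns
    -------
    Integer counts, same length as ``proportions``, summing to ``n``.
    """
    p = np.asarray(proportions, dtype=float)
    if n < 0:
        raise ValueError("n must be non-negative")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum():.12g}")
    quota = n * p
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short:
        frac = quota - counts
        # stable sort descending on fractional part -> earlier index wins ties
        order = np.argsort(-frac, kind="stable")
        counts[order[:short]] += 1
    assert counts.sum() == n
    return counts


def is_exact(n: int, proportions) -> bool:
    """True when every quota ``n * p`` is an integer (no rounding needed)."""
    return all(
        math.isclose(n * p, round(n * p), abs_tol=1e-9) for p in proportions
    )
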