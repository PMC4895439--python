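"""Binary-segmentation change-point detection for piecewise-constant means.

Recursively splits a signal at the location that maximally reduces the
within-segment sum of squared deviations; a split is kept when the gain
exceeds a BIC-style penalty ``penalty * sigma**2 * log(n)``.  Written for
staircase-shaped AFM extension signals: O(n) per split via cumulative sums.
"""

from __future__ import annotations

import numpy as np

__all__ = ["binary_segmentation"]


def _best_split(csum: np.ndarray, csum2: np.ndarray, a: int, b: int, min_size: int):
    """Best interior split of [a, b); returns (gain, index) or (0, -1)."""
    n = b - a
    if n < 2 * min_size:
        return 0.0, -1
    total_sum = csum[b] - csum[a]
    total_cost = (csum2[b] - csum2[a]) - total_sum**2 / n
    # candidate boundaries a+min_size .. b-min_size
    idx = np.arange(a + min_size, b - min_size + 1)
    left_n = idx - a
    right_n = b - idx
    left_sum = csum[idx] - csum[a]
    right_sum = csum[b] - csum[idx]
    cost = (
        (csum2[idx] - csum2[a])
        - left_sum**2 / left_n
        + (csum2[b] - csum2[idx])
        - right_sum**2 / right_n
    )
    k = int(np.argmin(cost))
    gain = float(total_cost - cost[k])
    return gain, int(idx[k])


def binary_segmentation(
    y: np.ndarray,
    penalty: float,
    min_size: int = 2,
    max_changepoints: int | None = None,
) -> list[int]:
    """Return sorted interior change-point indices of ``y``.

    A boundary at index i means segments ``y[:i]`` and ``y[i:]``.  Splits are
    accepted greedily (largest gain first) while the gain exceeds ``penalty``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    csum = np.concatenate(([0.0], np.cumsum(y)))
    csum2 = np.concatenate(([0.0], np.cumsum(y * y)))

    # candidate heap as a dict segment -> (gain, split)
    segments = {(0, n): _best_split(csum, csum2, 0, n, min_size)}
    boundaries: list[int] = []
    while True:
        if max_changepoints is not None and len(boundaries) >= max_changepoints:
            break
        best_seg, (best_gain, best_idx) = max(
            segments.items(), key=lambda kv: kv[1][0]
        )
        if best_idx < 0 or best_gain <= penalty:
            break
        a, b = best_seg
        del segments[best_seg]
        boundaries.append(best_idx)
        segments[(a, best_idx)] = _best_split(csum, csum2, a, best_idx, min_size)
        segments[(best_idx, b)] = _best_split(csum, csum2, best_idx, b, min_size)
    return sorted(boundaries)
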