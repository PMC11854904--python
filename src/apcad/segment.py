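"""Changepoint detection: binary segmentation with a BIC-style penalty.

Operates on a (n, p) series of per-window statistics (delta_BAF, mean Log2R).
Piecewise-constant mean model; the noise scale is estimated robustly from
first differences so the penalty adapts to the actual window noise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["binary_segmentation"]


def _cumcost(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    c2 = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x * x, axis=0)])
    return c1, c2


def _sse(c1: np.ndarray, c2: np.ndarray, i: int, j: int) -> float:
    """Within-mean SSE of rows [i, j) summed over dimensions."""
    n = j - i
    if n <= 0:
        return 0.0
    s = c1[j] - c1[i]
    q = c2[j] - c2[i]
    return float(np.sum(q - s * s / n))


def binary_segmentation(
    series: np.ndarray,
    penalty: float = 12.0,
    min_size: int = 3,
) -> list[int]:
    """Return changepoint indices (exclusive right edges, excluding 0 and n).

    A split is accepted when the SSE reduction exceeds
    ``penalty * sigma2 * log(n)`` with sigma2 the robust per-dimension noise
    variance summed over dimensions (median absolute first difference).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if n < 2 * min_size:
        return []
    # robust noise scale per dimension from lag-1 differences
    d = np.diff(x, axis=0)
    mad = np.median(np.abs(d - np.median(d, axis=0)), axis=0)
    sigma = mad / 0.6745 / np.sqrt(2.0)
    sigma2 = float(np.sum(np.maximum(sigma, 1e-6) ** 2))
    pen = penalty * sigma2 * np.log(max(n, 2))

    c1, c2 = _cumcost(x)
    cps: list[int] = []

    def split(i: int, j: int) -> None:
        if j - i < 2 * min_size:
            return
        base = _sse(c1, c2, i, j)
        best_gain, best_k = 0.0, -1
        for k in range(i + min_size, j - min_size + 1):
            gain = base - _sse(c1, c2, i, k) - _sse(c1, c2, k, j)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k >= 0 and best_gain > pen:
            split(i, best_k)
            cps.append(best_k)
            split(best_k, j)

    split(0, n)
    return sorted(cps)
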