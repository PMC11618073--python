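"""Piecewise-constant segmentation by recursive binary splitting.

Shared change-point engine for photobleach detection and exchange-step
finding.  A segment is split at the point that maximally reduces the
residual sum of squares; the split is kept when the reduction exceeds a
BIC-style penalty expressed in units of the (robustly estimated) noise
variance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_noise_sd", "binary_segment", "segment_means"]


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise sd from the median absolute successive difference.

    For i.i.d. Gaussian noise, |x[i+1] - x[i]| has median 0.9539 sigma;
    level changes affect only a handful of differences and are ignored
    by the median.
    """
    d = np.abs(np.diff(np.asarray(x, dtype=float)))
    if len(d) == 0:
        return 0.0
    return float(np.median(d) / 0.9539)


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best interior split of one segment: (index, RSS reduction)."""
    n = len(x)
    if n < 2 * min_size:
        return -1, 0.0
    c = np.cumsum(x)
    total = c[-1]
    k = np.arange(min_size, n - min_size + 1)  # left part is x[:k]
    left_mean = c[k - 1] / k
    right_mean = (total - c[k - 1]) / (n - k)
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    j = int(np.argmax(gain))
    return int(k[j]), float(gain[j])


def binary_segment(
    x: np.ndarray,
    min_size: int = 3,
    penalty: float | None = None,
    noise_sd: float | None = None,
    max_splits: int | None = None,
) -> list[int]:
    """Interior breakpoints of a piecewise-constant mean model.

    ``penalty`` is the minimum RSS reduction, in units of noise
    variance, for a split to be kept (default ``3 ln n``).  Returns
    sorted breakpoint indices b such that segments are x[..:b], x[b:..].
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_size:
        return []
    if noise_sd is None:
        noise_sd = estimate_noise_sd(x)
    if noise_sd <= 0:
        noise_sd = 1e-12
    if penalty is None:
        penalty = 3.0 * np.log(n)
    threshold = penalty * noise_sd**2

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if max_splits is not None and len(breaks) >= max_splits:
            break
        k, gain = _best_split(x[a:b], min_size)
        if k < 0 or gain <= threshold:
            continue
        breaks.append(a + k)
        stack.append((a, a + k))
        stack.append((a + k, b))
    return sorted(breaks)


def segment_means(x: np.ndarray, breaks: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """(segment start indices, segment means) for given breakpoints."""
    x = np.asarray(x, dtype=float)
    edges = [0] + list(breaks) + [len(x)]
    starts = np.asarray(edges[:-1], dtype=int)
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return starts, means
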