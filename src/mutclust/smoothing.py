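"""Tukey-kernel smoothing of mutation positions along an element.

Each mutation contributes a compactly supported, symmetric biweight (Tukey)
kernel centered on its element position; the smoothing curve is the sum of
those contributions. Kernel mass falling outside the element is clipped —
never reflected or renormalized — so the observed curve and the simulated
null curves are distorted identically at the edges.
"""
from __future__ import annotations

import numpy as np


def tukey_kernel(w_smooth: int) -> np.ndarray:
    """Discrete Tukey biweight kernel of odd width ``w_smooth``, summing to 1.

    For offsets d in [-h, h] with h = (w_smooth - 1) / 2 the unnormalized
    weight is (1 - (d / (h + 1))^2)^2: symmetric, strictly decreasing away
    from the center, and strictly positive out to the window edge.
    """
    if w_smooth < 3 or w_smooth % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 3, got {w_smooth}")
    h = (w_smooth - 1) // 2
    d = np.arange(-h, h + 1, dtype=float)
    weights = (1.0 - (d / (h + 1)) ** 2) ** 2
    return weights / weights.sum()


def smooth(length: int, positions, w_smooth: int = 11, kernel: np.ndarray | None = None) -> np.ndarray:
    """Smoothing curve of ``positions`` (a multiset of element indices).

    The result has one value per element position; its sum equals the number
    of mutations minus whatever kernel mass is clipped at the edges.
    """
    if kernel is None:
        kernel = tukey_kernel(w_smooth)
    h = (len(kernel) - 1) // 2
    curve = np.zeros(length, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        return curve
    if positions.min() < 0 or positions.max() >= length:
        raise ValueError("mutation position outside element")
    unique, counts = np.unique(positions, return_counts=True)
    for pos, count in zip(unique, counts):
        lo = max(pos - h, 0)
        hi = min(pos + h + 1, length)
        curve[lo:hi] += count * kernel[lo - (pos - h) : hi - (pos - h)]
    return curve
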