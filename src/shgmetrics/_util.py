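"""Small shared helpers (background estimation, SEM)."""

from __future__ import annotations

import numpy as np


def background_stats(image: np.ndarray, frac: float = 0.1) -> tuple[float, float]:
    """Mean and SD of the darkest ``frac`` of pixels (default: darkest decile).

    Used as the default noise-background estimator when no explicit background
    region is supplied.
    """
    flat = np.sort(np.asarray(image, dtype=float).ravel())
    n = max(1, int(round(len(flat) * frac)))
    bg = flat[:n]
    return float(bg.mean()), float(bg.std())


def ksigma_threshold(image: np.ndarray, k: float = 3.0, frac: float = 0.1) -> float:
    """Background mean + k·SD threshold from the darkest-decile rule."""
    m, s = background_stats(image, frac)
    return m + k * s


def sem(values: np.ndarray) -> float:
    """Standard error of the mean; NaN for fewer than two values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))
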