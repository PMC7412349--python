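"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive nested loops so they stay independent
of the vectorized implementations they check.
"""

import math

import numpy as np
import pytest


def bilateral_oracle(img: np.ndarray, radius: int, sigma_spatial: float, sigma_range: float) -> np.ndarray:
    """Direct double-loop evaluation of the bilateral filter definition."""
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    padded = np.pad(a, radius, mode="edge")
    out = np.empty_like(a)
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    v = padded[i + di + radius, j + dj + radius]
                    wgt = math.exp(-(di * di + dj * dj) / (2 * sigma_spatial**2)) * math.exp(
                        -((v - a[i, j]) ** 2) / (2 * sigma_range**2)
                    )
                    num += wgt * v
                    den += wgt
            out[i, j] = num / den
    return out


def kirsch_oracle(img: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Nested-loop 3×3 correlation with replicate padding, max over masks."""
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    padded = np.pad(a, 1, mode="edge")
    out = np.full((h, w), -np.inf)
    for m in masks:
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for di in range(3):
                    for dj in range(3):
                        acc += m[di, dj] * padded[i + di, j + dj]
                out[i, j] = max(out[i, j], acc)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
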