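"""Candidate-image preparation: bilateral smoothing, orientation, crop, resize.

The capture contains the finger plus frame, shadow and background clutter; the
candidate image is the filtered, margin-cropped, down-scaled version on which
boundary detection runs. The crop keeps one boundary pixel (retained extent =
original − margins + 1) and the resize rounds output dimensions up; these two
conventions jointly reproduce the published candidate sizes of all four
dataset presets exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config_io import DatasetPreset

__all__ = [
    "BilateralParams",
    "bilateral_filter",
    "inclusive_crop",
    "resize_bicubic",
    "candidate_shape",
    "prepare_candidate",
]


@dataclass(frozen=True)
class BilateralParams:
    """Edge-preserving Gaussian bilateral filter parameters.

    ``radius`` is the window half-width in pixels (window is (2r+1)²);
    ``sigma_spatial`` the spatial Gaussian scale in pixels; ``sigma_range``
    the intensity Gaussian scale in 8-bit gray levels. Defaults are
    conventional edge-preserving settings for 8-bit NIR captures.
    """

    radius: int = 4
    sigma_spatial: float = 3.0
    sigma_range: float = 30.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.sigma_spatial <= 0 or self.sigma_range <= 0:
            raise ValueError("sigmas must be positive")


def bilateral_filter(img: np.ndarray, params: BilateralParams | None = None) -> np.ndarray:
    """Smooth while preserving edges.

    Each output pixel is the Gaussian spatial × Gaussian range weighted mean
    of its (2r+1)² replicate-padded neighborhood. Returns float64 of the same
    shape; the output range never exceeds the input range (convex weights).
    """
    if params is None:
        params = BilateralParams()
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a nonempty 2-D image")
    r = params.radius
    padded = np.pad(a, r, mode="edge")
    h, w = a.shape
    num = np.zeros_like(a)
    den = np.zeros_like(a)
    inv2ss = 1.0 / (2.0 * params.sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * params.sigma_range**2)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            wgt = math.exp(-(dy * dy + dx * dx) * inv2ss) * np.exp(
                -((shifted - a) ** 2) * inv2sr
            )
            num += wgt * shifted
            den += wgt
    return num / den


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel (a = −0.5), the standard bicubic weight."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    m2 = (t > 1) & (t < 2)
    out[m2] = a * (t[m2] ** 3 - 5 * t[m2] ** 2 + 8 * t[m2] - 4)
    return out


def _resize_axis0(a: np.ndarray, out_len: int) -> np.ndarray:
    """Bicubic resample along axis 0 with replicate edge handling."""
    in_len = a.shape[0]
    if out_len == in_len:
        return a.astype(float)
    scale = in_len / out_len
    # pixel-center alignment: output center i maps to input coordinate x
    x = (np.arange(out_len) + 0.5) * scale - 0.5
    base = np.floor(x).astype(int)
    frac = x - base
    out = np.zeros((out_len,) + a.shape[1:])
    norm = np.zeros(out_len)
    for k in range(-1, 3):
        idx = np.clip(base + k, 0, in_len - 1)
        w = _keys_kernel(frac - k)
        out += w[:, None] * a[idx]
        norm += w
    return out / norm[:, None]


def resize_bicubic(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resize a 2-D image to (rows, cols) by separable Keys bicubic interpolation."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image")
    rows, cols = out_shape
    if rows < 1 or cols < 1:
        raise ValueError("output shape must be positive")
    a = _resize_axis0(a, rows)
    a = _resize_axis0(a.T, cols).T
    return a


def inclusive_crop(img: np.ndarray, top: int, bottom: int, left: int, right: int) -> np.ndarray:
    """Remove border margins, keeping one pixel of the far boundary.

    Retained rows = n_rows − top − bottom + 1 (when both margins are hit;
    zero margins degrade gracefully to no crop on that side).
    """
    n_rows, n_cols = img.shape
    r1 = min(n_rows - bottom + 1, n_rows)
    c1 = min(n_cols - right + 1, n_cols)
    out = img[top:r1, left:c1]
    if out.shape[0] < 3 or out.shape[1] < 3:
        raise ValueError(
            f"margins ({top},{bottom},{left},{right}) leave a degenerate "
            f"{out.shape} image from {img.shape}"
        )
    return out


def candidate_shape(input_shape: tuple[int, int], preset: DatasetPreset) -> tuple[int, int]:
    """Predict the candidate-image shape for an input of the given shape.

    Pure shape arithmetic (rotation, inclusive crop, ceil-rounded scale);
    independent of pixel content.
    """
    rows, cols = input_shape
    if preset.rotate_quarter_turns_ccw % 2 == 1:
        rows, cols = cols, rows
    rows = min(rows - preset.margin_bottom + 1, rows) - preset.margin_top
    cols = min(cols - preset.margin_right + 1, cols) - preset.margin_left
    return (math.ceil(rows * preset.scale), math.ceil(cols * preset.scale))


def prepare_candidate(
    img: np.ndarray,
    preset: DatasetPreset,
    bilateral: BilateralParams | None = None,
) -> np.ndarray:
    """Produce the candidate image: rotate → bilateral filter → crop → resize.

    Rotation first so the margins are expressed in viewing orientation
    (finger horizontal, tip to the right); filtering precedes the crop so the
    filter sees full context at the crop boundary.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image")
    if preset.rotate_quarter_turns_ccw:
        a = np.rot90(a, k=preset.rotate_quarter_turns_ccw)
    a = bilateral_filter(a, bilateral)
    a = inclusive_crop(a, preset.margin_top, preset.margin_bottom, preset.margin_left, preset.margin_right)
    out_shape = (math.ceil(a.shape[0] * preset.scale), math.ceil(a.shape[1] * preset.scale))
    return resize_bicubic(a, out_shape)
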