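"""Image I/O and dataset-specific preprocessing presets.

Finger-vein images are 8-bit single-channel captures (BMP or PNG). Each public
dataset needs its own margin crop and down-scale before boundary detection, so
those numbers live here as named presets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from fractions import Fraction

import imageio.v3 as iio
import numpy as np

__all__ = [
    "DatasetPreset",
    "dataset_preset",
    "PRESET_NAMES",
    "read_gray_image",
    "write_gray_image",
]

# ITU-R BT.601 luminance weights, used when an RGB capture sneaks in.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DatasetPreset:
    """Per-dataset candidate-region recipe.

    Margins are pixels removed from each border of the (possibly rotated)
    capture; ``scale`` is the subsequent bicubic down-scale factor.
    ``expected_candidate_shape`` is the published (rows, cols) of the candidate
    image for the dataset's native capture size, kept for sanity checks.
    """

    name: str
    rotate_quarter_turns_ccw: int
    margin_top: int
    margin_bottom: int
    margin_left: int
    margin_right: int
    scale: Fraction
    expected_candidate_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.rotate_quarter_turns_ccw not in (0, 1):
            raise ValueError("rotate_quarter_turns_ccw must be 0 or 1")
        for m in (self.margin_top, self.margin_bottom, self.margin_left, self.margin_right):
            if m < 0:
                raise ValueError("margins must be non-negative")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must lie in (0, 1]")


_PRESETS = {
    "HKPU": DatasetPreset("HKPU", 0, 30, 10, 30, 50, Fraction(1, 2), (109, 217)),
    "MMCBNU_6000": DatasetPreset("MMCBNU_6000", 0, 5, 5, 5, 5, Fraction(1, 4), (118, 158)),
    "FV-USM": DatasetPreset("FV-USM", 1, 150, 150, 5, 70, Fraction(1, 2), (171, 203)),
    "ZSC-FV": DatasetPreset("ZSC-FV", 0, 20, 20, 20, 20, Fraction(1, 2), (173, 237)),
}

PRESET_NAMES = tuple(_PRESETS)


def dataset_preset(name: str) -> DatasetPreset:
    """Return the preprocessing preset for one of the known datasets.

    Raises ``KeyError`` listing the valid names for anything unknown.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset preset {name!r}; valid names: {', '.join(_PRESETS)}"
        ) from None


def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as a 2-D uint8 array.

    RGB(A) inputs are collapsed to BT.601 luminance; an alpha channel is
    dropped. Raises ``OSError`` if the file is missing or cannot be decoded.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = np.rint(arr[:, :, :3].astype(float) @ _LUMA)
    elif arr.ndim != 2:
        raise OSError(f"cannot read image {path!r}: unsupported dimensionality {arr.ndim}")
    return np.clip(arr, 0, 255).astype(np.uint8)


def write_gray_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a 2-D image as 8-bit grayscale.

    Real-valued inputs are rounded and clamped to [0, 255]; write-then-read is
    the identity for any 8-bit image. Raises ``OSError`` on unwritable paths.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    data = np.clip(np.rint(img.astype(float)), 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, data)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise OSError(f"cannot write image {path!r}: {exc}") from exc
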