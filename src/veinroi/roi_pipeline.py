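"""End-to-end ROI localization: gradient → quadrant thresholds → boundaries → ROI.

The region of interest is the band strictly between the recovered upper and
lower finger boundaries. The per-image quality label records the deepest
threshold level any quadrant required and is aggregated over batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import (
    QUADRANTS,
    BoundaryDetectionError,
    assemble_boundary,
    classify_quality,
    detect_quadrant_edge,
    split_quadrants,
)
from .kirsch import HORIZONTAL_MASKS, kirsch_response
from .preprocess import resize_bicubic
from .threshold import THRESHOLD_SCHEDULE

__all__ = [
    "PipelineConfig",
    "ROIResult",
    "QualityStats",
    "locate_roi",
    "roi_mask",
    "normalize_roi",
    "batch_quality_stats",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the localization pipeline.

    ``l_fraction`` scales the minimum component span L = round(f × quadrant
    width); the sensible range is [1/3, 1/2] of the part width, default the
    stricter 1/2. ``normalized_shape`` is the output ROI size used for
    matching; ``rectangle_mode`` replaces the per-column band by the maximal
    inscribed rectangle for matchers that need straight edges.
    """

    mask_indices: tuple[int, ...] = HORIZONTAL_MASKS
    l_fraction: float = 0.5
    schedule: tuple[float, ...] = THRESHOLD_SCHEDULE
    normalized_shape: tuple[int, int] = (96, 192)
    rectangle_mode: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.l_fraction <= 1:
            raise ValueError("l_fraction must lie in (0, 1]")
        if list(self.schedule) != sorted(self.schedule, reverse=True):
            raise ValueError("schedule must be strictly decreasing")


@dataclass(frozen=True)
class ROIResult:
    """Everything the pipeline knows about one image."""

    mask: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    roi_image: np.ndarray
    quality: str
    levels: dict[str, float | None]
    spans: dict[str, int] = field(default_factory=dict)
    source_shape: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class QualityStats:
    """Good/medium/poor counts over a processed batch."""

    n_good: int
    n_medium: int
    n_poor: int

    @property
    def total(self) -> int:
        return self.n_good + self.n_medium + self.n_poor

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        return (self.n_good / t, self.n_medium / t, self.n_poor / t)

    def format_table(self) -> str:
        rows = ["Quality   Count  Percent"]
        for name, n, f in zip(("good", "medium", "poor"), (self.n_good, self.n_medium, self.n_poor), self.fractions):
            rows.append(f"{name:<9}{n:>6}  {n} ({f * 100:.2f}%)")
        return "\n".join(rows)


def roi_mask(upper: np.ndarray, lower: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean band strictly between the two boundary traces (rows excluded)."""
    upper = np.asarray(upper)
    lower = np.asarray(lower)
    rows, cols = shape
    if upper.shape != (cols,) or lower.shape != (cols,):
        raise ValueError("traces must have one entry per image column")
    bad = np.nonzero(upper >= lower)[0]
    if bad.size:
        raise ValueError(
            f"upper boundary not above lower boundary at column {bad[0]} "
            f"(upper={upper[bad[0]]}, lower={lower[bad[0]]})"
        )
    r = np.arange(rows)[:, None]
    return (r > upper[None, :]) & (r < lower[None, :])


def normalize_roi(
    candidate: np.ndarray, mask: np.ndarray, target: tuple[int, int]
) -> np.ndarray:
    """Crop the tight bounding box of the ROI band and resize to ``target``.

    Pixels inside the box but outside the per-column band are zeroed before
    the bicubic resize.
    """
    candidate = np.asarray(candidate, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    banded = np.where(mask, candidate, 0.0)
    crop = banded[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return resize_bicubic(crop, target)


def locate_roi(candidate: np.ndarray, config: PipelineConfig | None = None) -> ROIResult:
    """Run the full localization pipeline on a candidate image.

    Computes the horizontal Kirsch gradient, runs the escalating μ+kσ search
    independently in each quadrant, assembles the upper boundary from UL+UR
    and the lower from LL+LR, classifies image quality from the four levels,
    and extracts the normalized ROI.
    """
    if config is None:
        config = PipelineConfig()
    candidate = np.asarray(candidate, dtype=float)
    if candidate.ndim != 2 or min(candidate.shape) < 8:
        raise ValueError("candidate image must be 2-D and at least 8x8")
    G = kirsch_response(candidate, config.mask_indices)
    views = split_quadrants(*G.shape)
    edges = {
        which: detect_quadrant_edge(
            G[view.rows, view.cols], which, config.l_fraction, config.schedule
        )
        for which, view in views.items()
    }
    n_cols = G.shape[1]
    upper = assemble_boundary(
        edges["UL"], edges["UR"], n_cols,
        (views["UL"].row_offset, views["UL"].col_offset),
        (views["UR"].row_offset, views["UR"].col_offset),
        side="upper",
    )
    lower = assemble_boundary(
        edges["LL"], edges["LR"], n_cols,
        (views["LL"].row_offset, views["LL"].col_offset),
        (views["LR"].row_offset, views["LR"].col_offset),
        side="lower",
    )
    levels = {which: edges[which].level_used for which in QUADRANTS}
    quality = classify_quality([levels[q] for q in QUADRANTS])
    mask = roi_mask(upper, lower, candidate.shape)
    if config.rectangle_mode:
        top, bottom = int(upper.max()) + 1, int(lower.min()) - 1
        rect = np.zeros_like(mask)
        if top <= bottom:
            rect[top : bottom + 1, :] = True
        mask = rect
    roi_image = normalize_roi(candidate, mask, config.normalized_shape)
    return ROIResult(
        mask=mask,
        upper=upper,
        lower=lower,
        roi_image=roi_image,
        quality=quality,
        levels=levels,
        spans={which: edges[which].span_cols for which in QUADRANTS},
        source_shape=candidate.shape,
    )


def batch_quality_stats(results) -> QualityStats:
    """Count good/medium/poor over a batch of results (or bare labels)."""
    labels = [r.quality if isinstance(r, ROIResult) else r for r in results]
    if not labels:
        raise ValueError("empty result sequence")
    unknown = set(labels) - {"good", "medium", "poor"}
    if unknown:
        raise ValueError(f"unknown quality labels: {sorted(unknown)}")
    return QualityStats(
        n_good=labels.count("good"),
        n_medium=labels.count("medium"),
        n_poor=labels.count("poor"),
    )
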