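"""Quadrant-wise dynamic thresholding and boundary-trace assembly.

The gradient image is split into four parts (upper-left, upper-right,
lower-left, lower-right). Each part is binarized at μ+2σ of its own gradient
statistics; if the longest 8-connected component does not span at least L
columns the threshold escalates to μ+σ and then μ+0.5σ. The winning
component becomes a per-column trace, and the two same-side traces are joined
by linear interpolation into a full-width boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .threshold import THRESHOLD_SCHEDULE, GradientStats, binarize_at_sigma, gradient_stats

__all__ = [
    "QUADRANTS",
    "QuadrantView",
    "ComponentInfo",
    "QuadrantEdge",
    "BoundaryDetectionError",
    "split_quadrants",
    "longest_horizontal_component",
    "detect_quadrant_edge",
    "assemble_boundary",
    "classify_quality",
]

#: quadrant identifiers: upper/lower × left/right
QUADRANTS = ("UL", "UR", "LL", "LR")


class BoundaryDetectionError(RuntimeError):
    """No usable boundary component on one side of the image."""

    def __init__(self, side: str, diagnostics: dict | None = None):
        self.side = side
        self.diagnostics = diagnostics or {}
        super().__init__(f"boundary detection failed on the {side} side")


@dataclass(frozen=True)
class QuadrantView:
    """One of the four image parts, located by its offset within the image."""

    which: str
    row_offset: int
    col_offset: int
    n_rows: int
    n_cols: int

    @property
    def rows(self) -> slice:
        return slice(self.row_offset, self.row_offset + self.n_rows)

    @property
    def cols(self) -> slice:
        return slice(self.col_offset, self.col_offset + self.n_cols)


@dataclass(frozen=True)
class ComponentInfo:
    """An 8-connected component of edge pixels within one quadrant."""

    rows: np.ndarray  # pixel rows, quadrant-local
    cols: np.ndarray  # pixel cols, quadrant-local
    span_cols: int
    n_pixels: int


@dataclass(frozen=True)
class QuadrantEdge:
    """Outcome of the escalating threshold search in one quadrant.

    ``level_used`` is the schedule multiplier that produced a long-enough
    component, or ``None`` when the whole schedule failed. ``trace`` maps
    quadrant-local column → row for the winning (or best failing) component.
    """

    which: str
    level_used: float | None
    satisfied: bool
    trace_cols: np.ndarray
    trace_rows: np.ndarray
    span_cols: int
    length_threshold: int
    stats: GradientStats = field(repr=False, default=None)


def split_quadrants(n_rows: int, n_cols: int) -> dict[str, QuadrantView]:
    """Tile an image into UL/UR/LL/LR parts (floor split, remainder right/bottom)."""
    if n_rows < 2 or n_cols < 2:
        raise ValueError("image must be at least 2x2 to split into quadrants")
    rh, ch = n_rows // 2, n_cols // 2
    return {
        "UL": QuadrantView("UL", 0, 0, rh, ch),
        "UR": QuadrantView("UR", 0, ch, rh, n_cols - ch),
        "LL": QuadrantView("LL", rh, 0, n_rows - rh, ch),
        "LR": QuadrantView("LR", rh, ch, n_rows - rh, n_cols - ch),
    }


def longest_horizontal_component(B: np.ndarray) -> ComponentInfo | None:
    """Widest 8-connected component of a binary edge image.

    "Longest" means column span (count of distinct columns covered), the
    horizontal extent of a boundary line; ties prefer more pixels, then the
    component whose topmost pixel is higher. Returns ``None`` for an empty
    mask.
    """
    B = np.asarray(B, dtype=bool)
    if not B.any():
        return None
    labels, n = measure.label(B, connectivity=2, return_num=True)
    rr, cc = np.nonzero(labels)
    ids = labels[rr, cc]
    index = np.arange(1, n + 1)
    # any 8-connected path moves at most one column per step, so the columns a
    # component covers form a contiguous interval: span = max − min + 1
    min_col = ndimage.minimum(cc, ids, index)
    max_col = ndimage.maximum(cc, ids, index)
    span = (max_col - min_col + 1).astype(int)
    counts = np.bincount(ids, minlength=n + 1)[1:]
    top_row = ndimage.minimum(rr, ids, index)
    order = np.lexsort((top_row, -counts, -span))
    lab = index[order[0]]
    sel = ids == lab
    return ComponentInfo(
        rows=rr[sel], cols=cc[sel], span_cols=int(span[order[0]]), n_pixels=int(counts[order[0]])
    )


def _component_trace(comp: ComponentInfo, which: str) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a 2-D component to one row per column: the rounded mean row.

    Exact .5 means round toward the quadrant's outer border (up for the
    upper quadrants, down for the lower ones), i.e. toward the background.
    """
    order = np.argsort(comp.cols, kind="stable")
    cols = comp.cols[order]
    rows = comp.rows[order]
    uniq, start = np.unique(cols, return_index=True)
    sums = np.add.reduceat(rows.astype(float), start)
    counts = np.diff(np.append(start, len(rows)))
    mean = sums / counts
    if which in ("UL", "UR"):
        traced = np.ceil(mean - 0.5)  # half rounds toward row 0
    else:
        traced = np.floor(mean + 0.5)  # half rounds toward the bottom
    return uniq, traced.astype(int)


def detect_quadrant_edge(
    G_quad: np.ndarray,
    which: str,
    l_fraction: float = 0.5,
    schedule: tuple[float, ...] = THRESHOLD_SCHEDULE,
    stats: GradientStats | None = None,
) -> QuadrantEdge:
    """Find the boundary component in one quadrant with the escalating schedule.

    Statistics are computed on the quadrant's own gradient values by default
    (each part adopts its own threshold); pass ``stats`` to impose global
    statistics instead. The search stops at the first level whose longest
    component spans at least L = round(l_fraction × quadrant width) columns;
    if the whole schedule fails, the widest component seen is returned with
    ``satisfied=False`` (failure is a result, not an exception).
    """
    G_quad = np.asarray(G_quad, dtype=float)
    if which not in QUADRANTS:
        raise ValueError(f"unknown quadrant {which!r}")
    if not 0 < l_fraction <= 1:
        raise ValueError("l_fraction must lie in (0, 1]")
    n_cols = G_quad.shape[1]
    L = max(1, round(l_fraction * n_cols))
    st = stats if stats is not None else gradient_stats(G_quad)
    best: ComponentInfo | None = None
    for k in schedule:
        comp = longest_horizontal_component(binarize_at_sigma(G_quad, st, k))
        if comp is not None and (best is None or comp.span_cols > best.span_cols):
            best = comp
        if comp is not None and comp.span_cols >= L:
            cols, rows = _component_trace(comp, which)
            return QuadrantEdge(which, k, True, cols, rows, comp.span_cols, L, st)
    if best is not None:
        cols, rows = _component_trace(best, which)
        return QuadrantEdge(which, None, False, cols, rows, best.span_cols, L, st)
    return QuadrantEdge(
        which, None, False, np.empty(0, int), np.empty(0, int), 0, L, st
    )


def assemble_boundary(
    left: QuadrantEdge,
    right: QuadrantEdge,
    n_cols: int,
    left_offset: tuple[int, int],
    right_offset: tuple[int, int],
    side: str = "upper",
) -> np.ndarray:
    """Join two same-side quadrant edges into a full-width boundary trace.

    Only satisfied quadrants contribute (a failed quadrant is covered by the
    other's trace). Interior gaps are filled by linear interpolation between
    the nearest traced columns; the ends extend by constant continuation.
    Raises :class:`BoundaryDetectionError` when both quadrants failed.
    """
    xs, ys = [], []
    for edge, (r0, c0) in ((left, left_offset), (right, right_offset)):
        if edge.satisfied and edge.trace_cols.size:
            xs.append(edge.trace_cols + c0)
            ys.append(edge.trace_rows + r0)
    if not xs:
        raise BoundaryDetectionError(
            side,
            {
                e.which: {"level_used": e.level_used, "span_cols": e.span_cols, "L": e.length_threshold}
                for e in (left, right)
            },
        )
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = np.argsort(x, kind="stable")
    # np.interp fills interior gaps linearly and extends ends by the endpoints
    return np.rint(np.interp(np.arange(n_cols), x[order], y[order].astype(float))).astype(int)


def classify_quality(levels) -> str:
    """Per-image quality from the four quadrant threshold levels.

    good: every quadrant resolved at 2σ; poor: any quadrant needed 0.5σ (or
    failed outright); medium: otherwise (some quadrant needed σ).
    """
    levels = list(levels)
    if len(levels) != 4:
        raise ValueError("expected exactly four quadrant levels")
    if any(lv is None or lv == 0.5 for lv in levels):
        return "poor"
    if all(lv == 2.0 for lv in levels):
        return "good"
    return "medium"
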