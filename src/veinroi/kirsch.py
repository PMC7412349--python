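"""Kirsch compass edge operator.

Eight 3×3 templates, one per compass direction, each with three coefficients
of 5 facing the direction and five of −3 elsewhere (center 0). The edge
response is the pointwise maximum of the selected template correlations. For
a horizontally placed finger only the two horizontal templates (M1, top row
of 5s; M5, bottom row of 5s) are needed: they respond strongly to horizontal
intensity steps and suppress vertical ones.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["kirsch_masks", "kirsch_response", "HORIZONTAL_MASKS"]

# ring of outer positions, clockwise from the top-left corner
_RING = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]

#: mask indices realizing the horizontal-edge gradient (M1 and M5)
HORIZONTAL_MASKS = (1, 5)


def kirsch_masks() -> np.ndarray:
    """Return the eight Kirsch templates as an (8, 3, 3) int array.

    Mask k (1-based) places its 5s at ring positions {k−1, k, k+1} mod 8 of
    the clockwise outer ring, so M1 has top row (5,5,5) and M5 bottom row
    (5,5,5); each mask is a one-step ring rotation of the previous one and
    all coefficients sum to zero.
    """
    masks = np.full((8, 3, 3), -3, dtype=int)
    masks[:, 1, 1] = 0
    for k in range(8):
        for j in (k, k + 1, k + 2):
            r, c = _RING[j % 8]
            masks[k, r, c] = 5
    return masks


def kirsch_response(img: np.ndarray, mask_indices=HORIZONTAL_MASKS) -> np.ndarray:
    """Signed Kirsch edge gradient: max of the selected template correlations.

    Parameters
    ----------
    img : 2-D array, at least 3×3.
    mask_indices : nonempty subset of {1..8}, 1-based template indices.
        The default (1, 5) is the horizontal-edge case; all eight give the
        full compass operator.

    Correlation (no kernel flip) over a replicate-padded neighborhood, so the
    response has full image shape. Responses stay signed — no clamping or
    absolute value — so the gradient population keeps its normal-like shape
    for the downstream μ+kσ thresholds.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    indices = tuple(mask_indices)
    if not indices:
        raise ValueError("mask_indices must be nonempty")
    if any(not 1 <= k <= 8 for k in indices):
        raise ValueError("mask indices must lie in 1..8")
    masks = kirsch_masks()
    responses = [
        ndimage.correlate(a, masks[k - 1].astype(float), mode="nearest")
        for k in indices
    ]
    return np.maximum.reduce(responses)
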