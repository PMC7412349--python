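"""Finger-vein phantom generator with known ground-truth boundaries.

A phantom is a bright horizontal finger band on a darker background — the NIR
transillumination geometry — with soft boundary transitions, optional slant
(the finger may rotate up to 30°), darker vein-like strokes inside the band,
a smooth multiplicative illumination field, additive Gaussian pixel noise and
optional high-edge-density background clutter. Ground-truth boundary rows are
known per column, so every pipeline stage is testable without real captures.

Quality degradation is modelled by dimming the structural band-background
contrast inside chosen quadrants while the noise floor stays fixed, which is
what uneven illumination does to a capture: the local edge sinks toward the
gradient population and the μ+2σ cut stops seeing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .boundary import QUADRANTS, split_quadrants
from .preprocess import resize_bicubic

__all__ = [
    "PhantomSpec",
    "SyntheticSample",
    "synth_finger",
    "degrade_quadrant",
    "synth_batch",
    "MEDIUM_DIM",
    "POOR_DIM",
]

_MAX_SLOPE = math.tan(math.radians(30.0))

# Geometry of the dimmed region inside a degraded quadrant. The dim reaches
# full strength over the outer DIM_COL_PLATEAU fraction of the part's columns
# and feathers to nothing by DIM_COL_FEATHER toward the center seam; in the
# row direction it is full within DIM_ROW_CORE rows of the boundary line and
# feathers out by DIM_ROW_REACH rows, well before the quadrant seam. The
# feathering keeps the degradation free of gradients of its own: only the
# boundary edge weakens.
DIM_COL_PLATEAU = 0.6
DIM_COL_FEATHER = 0.8
DIM_ROW_CORE = 6.0
DIM_ROW_REACH = 34.0

# Batch dim factors, calibrated once against the default contrast (130 gray
# levels) and noise floor (sigma 3): a medium quadrant's weakened edge
# segment falls below the part's mu+2*sigma cut but stays above mu+sigma, so
# the 2-sigma component is too short and the sigma level recovers the full
# span; a poor quadrant's segment falls below mu+sigma as well and only
# mu+0.5*sigma (or nothing) recovers it.
MEDIUM_DIM = 0.21
POOR_DIM = 0.12


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom.

    ``upper_row``/``lower_row`` are the boundary-line row intercepts at
    column 0; ``slope`` is rows per column (|slope| ≤ tan 30°). The intensity
    ramps from ``background_level`` to ``finger_level`` over a skirt of width
    2×``edge_softness`` outside each boundary, saturating half a pixel inside
    it, so pixels strictly inside the band equal ``finger_level`` exactly in
    the noise-free case. ``illumination`` is ``None`` or (amplitude, scale_px)
    of a smooth multiplicative field; ``quadrant_dims`` maps quadrant ids to
    boundary-contrast factors in (0, 1] applied over the quadrant's outer
    columns (see :func:`degrade_quadrant`).
    """

    shape: tuple[int, int] = (160, 220)
    background_level: int = 40
    finger_level: int = 170
    upper_row: float = 32.0
    lower_row: float = 128.0
    slope: float = 0.0
    edge_softness: float = 0.75
    noise_sigma: float = 3.0
    vein_count: int = 4
    illumination: tuple[float, float] | None = None
    clutter_patches: int = 0
    quadrant_dims: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise ValueError("phantom must be at least 8x8")
        if self.finger_level - self.background_level < 20:
            raise ValueError("band contrast must be at least 20 gray levels")
        if abs(self.slope) > _MAX_SLOPE:
            raise ValueError("slope exceeds the 30-degree rotation assumption")
        for c in (0, cols - 1):
            u = self.upper_row + c * self.slope
            low = self.lower_row + c * self.slope
            if not 0 < u < low < rows - 1:
                raise ValueError(
                    f"boundary lines leave the image at column {c} (upper={u}, lower={low})"
                )
        if self.edge_softness < 0 or self.noise_sigma < 0:
            raise ValueError("edge_softness and noise_sigma must be non-negative")
        if self.illumination is not None:
            amp, scale = self.illumination
            if not 0 <= amp < 1 or scale <= 0:
                raise ValueError("illumination amplitude must be in [0,1), scale positive")
        for which, f in self.quadrant_dims:
            if which not in QUADRANTS or not 0 < f <= 1:
                raise ValueError(f"bad quadrant dim ({which!r}, {f})")


@dataclass(frozen=True)
class SyntheticSample:
    """A rendered phantom with its ground truth."""

    image: np.ndarray
    truth_upper: np.ndarray
    truth_lower: np.ndarray
    spec: PhantomSpec
    seed: int
    label: str = "good"
    dimmed: tuple[str, ...] = ()


def _ramp(d: np.ndarray, softness: float) -> np.ndarray:
    """0 at d ≤ −2·softness, 1 at d ≥ 0.5, linear between (d measured into the band)."""
    return np.clip((d + 2.0 * softness) / (2.0 * softness + 0.5), 0.0, 1.0)


def _cos_window(x: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """1 for x ≤ inner, 0 for x ≥ outer, raised-cosine in between."""
    with np.errstate(invalid="ignore"):
        ramp = 0.5 * (1.0 + np.cos(np.pi * (x - inner) / (outer - inner)))
    return np.where(x <= inner, 1.0, np.where(x >= outer, 0.0, ramp))


def _dim_window(n_rows: int, view, which: str, line: np.ndarray) -> np.ndarray:
    """Smooth weight field in [0,1] marking where a quadrant's dim applies.

    Full weight around the quadrant's own boundary line over the outer
    portion of the part's columns, raised-cosine feathered to zero toward
    the center seam (columns) and away from the line (rows). The row feather
    is slow enough that the rejoin to full contrast adds no detectable
    gradient of its own — it may reach past the quadrant seam, which is
    harmless because the neighboring part's boundary lies far away. Returned
    field covers all image rows × the quadrant's columns.
    """
    n = max(view.n_cols - 1, 1)
    local_c = np.arange(view.n_cols)
    t = local_c / n if which in ("UL", "LL") else (n - local_c) / n
    wc = _cos_window(t, DIM_COL_PLATEAU, DIM_COL_FEATHER)
    rr = np.arange(n_rows)[:, None]
    dist = np.abs(rr - line[None, view.cols])
    wr = _cos_window(dist, DIM_ROW_CORE, DIM_ROW_REACH)
    return wr * wc[None, :]


def _illumination_field(rng: np.random.Generator, shape, amplitude, scale):
    rows, cols = shape
    gr = max(2, math.ceil(rows / scale) + 1)
    gc = max(2, math.ceil(cols / scale) + 1)
    coarse = rng.uniform(-1.0, 1.0, size=(gr, gc))
    fld = np.clip(resize_bicubic(coarse, (rows, cols)), -1.0, 1.0)
    return 1.0 + amplitude * fld


def synth_finger(spec: PhantomSpec, seed: int) -> SyntheticSample:
    """Render one phantom; bit-identical for identical spec and seed."""
    rng = np.random.default_rng(seed)
    rows, cols = spec.shape
    c = np.arange(cols)
    r = np.arange(rows)[:, None]
    u_line = spec.upper_row + c * spec.slope
    l_line = spec.lower_row + c * spec.slope
    contrast = float(spec.finger_level - spec.background_level)
    band = _ramp(r - u_line[None, :], spec.edge_softness) * _ramp(
        l_line[None, :] - r, spec.edge_softness
    )
    structure = spec.background_level + contrast * band

    # vein-like darker strokes, kept away from the boundaries so they only
    # exercise false-edge robustness, never replace the band edges
    interior = band >= 1.0
    for _ in range(spec.vein_count):
        margin = 8.0
        center = rng.uniform(spec.upper_row + margin, spec.lower_row - margin)
        amp = rng.uniform(2.0, 6.0)
        wavelength = rng.uniform(60.0, 150.0)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        # veins are subtle in NIR: a shallow, wide dip, far weaker than the
        # finger silhouette so they never rival a (weakened) boundary edge
        width = rng.uniform(2.0, 3.0)
        depth = contrast * rng.uniform(0.05, 0.10)
        y = center + spec.slope * c + amp * np.sin(2.0 * math.pi * c / wavelength + phase)
        stroke = depth * np.exp(-((r - y[None, :]) ** 2) / (2.0 * width**2))
        structure = structure - stroke * interior

    # per-quadrant boundary-contrast dimming (uneven illumination proxy)
    dims = dict(spec.quadrant_dims)
    if dims:
        views = split_quadrants(rows, cols)
        for which, f in dims.items():
            v = views[which]
            line = u_line if which in ("UL", "UR") else l_line
            w = _dim_window(rows, v, which, line)
            block = structure[:, v.cols]
            structure[:, v.cols] = spec.background_level + (
                1.0 + (f - 1.0) * w
            ) * (block - spec.background_level)

    img = structure
    if spec.illumination is not None:
        img = img * _illumination_field(rng, spec.shape, *spec.illumination)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    else:
        rng.normal(0.0, 1.0, size=spec.shape)  # keep the draw order stable

    # background clutter patches with high edge density (complicated-background
    # sensors); stamped fully outside the band skirt
    skirt = math.ceil(2.0 * spec.edge_softness) + 2
    top_limit = int(np.floor(u_line.min())) - skirt
    bottom_start = int(np.ceil(l_line.max())) + skirt
    for _ in range(spec.clutter_patches):
        ph, pw = int(rng.integers(8, 14)), int(rng.integers(10, 18))
        regions = []
        if top_limit - ph > 0:
            regions.append(("top", top_limit - ph))
        if bottom_start + ph < rows:
            regions.append(("bottom", rows - ph - bottom_start))
        if not regions:
            break
        region, extent = regions[int(rng.integers(len(regions)))]
        r0 = int(rng.integers(0, extent))
        if region == "bottom":
            r0 += bottom_start
        c0 = int(rng.integers(0, cols - pw))
        texture = rng.integers(0, 2, size=(ph, pw)) * rng.uniform(40.0, 80.0)
        img[r0 : r0 + ph, c0 : c0 + pw] = spec.background_level + texture

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSample(
        image=image,
        truth_upper=np.rint(u_line).astype(int),
        truth_lower=np.rint(l_line).astype(int),
        spec=spec,
        seed=int(seed),
    )


def degrade_quadrant(sample: SyntheticSample, which: str, dim_factor: float) -> SyntheticSample:
    """Dim the boundary contrast inside one quadrant.

    The band-background step across the quadrant's own boundary line is
    multiplied by ``dim_factor`` over the outer portion of the part's
    columns (the :data:`DIM_COL_PLATEAU` fraction, feathered toward the
    center seam), emulating a local illumination falloff: the remaining
    strong segment of the edge is shorter than the span threshold L, so the
    part must escalate to a deeper threshold to recover the full boundary.
    The illumination field, noise realization and ground truth are unchanged
    (same seed, same draw order). ``dim_factor=1`` is the identity.
    """
    if which not in QUADRANTS:
        raise ValueError(f"unknown quadrant {which!r}")
    if not 0 < dim_factor <= 1:
        raise ValueError("dim_factor must lie in (0, 1]")
    dims = dict(sample.spec.quadrant_dims)
    dims[which] = dims.get(which, 1.0) * dim_factor
    new_spec = replace(sample.spec, quadrant_dims=tuple(sorted(dims.items())))
    rendered = synth_finger(new_spec, sample.seed)
    dimmed = sample.dimmed if dim_factor == 1.0 else tuple(
        sorted(set(sample.dimmed) | {which})
    )
    return replace(rendered, label=sample.label, dimmed=dimmed)


def synth_batch(
    n: int,
    quality_mix: tuple[float, float, float] = (1.0, 0.0, 0.0),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[SyntheticSample]:
    """Generate ``n`` phantoms with the given good/medium/poor mix.

    Band position and slant jitter per sample; "medium" samples get one
    quadrant dimmed to :data:`MEDIUM_DIM`, "poor" samples one or two
    quadrants (never both on the same side) dimmed to :data:`POOR_DIM`.
    Deterministic per seed; every sample carries its intended label and the
    set of dimmed quadrants.
    """
    if n < 1:
        raise ValueError("n must be positive")
    mix = np.asarray(quality_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("quality_mix must be three non-negative numbers summing to 1")
    if base_spec is None:
        base_spec = PhantomSpec(illumination=(0.1, 90.0))
    rng = np.random.default_rng(seed)
    labels = rng.choice(["good", "medium", "poor"], size=n, p=mix)
    max_slope = math.tan(math.radians(5.0))
    samples = []
    for label in labels:
        child_seed = int(rng.integers(0, 2**31))
        spec = replace(
            base_spec,
            upper_row=base_spec.upper_row + rng.uniform(-5.0, 5.0),
            lower_row=base_spec.lower_row + rng.uniform(-5.0, 5.0),
            slope=rng.uniform(-max_slope, max_slope),
        )
        sample = replace(synth_finger(spec, child_seed), label=str(label))
        if label == "medium":
            which = QUADRANTS[int(rng.integers(4))]
            sample = degrade_quadrant(sample, which, MEDIUM_DIM)
        elif label == "poor":
            upper_q = ("UL", "UR")[int(rng.integers(2))]
            lower_q = ("LL", "LR")[int(rng.integers(2))]
            targets = [upper_q, lower_q][: int(rng.integers(1, 3))]
            for which in targets:
                sample = degrade_quadrant(sample, which, POOR_DIM)
        samples.append(replace(sample, label=str(label)))
    return samples
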