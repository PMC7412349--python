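# veinroi

Robust region-of-interest (ROI) localization for NIR finger-vein images.

Finger-vein identification systems image the finger in near-infrared
transillumination: the finger appears as a bright horizontal band whose
subcutaneous veins form dark patterns. Before any feature extraction, the
finger region must be separated from the background — but uneven
illumination, sensor noise and cluttered backgrounds make simple global
thresholds unreliable. `veinroi` localizes the ROI by finding the finger's
upper and lower silhouette boundaries with a dynamic, locally adaptive
threshold strategy, and reports how hard each image was to process.

## Method

1. **Preprocessing** — an edge-preserving Gaussian bilateral filter smooths
   the capture, dataset-specific margins are cropped (keeping one boundary
   pixel: retained extent = original − margins + 1) and the result is
   bicubically down-scaled (output dimensions rounded up). Presets for four
   acquisition setups (HKPU, MMCBNU_6000, FV-USM, ZSC-FV) are built in.
2. **Horizontal Kirsch gradient** — of the eight 3×3 Kirsch compass
   templates, only the two horizontal ones are applied
   (M1 = [[5,5,5],[−3,0,−3],[−3,−3,−3]] and its vertical flip M5), and the
   pointwise maximum G = max(M1∗A, M5∗A) is the edge response. Horizontal
   masks suppress vertical clutter edges and respond 15h to a horizontal
   step of height h.
3. **3σ-criterion dynamic threshold** — the gradient population of a finger
   image is approximately normal, so binarizing at μ+kσ retains a
   predictable tail: 2.28% (k=2), 15.87% (k=1), 30.85% (k=0.5). The image
   is split into four parts (upper-left/right, lower-left/right); each part
   is binarized at μ+2σ of its own statistics, and if the longest
   8-connected component spans fewer than L = ½ of the part's width, the
   threshold escalates to μ+σ and then μ+0.5σ until a long-enough edge
   emerges.
4. **Boundary assembly and ROI** — the winning component in each part
   collapses to one row per column; same-side parts are joined, gaps filled
   by linear interpolation, and the ROI is the band strictly between the
   upper and lower boundary, cropped and resized to a fixed matching size.
5. **Quality label** — *good* if every part resolved at 2σ, *medium* if any
   needed σ, *poor* if any needed 0.5σ or failed.

A synthetic phantom generator (`veinroi.synthetic`) renders finger bands
with known ground-truth boundaries, slant, veins, illumination fields,
noise and background clutter, and can locally weaken a boundary to
construct medium/poor images — so the whole pipeline is testable without
any dataset downloads.

## Worked example

```python
import veinroi as vr

sample = vr.synth_finger(vr.PhantomSpec(), seed=3)   # ground truth known
result = vr.locate_roi(sample.image)
print(result.quality, result.levels)
import numpy as np
print("upper-boundary MAE:",
      np.abs(result.upper - sample.truth_upper).mean().round(3), "rows")
```

prints

```
good {'UL': 2.0, 'UR': 2.0, 'LL': 2.0, 'LR': 2.0}
upper-boundary MAE: 1.0 rows
```

i.e. every quadrant resolved at the strictest μ+2σ level (a *good* image)
and the recovered upper boundary deviates from the generator's ground truth
by one pixel row on average. `result.mask` is the ROI band and
`result.roi_image` the normalized 96×192 crop.

The same pipeline is scriptable from the shell:

```sh
veinroi synth --quality poor -n 5 --seed 1 --out phantoms/
veinroi extract phantoms/poor_0000.png --out-mask mask.png --stats-json info.json
veinroi batch phantoms/ --report report.csv && veinroi stats report.csv
```

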