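# octamorph

Quantitative morphometry of the retinal microvasculature from en-face
OCTA (optical coherence tomography angiography) angiograms, built for
case–control biomarker studies of neuro-ophthalmic disease — for
example, comparing eyes of neuromyelitis optica spectrum disorder
(NMOSD) patients, with and without an optic-neuritis history, against
healthy controls.

The package takes a 3 × 3 mm, 304 × 304-pixel en-face angiogram per
retinal plexus (superficial, intermediate or deep vascular complex) and
produces:

1. **Segmentations** — a binary vessel mask via a local-phase (log-Gabor
   phase-symmetry) enhancement map feeding a two-channel region-based
   active contour, and the foveal avascular zone (FAZ) as the central
   avascular component after morphological closing. Precomputed masks
   can be supplied instead, bypassing this stage.
2. **Twelve biomarkers** per image:
   FAZ area (FA), circularity (FC = 4πA/P²), axial ratio (FAR, moment
   ellipse major/minor), roundness (FR = 4A/(π·major²)), solidity (FS =
   A / convex-hull area); direction-ellipse area and axis ratio from the
   polar rose of structure-tensor vessel orientations; arc–chord
   tortuosity over skeleton branches; vessel area density (VAD, %) and
   vessel length density (VLD, %); box-counting fractal dimension (FD);
   and the bifurcation count (B-num) from the thinned vessel graph.
3. **ETDRS sub-regional analysis** — the macular grid (central circle of
   diameter 0.75 mm, internal and external rings at 1.5 / 2.25 mm, split
   into superior/temporal/inferior/nasal quadrants: SI, TI, II, NI, SE,
   TE, IE, NE, laterality-aware) with VAD, VLD, FD, tortuosity and
   B-num per sector.
4. **Group statistics** — Welch/pooled two-sample t-tests (from raw
   samples or printed summary statistics), age-adjusted logistic
   regression fitted by IRLS with per-SD odds ratios and Wald 95% CIs,
   and three-color sector significance maps (p ≤ 0.001 / p ≤ 0.05 /
   p > 0.05).

Because patient angiograms are not redistributable, the package ships a
first-class synthetic-data module: a stochastic branching-tree grower
with exact recorded ground truth (every centerline, split event and
branch length) around a perturbed-ellipse FAZ ringed by a terminal
capillary arcade, plus a cohort simulator that draws per-eye biomarker
tables from published group means/SDs.

## Worked example

```python
from octamorph import (TreeParams, generate_vessel_tree,
                       segment_vessels, segment_faz)
from octamorph.pipeline import analyze_eye

params = TreeParams(seed=7)                 # 304x304, 3x3 mm conditions
image, mask, truth = generate_vessel_tree(params)

result = analyze_eye(image)                 # full segmentation path
m = result.metrics
print(f"VAD {m['VAD']:.2f}%  VLD {m['VLD']:.2f}%  FD {m['FD']:.3f}  "
      f"B-num {m['B_num']:.0f}  (true {truth.bifurcation_count})")
print(f"FAZ: FC {m['FC']:.3f}  FAR {m['FAR']:.3f}  FS {m['FS']:.3f}")
```

prints

```
VAD 16.48%  VLD 3.03%  FD 1.515  B-num 8  (true 8)
FAZ: FC 0.981  FAR 1.005  FS 0.977
```

i.e. 16.5% of the field is perfused vessel, 3.0% is centerline, the
vascular pattern has box-counting dimension 1.52, and all 8 recorded
split events of the generator are recovered from the segmented image.
The FAZ is nearly circular (FC and FAR close to 1), as constructed.

A command-line interface mirrors the library:

```bash
octamorph simulate --preset on_vs_hc --seed 1 --out data/
octamorph segment  --in data/tree_000_image.png --out-mask m.png --out-faz f.png
octamorph metrics  --mask m.png --faz f.png --image data/tree_000_image.png --out metrics.csv
octamorph etdrs    --mask m.png --faz f.png --eye OD --out sectors.csv
octamorph stats    --table data/cohort_on_vs_hc.csv --contrast on-vs-hc --out report/
```

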