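# clearquant

Quantification pipelines for cleared-organ fluorescence imaging.

Optical tissue clearing (e.g. ethyl-cinnamate-based protocols) combined with
a vascular stain that binds the negatively charged glycosaminoglycans of
vessel walls and glomerular basement membranes makes whole mouse organs
transparent enough for deep 3D fluorescence imaging: kidneys show bright
glomeruli and vessels on a dark tubule background, skin shows the dermal
vascular network. `clearquant` implements the downstream analysis such
studies need, as a tested, reusable Python library with a CLI:

* **Glomeruli quantification (3D).** Median filter → Otsu threshold →
  binary opening → hole filling → connected components → supervised
  two-class filtering. Objects are counted and measured (volume in µm³ from
  voxel counts and the voxel size); a nearest-centroid classifier trained
  from a handful of manually labelled glomeruli keeps fully visible
  glomeruli (class 1) and rejects partially visible ones and background
  objects such as tubule fragments (class 2) — objects touching the stack
  border are always class 2. Class-1 volumes are grouped into a six-bin
  histogram used for colour coding (group 0, red, is the smallest).
* **Vessel segmentation (3D).** The same simple recipe without the
  classifier: median filter, global threshold (Otsu or fixed), opening and
  small-object removal, reporting the mask, foreground fraction and
  component count.
* **Organ shrinkage analysis (2D).** Photographs of each organ before and
  after clearing, next to a 1-cm scale object, are segmented (median 3×3,
  fixed threshold, opening, hole filling, dilation, hole filling, two-class
  particle filtering, biggest object); the scale object's pixel extent
  calibrates pixels/cm, areas are reported in cm² and the after-area as a
  percentage of the before-area (before ≡ 100%). Paired two-sided t-tests
  (`t = mean(d)/(sd(d)/√n)`, `d = after − before`, `df = n−1`, α = 0.05)
  compare before vs after.
* **Synthetic data.** Because such studies rarely deposit raw volumes, a
  first-class generator produces ground-truthed kidney stacks (glomerular
  shells with stained capillary tufts, vessel trees, background debris,
  anisotropic axial blur, Poisson–Gaussian noise; optional high-tubule
  background emulating a leaky low-molecular-weight conjugate) and organ
  photo pairs (irregular blob, ruler bar, illumination gradient, noise,
  known linear shrink factor), so every pipeline stage is verifiable
  against planted truth.

## Worked example

```python
from clearquant.synthetic import KidneySceneSpec, generate_kidney_stack
from clearquant.glomeruli import analyze_stack

spec = KidneySceneSpec(seed=1)          # 43 planted glomeruli, 3 cut by the border
stack, truth = generate_kidney_stack(spec)
labels, records, hist, summary = analyze_stack(stack)
print(f"objects found: {labels.n_objects}")
print(f"class 1 (glomeruli): {summary.n_class1}")
print(f"class 2 (background/partial): {summary.n_class2}")
print(f"mean class-1 volume: {summary.mean_volume_um3:.0f} um^3")
print(f"volume-histogram counts: {hist.counts.tolist()}")
```

prints

```
objects found: 57
class 1 (glomeruli): 40
class 2 (background/partial): 17
mean class-1 volume: 186838 um^3
volume-histogram counts: [5, 6, 8, 12, 4, 5]
```

The scene plants 43 glomeruli of which 3 are truncated by the volume
border; the pipeline finds 57 raw objects (glomeruli plus vessels and small
debris), and the classifier keeps exactly the 40 fully interior glomeruli
as class 1. Their mean volume (~1.9×10⁵ µm³) reflects the generator's
radius distribution (36 ± 3 µm truncated to [30, 44] µm); the six histogram
counts sum to the class-1 count by construction.

The same analyses are available from the shell:

```sh
clearquant simulate kidney --seed 1 --out sim/
clearquant segment-glomeruli sim/stack.tif --out results/ --plot
clearquant segment-vessels sim/stack.tif --out vessels/ --threshold 90
clearquant simulate photos --seed 1 --shrink 0.9 --out photos/
clearquant shrinkage manifest.csv --out shrink/
```

Each command archives its resolved configuration as `config.json` next to
its outputs.

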