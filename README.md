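# oximap

Hyperspectral retinal oximetry in Python: estimate the oxygen saturation of
individual retinal vessels from snapshot hyperspectral fundus image cubes, and
analyze paired occlusion experiments the way an acute retinal-vein-occlusion
(RVO) study is analyzed.

## Who this is for

Researchers working with hyperspectral fundus imaging (76 spectral bands over
450–700 nm per frame) who need a tested, transparent pipeline from an image
cube to per-vessel SO₂ values, pseudocolor saturation maps, and cohort
statistics — plus a synthetic-scene generator that produces cubes with known
ground truth for validating any step of that pipeline.

## The model

A vessel's optical density against the adjacent fundus background,

```
OD(λ) = log₁₀( I_ref(λ) / I_vessel(λ) ),
```

follows a modified Beer–Lambert law: linear in the molar extinctions of
oxygenated and deoxygenated hemoglobin plus an additive scatter term,

```
OD(λ) = a·ε_HbO₂(λ) + b·ε_Hb(λ) + g(λ),     a = L·c·s,  b = L·c·(1−s),
```

with `L` the optical path through the vessel, `c` total hemoglobin, and `s`
the oxygen saturation. Ordinary least squares over a deterministic subset of
28 wavelengths (chosen in 500–600 nm for oxy/deoxy discriminability, with two
near-isosbestic bands anchoring the amplitude) yields the saturation as the
coefficient ratio

```
ŝ = a / (a + b),
```

which cancels `L` and `c`, so no absolute calibration is required. The scatter
term `g` is constant or constant + linear in λ; both keep the fit linear.

Synthetic rabbit-retina scenes place paired arteries and veins along a
horizontal medullary ray (temporal side occludable, nasal side as internal
control) and render each vessel with the same forward model, so noise-free
inversion is exact and every estimator property is testable against ground
truth. Cohort scenarios reproduce a paired pre/post occlusion design with
per-animal saturation draws, optional spontaneous recannulation, and paired
two-tailed Student t-tests.

## Worked example

```python
from oximap import (SceneSpec, VesselSpec, compute_od, default_model, fit_so2,
                    load_reference_table, make_band_grid, render_cube,
                    segments_from_truth)

extinction = load_reference_table()
bands = make_band_grid(450, 700, 76)
vein = VesselSpec(kind="vein", region="temporal",
                  centerline=[(30, 10), (30, 80)], diameter_um=100,
                  true_so2=0.714)
cube = render_cube(SceneSpec(shape=(60, 90), vessels=[vein],
                             noise_kind="none"), bands, extinction)
(segment,) = segments_from_truth(cube)
result = fit_so2(compute_od(cube, segment),
                 extinction, default_model(bands))
print(f"SO2 = {result.so2_percent:.3f}%")
```

prints

```
SO2 = 71.400%
```

— a noise-free 100 µm vein rendered at 71.4% saturation inverts exactly,
because the coefficient ratio recovers `s` whatever the (unknown) path length
and hemoglobin concentration. `examples/` contains this and three more
narrative scripts: the extinction table and its isosbestic point
(`01_extinction_spectra.py`), a full 20-animal stochastic occlusion cohort
with paired t-tests (`03_rvo_cohort_study.py`, temporal vein dropping ~7.4
saturation points at p ≈ 10⁻⁹ while nasal controls stay flat), and
pseudocolor map rendering (`04_pseudocolor_map.py`, blue = 0% to red = 100%).

A thin CLI wraps the same pipeline for shell use:

```
oximap simulate --preset rvo-baseline --seed 7 --out sim/
oximap oximetry --input sim/ --out results.csv
oximap study    --input results.csv --out study/
oximap render   --input sim/animal01_baseline.hdr --out map.png
```

Cubes are written as ENVI-style header + raw binary (or multi-page TIFF with
a wavelength sidecar); all outputs carry seed/config provenance headers.

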