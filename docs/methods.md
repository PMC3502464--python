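# Methods

## Forward model

Every synthetic vessel is rendered under a modified Beer–Lambert law. A
background pixel carries `I₀(λ) = illumination × reflectance(λ)`; a vessel
pixel carries

```
I(λ) = I₀(λ) · 10^( −L·c·[ s·ε_HbO₂(λ) + (1−s)·ε_Hb(λ) ] − g(λ) )
```

* `L` — optical path (cm), `path_length_scale × diameter`. Default scale 1.0
  (single transit); double-pass and photon-path effects are folded into the
  fitted amplitude, which the saturation ratio cancels anyway.
* `c` — total hemoglobin, default 2.3·10⁻³ mol/L (150 g/L at 64 500 g/mol).
* `s` — true oxygen saturation, a fraction in [0, 1].
* `g(λ)` — additive scatter. Default `linear`: `g₀ + g₁(λ − 575 nm)` with
  g₀ = 0.05 OD and g₁ = 10⁻⁴ OD/nm, which lies **inside** the model class the
  estimator fits, so noise-free inversion is exact by construction. A
  `powerlaw` mode, `g₀(λ/575)^−1.3`, sits outside the fit class and exists to
  stress the estimator under model mismatch.

Vessel profiles are top-hat (uniform transmission across the lumen): real
vessels show center-to-edge path-length variation and a central light reflex,
which this generator deliberately omits (see Limitations).

## Extinction spectra

The packaged table (`data/hb_extinction_synthetic.csv`) is a synthetic
compilation on a 1 nm grid over 440–710 nm, built by monotone (PCHIP)
interpolation through anchor points that encode the canonical features of
hemoglobin absorption: descending Soret tails below 500 nm, the HbO₂ β/α
bands at 542/577 nm, the deoxy-Hb peak at 555 nm, isosbestic crossings near
506, 548, 570 and 586 nm (the 586 nm crossing exact by construction), and
deoxy dominance in the red (ε_Hb/ε_HbO₂ ≈ 10 at 660 nm). It is not a copy of
any published instrument calibration; because the same table drives both the
forward model and the unmixing, all recovery results are internally
consistent, and absolute agreement with any particular spectrometer is
neither claimed nor needed for the saturation ratio. Runtime resampling is
piecewise linear — monotone, artifact-free, and exact at knots, which is
sufficient at the ~3.3 nm band spacing of the acquisition grid.

## Scene and cohort generation

The acquisition grid defaults to 76 evenly spaced bands over 450–700 nm. The
rabbit-like preset places a horizontal medullary-ray band in a 96×160 frame
at 10 µm/pixel: an 80 µm artery above a 120 µm vein on each of the temporal
(left, occludable) and nasal (right, control) sides. The 50 µm floor on
renderable vessel diameter mirrors the resolution limit of the emulated
instrument (5 pixels at default pitch).

Cohort scenarios assign each (kind, region) arm either a fixed saturation or
a normal(mean, SD) draw per animal. Defaults are the emulated study's arm
statistics: temporal artery/vein 85.1 ± 6.1 / 71.4 ± 5.5 %, nasal controls
85.2 ± 7.6 / 69.2 ± 6.2 %, with one-hour post-occlusion drops of 4.5 (artery)
and 7.4 (vein) saturation points applied to the temporal side only. Across
timepoints the per-animal noise is correlated with ρ = 0.7 (shared animal
effect plus residual); the paired design implies a positive correlation but
no value is published, so 0.7 is declared here and is configurable — it
matters only for the stochastic power checks, not for the deterministic
recovery targets. A recannulation timepoint, when set, restores each
animal's pre-occlusion saturations exactly, emulating spontaneous
recannulation of the occluded vein.

Noise defaults to per-pixel, per-band Gaussian with σ = 1% of illumination
(a shot-noise-scaled Poisson mode is available); all draws are seeded, and a
cohort expands its seed into independent per-scene child seeds, so the same
cohort seed yields bit-identical cubes.

## Optical-density extraction

Segments come from detection or from ground-truth labels; both feed the same
OD computation:

* **Detection** thresholds a single green band (570 nm default, where
  hemoglobin contrast is strong) at 0.7× the median image intensity — the
  median is a robust background estimate because vessels occupy a small
  fraction of the frame — then labels connected components, discards specks
  under 20 pixels and components with <5% contrast, and takes the centerline
  from the morphological skeleton. Otsu thresholding was rejected: with two
  vessel classes of very different darkness it can split vessel-vs-vessel
  instead of vessel-vs-background.
* **OD** is `log₁₀(reference/vessel)` per band, with 10% trimmed means on
  both sides for robustness to stray pixels. The vessel mean uses only the
  central 50% of the width (by distance transform) to avoid partial-volume
  edge pixels; the reference is a pair of 3-row strips parallel to the
  centerline at a lateral offset of 2× the vessel width (clamped into the
  frame), excluding all vessel pixels of any segment. A zero vessel mean
  would send OD to +∞; it is capped at 6.0 with a logged warning. These
  sampling rules are declared package choices — the acquisition literature
  does not specify them.

## Saturation estimation

The unmixing design matrix has columns `ε_HbO₂`, `ε_Hb`, `1`, and optionally
`(λ − λ̄)/100`; the fit is `numpy.linalg.lstsq` and the saturation is
`ŝ = a/(a+b)`, clipped to [0, 1] with a flag (a `raw` policy reports the
unclipped ratio instead). Rank deficiency (e.g. an all-isosbestic design)
raises; a non-positive fitted amplitude `a + b` yields a flagged degenerate
result with NaN saturation rather than a misleading number.

The default 28 fit wavelengths are chosen deterministically from the bands in
500–600 nm: the two most nearly isosbestic bands (amplitude anchors) plus the
remainder ranked by |ε_HbO₂ − ε_Hb|, ties toward the shorter wavelength, the
window widening symmetrically if it holds fewer than 28 bands. The published
description of the emulated instrument gives the count but not the
identities, so the rule is declared, deterministic and configurable; exact
numeric equivalence with the original device is not claimed.

Saturation maps paint the segment-level estimate over the segment's pixels
(the per-vessel mean is the reporting unit); per-pixel fitting is an opt-in
slow path. Pseudocolor rendering is a linear blue→red ramp,
RGB = (s, 0, 1−s), with sentinel pixels showing the grayscale fundus band.

## Cohort statistics

Measurements are averaged per animal within each arm and timepoint before
testing, so animals — not vessel segments — are the unit of analysis (a
per-segment mode is available via `paired_ttest` directly). The paired
two-tailed Student t-test uses `t = mean(d)/(sd(d)/√n)` with the sample SD
and df = n − 1; identical pairs give t = 0, p = 1; zero-variance nonzero-mean
differences give a p = 0 sentinel with a warning. No multiple-testing
correction is applied, matching per-comparison reporting. Saturations are
percent externally, fractions internally.

## Problem sizes and numerical choices

The reference cohort computation (acceptance script and end-to-end tests)
renders 20 animals × 2 timepoints of 96×160×76 noise-free cubes and runs the
full detection/OD/unmixing pipeline, completing in a few seconds. Statistical
calibrations simulate at the cohort level: 500–1000 null cohorts for type-I
error (expected rejection fraction 0.05 ± 0.02), 200 cohorts at the study
effect size for power (>0.95), 200 zero-delta control arms (≥90%
non-significant). Noisy-recovery checks use 200 seeded single-vessel
replicates at σ = 1% noise (mean |ŝ − s| ≤ 0.02).

ENVI-style I/O writes band-sequential little-endian floats; float32 cubes as
data type 4 and float64 as type 5, so round trips are bit-exact for both.
Package metadata rides in the header as JSON; ground-truth label images go to
a sidecar TIFF.

## Limitations

* No radiative-transfer realism: no Monte-Carlo photon transport, ocular
  media opacity, pigmentation classes, vessel light reflex, or partial-volume
  edge profiles. Passing recovery tests therefore demonstrates correctness of
  the inverse computation under the stated forward model, not robustness to
  everything real fundus data contains.
* Hemorrhage and edema (the main human-data confounders) are not rendered.
* Collateral/retrograde filling is not modelled mechanistically; per-animal
  variation enters only through the declared saturation distributions.
* Detection assumes near-horizontal, well-separated vessels on a flat
  background (the medullary-ray geometry); it is not a general fundus
  vessel segmenter, and artery/vein/region roles for detected segments come
  from the preset layout convention (temporal left, artery above vein).
* Temperature/pH effects on extinction and other hemoglobin species
  (met-Hb, carboxy-Hb) are out of scope.
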