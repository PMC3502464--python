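"""Synthetic hyperspectral fundus scenes with known oxygen saturations.

Emulates snapshot hyperspectral fundus imaging of the rabbit retina, whose
vasculature is confined to a horizontal band (the medullary rays) carrying
paired arteries and veins on the temporal and nasal sides of the optic disc.
Each vessel is rendered under the Beer-Lambert forward model

    I(lambda) = I0(lambda) * 10^(-L c [s eps_oxy + (1-s) eps_deoxy] - g(lambda))

with I0 the illumination times background reflectance, L the optical path
(path_length_scale x diameter), c the total hemoglobin concentration, s the
true oxygen saturation and g an additive scatter term. The default scatter is
constant + linear in wavelength, i.e. inside the model class the unmixing fit
assumes, so noise-free inversion is exact; a wavelength-power-law mode
provides deliberate model mismatch for robustness tests.

Cohort scenarios reproduce the experimental design of an acute retinal vein
occlusion (RVO) study: a temporal vein is occluded, the nasal vessels of the
same eye serve as internal controls, and saturations are re-imaged at later
timepoints, optionally with spontaneous recannulation restoring baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeometryError
from .hb_spectra import ExtinctionTable, resample
from .vessel_extraction import HyperspectralCube

__all__ = [
    "SpectralBandSet",
    "VesselSpec",
    "SceneSpec",
    "CohortSpec",
    "CohortScenes",
    "make_band_grid",
    "render_cube",
    "make_rvo_cohort",
    "vessel_exponent",
    "medullary_ray_scene",
    "rvo_baseline_cohort",
    "BASELINE_SO2",
    "RVO_1H_DELTAS",
]

# Default total hemoglobin: 150 g/L at 64500 g/mol.
HB_CONCENTRATION_M = 2.3e-3

# Study-condition constants: cohort arm means (%) and SDs from the rabbit RVO
# experiment these scenarios emulate, on the saturation-fraction scale.
BASELINE_SO2 = {
    ("artery", "temporal"): (0.851, 0.061),
    ("vein", "temporal"): (0.714, 0.055),
    ("artery", "nasal"): (0.852, 0.076),
    ("vein", "nasal"): (0.692, 0.062),
}
# One hour post-occlusion saturation drops on the occluded (temporal) side.
RVO_1H_DELTAS = {"artery": -0.045, "vein": -0.074}


@dataclass(frozen=True)
class SpectralBandSet:
    """Strictly increasing wavelength grid (nm); >= 2 bands."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or len(w) < 2:
            raise ValueError("band set needs at least 2 wavelengths")
        if not np.all(np.diff(w) > 0):
            raise ValueError("band wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class VesselSpec:
    """One renderable vessel: geometry plus Beer-Lambert ground truth."""

    kind: str                      # artery | vein
    region: str                    # temporal | nasal
    centerline: list               # [(row, col), ...] image points
    diameter_um: float
    true_so2: float                # fraction in [0, 1]
    hb_concentration: float = HB_CONCENTRATION_M   # mol/L
    path_length_scale: float = 1.0                 # optical path / diameter
    scatter_mode: str = "linear"   # linear (in fit class) | powerlaw (mismatch)
    scatter_offset: float = 0.05   # OD units
    scatter_slope: float = 1e-4    # OD per nm (linear mode)
    scatter_exponent: float = 1.3  # powerlaw mode: offset*(lambda/575)^-b

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_so2 <= 1.0:
            raise ValueError("true_so2 must lie in [0, 1]")
        if self.diameter_um < 50.0:
            raise ValueError("vessels below ~50 um are not renderable")
        if self.kind not in ("artery", "vein"):
            raise ValueError(f"unknown vessel kind {self.kind!r}")


@dataclass
class SceneSpec:
    """A single synthetic fundus frame."""

    shape: tuple = (96, 160)          # rows, cols
    pixel_pitch_um: float = 10.0
    background_reflectance: float | np.ndarray = 0.6   # scalar or per-band
    illumination: float = 1.0
    vessels: list = field(default_factory=list)
    noise_kind: str = "gaussian"      # none | gaussian | poisson
    noise_sigma: float = 0.01         # gaussian sigma, fraction of illumination
    poisson_gain: float = 1e4         # photons per intensity unit
    seed: int = 0


@dataclass
class CohortSpec:
    """A paired pre/post cohort scenario.

    ``assignments`` maps (kind, region) to either a fixed saturation fraction
    or a (mean, sd) tuple sampled per animal. ``occlusion_deltas`` maps a
    timepoint to per-kind saturation deltas applied to occluded-side
    (temporal) vessels only. If ``recannulation_timepoint`` is set, occluded
    vessels recover their pre-occlusion saturations at that timepoint.
    ``rho`` is the within-animal correlation of the saturation noise across
    timepoints (paired design).
    """

    n_animals: int = 20
    assignments: dict = field(default_factory=lambda: dict(BASELINE_SO2))
    timepoints: tuple = ("baseline", "1h")
    occlusion_deltas: dict = field(default_factory=lambda: {"1h": dict(RVO_1H_DELTAS)})
    recannulation_timepoint: str | None = None
    rho: float = 0.7
    noise_kind: str = "gaussian"
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class CohortScenes:
    """Scenes and ground truth for every (animal, timepoint) of a cohort."""

    scenes: dict          # (animal, timepoint) -> SceneSpec
    truth: pd.DataFrame   # animal, timepoint, vessel_id, kind, region, true_so2
    bands: SpectralBandSet


def make_band_grid(lambda_min: float, lambda_max: float, n_bands: int = 76) -> SpectralBandSet:
    """Evenly spaced band grid with both endpoints included.

    The default mirrors a snapshot hyperspectral fundus camera acquiring
    ~76 bands over 450-700 nm (~3.3 nm spacing).
    """
    if lambda_min >= lambda_max:
        raise ValueError("lambda_min must be < lambda_max")
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    return SpectralBandSet(np.linspace(lambda_min, lambda_max, n_bands))


def vessel_exponent(vessel: VesselSpec, bands: SpectralBandSet, extinction: ExtinctionTable) -> np.ndarray:
    """Closed-form absorbance exponent E(lambda) of a vessel, in OD units.

    E = L c [s eps_oxy + (1-s) eps_deoxy] + g(lambda); vessel pixels transmit
    I0 * 10^-E.
    """
    eps = resample(extinction, bands)
    L_cm = vessel.path_length_scale * vessel.diameter_um * 1e-4
    s = vessel.true_so2
    absorbance = L_cm * vessel.hb_concentration * (
        s * eps.eps_oxy + (1.0 - s) * eps.eps_deoxy
    )
    lam = bands.wavelengths
    if vessel.scatter_mode == "linear":
        g = vessel.scatter_offset + vessel.scatter_slope * (lam - 575.0)
    elif vessel.scatter_mode == "powerlaw":
        g = vessel.scatter_offset * (lam / 575.0) ** (-vessel.scatter_exponent)
    else:
        raise ValueError(f"unknown scatter mode {vessel.scatter_mode!r}")
    return absorbance + g


def _vessel_mask(vessel: VesselSpec, shape: tuple, pitch_um: float) -> np.ndarray:
    """Pixels within half a diameter of the centerline polyline."""
    pts = np.asarray(vessel.centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("centerline must be a list of (row, col) points")
    half_px = vessel.diameter_um / pitch_um / 2.0
    if (
        pts[:, 0].min() < 0 or pts[:, 1].min() < 0
        or pts[:, 0].max() >= shape[0] or pts[:, 1].max() >= shape[1]
    ):
        raise GeometryError("vessel centerline outside image bounds")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dmin = np.full(len(pix), np.inf)
    if len(pts) == 1:
        dmin = np.linalg.norm(pix - pts[0], axis=1)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = p1 - p0
        L2 = seg @ seg
        if L2 == 0:
            d = np.linalg.norm(pix - p0, axis=1)
        else:
            t = np.clip((pix - p0) @ seg / L2, 0.0, 1.0)
            d = np.linalg.norm(pix - (p0 + t[:, None] * seg), axis=1)
        dmin = np.minimum(dmin, d)
    mask = (dmin <= half_px).reshape(shape)
    if not mask.any():
        raise GeometryError("vessel renders to zero pixels")
    return mask


def render_cube(scene: SceneSpec, bands: SpectralBandSet, extinction: ExtinctionTable) -> HyperspectralCube:
    """Render a scene into a hyperspectral cube with ground truth attached.

    Background pixels carry I0 = illumination x reflectance per band; vessel
    pixels are attenuated by their Beer-Lambert exponent. Noise (if any) is
    applied per band with the scene's seed; the label image and per-vessel
    truth go into cube metadata.
    """
    nrows, ncols = scene.shape
    nbands = len(bands)
    refl = np.broadcast_to(
        np.asarray(scene.background_reflectance, dtype=float), (nbands,)
    )
    if np.any(refl <= 0) or np.any(refl > 1):
        raise ValueError("background reflectance must lie in (0, 1]")
    I0 = scene.illumination * refl
    cube = np.broadcast_to(I0, (nrows, ncols, nbands)).copy()

    labels = np.zeros((nrows, ncols), dtype=np.int32)
    truth = []
    for vid, vessel in enumerate(scene.vessels, start=1):
        mask = _vessel_mask(vessel, scene.shape, scene.pixel_pitch_um)
        E = vessel_exponent(vessel, bands, extinction)
        cube[mask] = I0 * 10.0 ** (-E)
        labels[mask] = vid
        truth.append(
            {
                "vessel_id": vid,
                "kind": vessel.kind,
                "region": vessel.region,
                "true_so2": vessel.true_so2,
                "diameter_um": vessel.diameter_um,
            }
        )

    if scene.noise_kind not in ("none", "gaussian", "poisson"):
        raise ValueError(f"unknown noise kind {scene.noise_kind!r}")
    if scene.noise_kind == "gaussian" and scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        cube = cube + rng.normal(
            0.0, scene.noise_sigma * scene.illumination, size=cube.shape
        )
        cube = np.clip(cube, 0.0, None)
    elif scene.noise_kind == "poisson":
        rng = np.random.default_rng(scene.seed)
        cube = rng.poisson(cube * scene.poisson_gain).astype(float) / scene.poisson_gain

    meta = {
        "labels": labels,
        "truth": truth,
        "seed": scene.seed,
        "noise_kind": scene.noise_kind,
        "noise_sigma": scene.noise_sigma,
        "pixel_pitch_um": scene.pixel_pitch_um,
        "illumination": scene.illumination,
    }
    return HyperspectralCube(cube, bands.wavelengths.copy(), meta)


# ---------------------------------------------------------------------------
# Rabbit medullary-ray preset and RVO cohort scenarios


def medullary_ray_scene(
    so2: dict,
    shape: tuple = (96, 160),
    noise_kind: str = "gaussian",
    noise_sigma: float = 0.01,
    seed: int = 0,
    scatter_mode: str = "linear",
) -> SceneSpec:
    """Rabbit-like frame: temporal artery/vein pair left, nasal pair right.

    ``so2`` maps (kind, region) to true saturation fractions. Arteries
    (80 um) run above veins (120 um) along the horizontal medullary ray;
    10 um/pixel pitch.
    """
    nrows, ncols = shape
    mid = ncols // 2
    spans = {"temporal": (8, mid - 12), "nasal": (mid + 12, ncols - 8)}
    rows = {"artery": int(nrows * 0.31), "vein": int(nrows * 0.69)}
    diam = {"artery": 80.0, "vein": 120.0}
    vessels = []
    for region, kind in itertools.product(("temporal", "nasal"), ("artery", "vein")):
        c0, c1 = spans[region]
        vessels.append(
            VesselSpec(
                kind=kind,
                region=region,
                centerline=[(rows[kind], c0), (rows[kind], c1)],
                diameter_um=diam[kind],
                true_so2=float(np.clip(so2[(kind, region)], 0.0, 1.0)),
                scatter_mode=scatter_mode,
            )
        )
    return SceneSpec(
        shape=shape,
        vessels=vessels,
        noise_kind=noise_kind,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _draw_saturations(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-animal, per-timepoint true saturations under the paired design."""
    rows = []
    sqrho = np.sqrt(max(spec.rho, 0.0))
    sqres = np.sqrt(max(1.0 - spec.rho, 0.0))
    first_tp = spec.timepoints[0]
    for animal in range(1, spec.n_animals + 1):
        z_animal = {key: rng.standard_normal() for key in spec.assignments}
        baseline: dict = {}
        for tp in spec.timepoints:
            deltas = spec.occlusion_deltas.get(tp, {})
            recan = tp == spec.recannulation_timepoint
            for (kind, region), assign in spec.assignments.items():
                if isinstance(assign, (tuple, list)):
                    mean, sd = assign
                else:
                    mean, sd = float(assign), 0.0
                z = sqrho * z_animal[(kind, region)] + sqres * rng.standard_normal()
                if recan and region == "temporal":
                    # spontaneous recannulation: flow (and saturation) returns
                    # exactly to this animal's pre-occlusion level
                    s = baseline[(kind, region)]
                else:
                    s = mean + sd * z
                    if region == "temporal":
                        s += deltas.get(kind, 0.0)
                s = float(np.clip(s, 0.0, 1.0))
                if tp == first_tp:
                    baseline[(kind, region)] = s
                rows.append(
                    {
                        "animal": animal,
                        "timepoint": tp,
                        "kind": kind,
                        "region": region,
                        "true_so2": s,
                    }
                )
    return pd.DataFrame(rows)


def make_rvo_cohort(spec: CohortSpec, shape: tuple = (96, 160)) -> CohortScenes:
    """Expand a cohort scenario into per-animal, per-timepoint scenes.

    Deterministic given ``spec.seed``: saturations are drawn first (animal-
    then timepoint-ordered), then each scene receives an independent child
    seed for its noise draws. Occlusion deltas apply to temporal vessels only;
    the recannulation timepoint (if any) restores pre-occlusion saturations.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _draw_saturations(spec, rng)
    bands = make_band_grid(450.0, 700.0, 76)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_animals * len(spec.timepoints))
    scenes = {}
    truth = truth.set_index(["animal", "timepoint", "kind", "region"])
    idx = 0
    vids = {}
    for animal in range(1, spec.n_animals + 1):
        for tp in spec.timepoints:
            so2 = {
                (kind, region): truth.loc[(animal, tp, kind, region), "true_so2"]
                for kind in ("artery", "vein")
                for region in ("temporal", "nasal")
            }
            scene = medullary_ray_scene(
                so2,
                shape=shape,
                noise_kind=spec.noise_kind,
                noise_sigma=spec.noise_sigma,
                seed=int(seeds[idx].generate_state(1)[0] % (2**31)),
            )
            scenes[(animal, tp)] = scene
            idx += 1
    truth = truth.reset_index()
    # vessel ids in render order (temporal artery, temporal vein, nasal artery, nasal vein)
    order = {
        ("artery", "temporal"): 1,
        ("vein", "temporal"): 2,
        ("artery", "nasal"): 3,
        ("vein", "nasal"): 4,
    }
    truth["vessel_id"] = [order[(k, r)] for k, r in zip(truth["kind"], truth["region"])]
    return CohortScenes(scenes=scenes, truth=truth, bands=bands)


def rvo_baseline_cohort(
    n_animals: int = 20,
    fixed: bool = False,
    noise_kind: str = "gaussian",
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> CohortSpec:
    """The acute-RVO study scenario: baseline and one-hour-post timepoints.

    Arm means/SDs and the post-occlusion drops (artery -4.5, vein -7.4
    saturation points) follow the rabbit cohort this generator emulates. With
    ``fixed=True`` every animal receives exactly the arm mean (SD 0).
    """
    assignments = {
        key: (mean, 0.0 if fixed else sd) for key, (mean, sd) in BASELINE_SO2.items()
    }
    return CohortSpec(
        n_animals=n_animals,
        assignments=assignments,
        timepoints=("baseline", "1h"),
        occlusion_deltas={"1h": dict(RVO_1H_DELTAS)},
        noise_kind=noise_kind,
        noise_sigma=noise_sigma,
        seed=seed,
    )
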