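"""Oxygen saturation by linear least-squares unmixing of hemoglobin spectra.

The modified Beer-Lambert model makes vessel optical density linear in the
two hemoglobin extinction curves plus a scatter term:

    OD(lambda) = a eps_oxy(lambda) + b eps_deoxy(lambda) + scatter(lambda)

with a = L c s and b = L c (1 - s). Solving this by ordinary least squares
over a deterministic 28-wavelength subset and forming s_hat = a / (a + b)
cancels the unknown path length and hemoglobin concentration, so saturation
is recovered without absolute calibration. The scatter term is constant or
constant + linear-in-wavelength; both keep the fit linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegeneracyError
from .hb_spectra import ExtinctionTable, load_reference_table, resample
from .vessel_extraction import HyperspectralCube, ODSpectrum, VesselSegment, compute_od

__all__ = [
    "OximetryModel",
    "OximetryResult",
    "select_fit_wavelengths",
    "fit_so2",
    "so2_map",
    "SENTINEL",
]

log = logging.getLogger(__name__)

SENTINEL = np.nan  # no-data marker in saturation maps

DEFAULT_N_WAVELENGTHS = 28
SELECTION_WINDOW = (500.0, 600.0)
N_ISOSBESTIC_ANCHORS = 2


@dataclass(frozen=True)
class OximetryModel:
    """Fit configuration: wavelength subset, scatter term, clipping policy."""

    fit_wavelengths: np.ndarray
    scatter: str = "linear"          # const | linear
    clipping: str = "clip"           # clip (to [0,1]) | raw (report + flag)

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.fit_wavelengths, dtype=float))
        if len(w) < 3:
            raise ValueError("need at least 3 fit wavelengths")
        if self.scatter not in ("const", "linear"):
            raise ValueError(f"unknown scatter term {self.scatter!r}")
        if self.clipping not in ("clip", "raw"):
            raise ValueError(f"unknown clipping policy {self.clipping!r}")
        object.__setattr__(self, "fit_wavelengths", np.sort(w))


@dataclass
class OximetryResult:
    """Estimated saturation for one segment, with fit diagnostics."""

    segment_id: int
    so2: float                 # fraction; NaN when degenerate
    coefficients: dict = field(default_factory=dict)  # a, b, scatter terms
    residual_norm: float = 0.0
    clipped: bool = False
    degenerate: bool = False

    @property
    def so2_percent(self) -> float:
        return 100.0 * self.so2


def select_fit_wavelengths(
    bands,
    n: int = DEFAULT_N_WAVELENGTHS,
    extinction: ExtinctionTable | None = None,
    window: tuple[float, float] = SELECTION_WINDOW,
) -> np.ndarray:
    """Deterministic choice of ``n`` fit wavelengths from a band grid.

    The bands inside ``window`` (green-yellow, where the oxy/deoxy curves
    differ most and fundus signal is strong) are ranked by spectral
    discriminability |eps_oxy - eps_deoxy|; the top ``n`` are taken, except
    that the two most nearly isosbestic bands in the window are always
    included to anchor the total-hemoglobin amplitude. Ties break toward the
    shorter wavelength. The window widens symmetrically if it holds fewer
    than ``n`` bands; ``n`` equal to the band count returns every band.
    """
    w = np.asarray(getattr(bands, "wavelengths", bands), dtype=float)
    if n > len(w):
        raise ValueError(f"cannot select {n} wavelengths from {len(w)} bands")
    if n == len(w):
        return w.copy()
    if extinction is None:
        extinction = load_reference_table()

    lo, hi = window
    inside = (w >= lo) & (w <= hi)
    while inside.sum() < n:
        lo -= 10.0
        hi += 10.0
        inside = (w >= lo) & (w <= hi)
    cand = w[inside]
    eps = resample(extinction, cand)
    diff = np.abs(eps.eps_oxy - eps.eps_deoxy)

    # stable orderings with ties toward shorter wavelength
    by_iso = np.lexsort((cand, diff))          # ascending |diff|
    by_disc = np.lexsort((cand, -diff))        # descending |diff|
    chosen = list(cand[by_iso[:N_ISOSBESTIC_ANCHORS]])
    for lam in cand[by_disc]:
        if len(chosen) >= n:
            break
        if lam not in chosen:
            chosen.append(lam)
    return np.sort(np.asarray(chosen))


def _design_matrix(lam: np.ndarray, eps: ExtinctionTable, scatter: str) -> np.ndarray:
    cols = [eps.eps_oxy, eps.eps_deoxy, np.ones_like(lam)]
    if scatter == "linear":
        cols.append((lam - lam.mean()) / 100.0)
    return np.column_stack(cols)


def fit_so2(od: ODSpectrum, extinction: ExtinctionTable, model: OximetryModel) -> OximetryResult:
    """Least-squares unmixing of one OD spectrum into s_hat = a / (a + b).

    Raises :class:`DegeneracyError` when the design is rank-deficient (e.g.
    all fit wavelengths isosbestic). A non-positive fitted total hemoglobin
    amplitude a + b yields a flagged degenerate result with NaN saturation.
    """
    lam = model.fit_wavelengths
    idx = []
    for target in lam:
        j = np.argmin(np.abs(od.wavelengths - target))
        if abs(od.wavelengths[j] - target) > 1e-6:
            raise ValueError(f"OD spectrum does not cover fit wavelength {target:g} nm")
        idx.append(j)
    y = od.od[idx]
    eps = resample(extinction, lam)
    X = _design_matrix(lam, eps, model.scatter)

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegeneracyError(
            "rank-deficient unmixing design (fit wavelengths do not separate "
            "oxy- from deoxyhemoglobin)"
        )
    a, b = float(beta[0]), float(beta[1])
    residual = float(np.linalg.norm(y - X @ beta))
    coeffs = {"a": a, "b": b, "scatter": [float(v) for v in beta[2:]]}

    if a + b <= 0:
        log.warning("segment %s: non-positive hemoglobin amplitude", od.segment_id)
        return OximetryResult(
            segment_id=od.segment_id,
            so2=SENTINEL,
            coefficients=coeffs,
            residual_norm=residual,
            degenerate=True,
        )
    raw = a / (a + b)
    clipped = not (0.0 <= raw <= 1.0)
    so2 = float(np.clip(raw, 0.0, 1.0)) if model.clipping == "clip" else raw
    return OximetryResult(
        segment_id=od.segment_id,
        so2=so2,
        coefficients=coeffs,
        residual_norm=residual,
        clipped=clipped,
    )


def default_model(bands, n: int = DEFAULT_N_WAVELENGTHS, scatter: str = "linear",
                  extinction: ExtinctionTable | None = None) -> OximetryModel:
    """Convenience: model with the default deterministic wavelength selection."""
    return OximetryModel(
        fit_wavelengths=select_fit_wavelengths(bands, n=n, extinction=extinction),
        scatter=scatter,
    )


def so2_map(
    cube: HyperspectralCube,
    segments: list[VesselSegment],
    extinction: ExtinctionTable,
    model: OximetryModel,
    per_pixel: bool = False,
) -> np.ndarray:
    """Saturation map: every vessel pixel carries its segment's s_hat.

    Non-vessel pixels hold NaN. With ``per_pixel=True`` each vessel pixel is
    unmixed from its own spectrum against the segment reference (slow path).
    Per-segment fit failures are logged and leave that segment as sentinel.
    """
    out = np.full(cube.shape[:2], SENTINEL)
    for seg in segments:
        try:
            if per_pixel:
                ref = cube.intensities[
                    seg.reference_pixels[0], seg.reference_pixels[1], :
                ].mean(axis=0)
                for r, c in zip(*seg.vessel_pixels):
                    pix = cube.intensities[r, c, :]
                    with np.errstate(divide="ignore"):
                        od = np.log10(ref) - np.log10(np.maximum(pix, 1e-30))
                    spec = ODSpectrum(seg.id, cube.wavelengths, od)
                    out[r, c] = fit_so2(spec, extinction, model).so2
            else:
                res = fit_so2(compute_od(cube, seg), extinction, model)
                out[seg.vessel_pixels] = res.so2
        except Exception as exc:  # keep other segments alive
            log.warning("segment %s: fit failed (%s)", seg.id, exc)
    return out
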