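"""Molar extinction spectra of oxy- and deoxyhemoglobin over the visible range.

The package ships a synthetic compilation of the two extinction curves
(``data/hb_extinction_synthetic.csv``) constructed from the canonical band
structure of hemoglobin absorption — descending Soret tails below 500 nm, the
HbO2 beta/alpha bands at 542/577 nm, the deoxy-Hb peak at 555 nm, isosbestic
crossings near 506, 548, 570 and 586 nm, and the strong deoxy dominance around
660 nm exploited by pulse oximetry. It is not a copy of any published
instrument calibration; within this package the same table drives both the
synthetic forward model and the unmixing fit, so oximetry estimates are
internally consistent.

Units: wavelengths in nm, extinction in cm^-1 (mol/L)^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["ExtinctionTable", "load_reference_table", "resample", "isosbestic_wavelength"]

_REFERENCE_CSV = "hb_extinction_synthetic.csv"


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength molar extinction of HbO2 (``eps_oxy``) and Hb (``eps_deoxy``).

    Wavelengths are strictly increasing; extinctions are strictly positive.
    """

    wavelengths: np.ndarray  # nm
    eps_oxy: np.ndarray      # cm^-1 M^-1
    eps_deoxy: np.ndarray    # cm^-1 M^-1

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        eo = np.asarray(self.eps_oxy, dtype=float)
        ed = np.asarray(self.eps_deoxy, dtype=float)
        if not (w.ndim == eo.ndim == ed.ndim == 1):
            raise ValueError("extinction table fields must be 1-D")
        if not (len(w) == len(eo) == len(ed)):
            raise ValueError("wavelengths, eps_oxy and eps_deoxy must have equal length")
        if len(w) < 1:
            raise ValueError("extinction table cannot be empty")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(eo > 0) and np.all(ed > 0)):
            raise ValueError("extinction values must be strictly positive")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "eps_oxy", eo)
        object.__setattr__(self, "eps_deoxy", ed)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def to_csv(self, path) -> None:
        """Export as CSV with columns wavelength_nm, eps_oxy, eps_deoxy."""
        arr = np.column_stack([self.wavelengths, self.eps_oxy, self.eps_deoxy])
        np.savetxt(
            path,
            arr,
            delimiter=",",
            header="wavelength_nm,eps_oxy,eps_deoxy",
            comments="",
            fmt="%.6g",
        )


def load_reference_table() -> ExtinctionTable:
    """Load the embedded hemoglobin extinction table (covers 440-710 nm)."""
    with resources.files("oximap.data").joinpath(_REFERENCE_CSV).open("rb") as fh:
        data = np.loadtxt(fh, delimiter=",", skiprows=1)
    return ExtinctionTable(data[:, 0], data[:, 1], data[:, 2])


def resample(table: ExtinctionTable, grid) -> ExtinctionTable:
    """Linearly interpolate both extinction curves onto ``grid`` (nm).

    ``grid`` may be a wavelength array or any object with a ``wavelengths``
    attribute (e.g. a :class:`~oximap.synthetic_fundus.SpectralBandSet`).
    Raises ``ValueError`` naming the offending wavelength if the grid leaves
    the table's span.
    """
    w = np.asarray(getattr(grid, "wavelengths", grid), dtype=float)
    lo, hi = table.span
    bad = w[(w < lo) | (w > hi)]
    if bad.size:
        raise ValueError(
            f"wavelength {bad[0]:g} nm outside extinction table span [{lo:g}, {hi:g}] nm"
        )
    eo = np.interp(w, table.wavelengths, table.eps_oxy)
    ed = np.interp(w, table.wavelengths, table.eps_deoxy)
    return ExtinctionTable(w, eo, ed)


def isosbestic_wavelength(table: ExtinctionTable, window: tuple[float, float] = (560.0, 590.0)) -> float:
    """Wavelength in ``window`` where |eps_oxy - eps_deoxy| is smallest.

    At an isosbestic point the vessel optical density is independent of
    oxygen saturation, which anchors the fitted hemoglobin amplitude.
    """
    m = (table.wavelengths >= window[0]) & (table.wavelengths <= window[1])
    if not m.any():
        raise ValueError(f"no table wavelengths inside window {window}")
    diff = np.abs(table.eps_oxy[m] - table.eps_deoxy[m])
    return float(table.wavelengths[m][np.argmin(diff)])
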