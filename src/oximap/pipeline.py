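"""End-to-end pipeline: cubes -> segments -> OD -> saturation -> cohort table."""

from __future__ import annotations

import logging

import pandas as pd

from .hb_spectra import ExtinctionTable, load_reference_table
from .oximetry_core import OximetryModel, default_model, fit_so2
from .synthetic_fundus import CohortScenes, render_cube
from .vessel_extraction import (
    HyperspectralCube,
    assign_preset_roles,
    compute_od,
    detect_vessels,
    segments_from_truth,
)

__all__ = ["analyze_cube", "analyze_cohort"]

log = logging.getLogger(__name__)


def analyze_cube(
    cube: HyperspectralCube,
    extinction: ExtinctionTable | None = None,
    model: OximetryModel | None = None,
    use_truth_segments: bool = False,
    assign_roles: bool = True,
) -> pd.DataFrame:
    """Estimate per-segment saturation for one cube.

    Segments come from ridge/threshold detection (default) or from the
    generator's ground-truth labels (``use_truth_segments``). Detected
    segments are assigned artery/vein and temporal/nasal roles from the
    medullary-ray layout when ``assign_roles`` is set. Returns one row per
    segment: id, kind, region, so2_percent, residual, clipped, degenerate.
    """
    extinction = extinction or load_reference_table()
    model = model or default_model(cube.wavelengths, extinction=extinction)
    if use_truth_segments:
        segments = segments_from_truth(cube)
    else:
        segments = detect_vessels(cube)
        if assign_roles:
            assign_preset_roles(segments, cube.shape[:2])
    rows = []
    for seg in segments:
        res = fit_so2(compute_od(cube, seg), extinction, model)
        rows.append(
            {
                "segment_id": seg.id,
                "kind": seg.kind,
                "region": seg.region,
                "so2_percent": res.so2_percent,
                "residual": res.residual_norm,
                "clipped": res.clipped,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id", "kind", "region", "so2_percent",
            "residual", "clipped", "degenerate",
        ],
    )


def analyze_cohort(
    cohort: CohortScenes,
    extinction: ExtinctionTable | None = None,
    model: OximetryModel | None = None,
    use_truth_segments: bool = False,
) -> pd.DataFrame:
    """Render and analyze every scene of a cohort.

    Returns the measurements table (animal, timepoint, kind, region,
    so2_percent, ...) consumed by :mod:`oximap.study_stats`.
    """
    extinction = extinction or load_reference_table()
    model = model or default_model(cohort.bands, extinction=extinction)
    frames = []
    for (animal, timepoint), scene in cohort.scenes.items():
        cube = render_cube(scene, cohort.bands, extinction)
        df = analyze_cube(
            cube,
            extinction=extinction,
            model=model,
            use_truth_segments=use_truth_segments,
        )
        df.insert(0, "animal", animal)
        df.insert(1, "timepoint", timepoint)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
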