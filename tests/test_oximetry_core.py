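import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oximap.exceptions import DegeneracyError
from oximap.hb_spectra import ExtinctionTable, resample
from oximap.oximetry_core import (
    OximetryModel,
    default_model,
    fit_so2,
    select_fit_wavelengths,
    so2_map,
)
from oximap.synthetic_fundus import SceneSpec, VesselSpec, render_cube, medullary_ray_scene
from oximap.vessel_extraction import ODSpectrum, compute_od, segments_from_truth


def synthetic_od(extinction, lam, s, kappa=1.0, offset=0.0):
    """OD proportional to the s-mixture of the two extinction curves."""
    eps = resample(extinction, lam)
    return ODSpectrum(
        0, np.asarray(lam, float),
        kappa * (s * eps.eps_oxy + (1 - s) * eps.eps_deoxy) + offset,
    )


@pytest.fixture
def lam5(extinction, bands76):
    return select_fit_wavelengths(bands76, n=5, extinction=extinction)


class TestWavelengthSelection:
    def test_default_selection_returns_28(self, bands76, extinction):
        sel = select_fit_wavelengths(bands76, extinction=extinction)
        assert len(sel) == 28
        assert len(np.unique(sel)) == 28
        assert set(sel) <= set(bands76.wavelengths)

    def test_selection_count_equal_to_bands_returns_all(self, bands76, extinction):
        sel = select_fit_wavelengths(bands76, n=76, extinction=extinction)
        assert np.array_equal(sel, bands76.wavelengths)

    def test_selection_is_deterministic(self, bands76, extinction):
        a = select_fit_wavelengths(bands76, extinction=extinction)
        b = select_fit_wavelengths(bands76, extinction=extinction)
        assert np.array_equal(a, b)

    def test_selection_includes_isosbestic_anchors(self, bands76, extinction):
        """At least two nearly-isosbestic bands anchor the amplitude."""
        sel = select_fit_wavelengths(bands76, extinction=extinction)
        eps = resample(extinction, sel)
        rel_gap = np.abs(eps.eps_oxy - eps.eps_deoxy) / eps.eps_oxy
        assert (rel_gap < 0.1).sum() >= 2

    def test_more_wavelengths_than_bands_rejected(self, bands76, extinction):
        with pytest.raises(ValueError):
            select_fit_wavelengths(bands76, n=77, extinction=extinction)


class TestFitSO2:
    def test_pure_oxyhemoglobin(self, extinction, model28):
        od = synthetic_od(extinction, model28.fit_wavelengths, 1.0)
        res = fit_so2(od, extinction, model28)
        assert res.so2 == pytest.approx(1.0, abs=1e-9)
        assert res.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_pure_deoxyhemoglobin(self, extinction, model28):
        od = synthetic_od(extinction, model28.fit_wavelengths, 0.0)
        res = fit_so2(od, extinction, model28)
        assert res.so2 == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(kappa=st.floats(min_value=1e-3, max_value=1e3))
    def test_equal_mixture_is_half_for_any_amplitude(self, kappa):
        from oximap.hb_spectra import load_reference_table

        extinction = load_reference_table()
        model = default_model(np.linspace(450, 700, 76), extinction=extinction)
        od = synthetic_od(extinction, model.fit_wavelengths, 0.5, kappa=kappa)
        res = fit_so2(od, extinction, model)
        assert res.so2 == pytest.approx(0.5, abs=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        s=st.floats(min_value=0.0, max_value=1.0),
        kappa=st.floats(min_value=1e-2, max_value=1e2),
        offset=st.floats(min_value=-0.5, max_value=0.5),
    )
    def test_amplitude_and_offset_invariance(self, s, kappa, offset):
        """Scaling OD or adding a constant leaves the saturation ratio fixed."""
        from oximap.hb_spectra import load_reference_table

        extinction = load_reference_table()
        model = default_model(np.linspace(450, 700, 76), extinction=extinction)
        base = fit_so2(
            synthetic_od(extinction, model.fit_wavelengths, s), extinction, model
        )
        moved = fit_so2(
            synthetic_od(extinction, model.fit_wavelengths, s, kappa, offset),
            extinction, model,
        )
        assert moved.so2 == pytest.approx(base.so2, abs=1e-7)

    def test_estimate_strictly_increasing_in_truth(self, extinction, model28):
        s_grid = np.linspace(0, 1, 11)
        est = [
            fit_so2(
                synthetic_od(extinction, model28.fit_wavelengths, s), extinction, model28
            ).so2
            for s in s_grid
        ]
        assert np.all(np.diff(est) > 0)

    def test_noise_free_forward_inverse_roundtrip(self, extinction, bands76, model28):
        """A rendered vessel with in-class scatter inverts exactly."""
        v = VesselSpec(
            kind="vein", region="temporal",
            centerline=[(30, 10), (30, 80)], diameter_um=100, true_so2=0.714,
        )
        cube = render_cube(
            SceneSpec(shape=(60, 90), vessels=[v], noise_kind="none"),
            bands76, extinction,
        )
        (seg,) = segments_from_truth(cube)
        res = fit_so2(compute_od(cube, seg), extinction, model28)
        assert res.so2 == pytest.approx(0.714, abs=1e-6)

    def test_matches_normal_equations_oracle(self, extinction, lam5):
        """On a small problem the lstsq path equals an explicit normal-
        equations solve."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            od = synthetic_od(extinction, lam5, rng.uniform(0, 1), kappa=rng.uniform(0.5, 2))
            od.od += rng.normal(0, 0.01, size=len(lam5))
            model = OximetryModel(fit_wavelengths=lam5, scatter="linear")
            res = fit_so2(od, extinction, model)
            eps = resample(extinction, lam5)
            X = np.column_stack([
                eps.eps_oxy, eps.eps_deoxy,
                np.ones_like(lam5), (lam5 - lam5.mean()) / 100.0,
            ])
            beta = np.linalg.solve(X.T @ X, X.T @ od.od)
            assert res.coefficients["a"] == pytest.approx(beta[0], abs=1e-10)
            assert res.coefficients["b"] == pytest.approx(beta[1], abs=1e-10)

    def test_noisy_recovery_bias_under_two_points(self, extinction, bands76, model28):
        """Mean absolute saturation error stays below 0.02 at 1% illumination
        noise over 200 seeded replicates."""
        v = VesselSpec(
            kind="vein", region="temporal",
            centerline=[(30, 10), (30, 80)], diameter_um=100, true_so2=0.714,
        )
        errors = []
        for seed in range(200):
            cube = render_cube(
                SceneSpec(
                    shape=(60, 90), vessels=[v],
                    noise_kind="gaussian", noise_sigma=0.01, seed=seed,
                ),
                bands76, extinction,
            )
            (seg,) = segments_from_truth(cube)
            res = fit_so2(compute_od(cube, seg), extinction, model28)
            errors.append(abs(res.so2 - 0.714))
        assert np.mean(errors) <= 0.02

    def test_isosbestic_only_design_is_degenerate(self, model28):
        lam = np.linspace(500, 600, 30)
        eps = np.linspace(3e4, 5e4, 30)
        flat = ExtinctionTable(lam, eps, eps)  # oxy == deoxy everywhere
        od = ODSpectrum(0, model28.fit_wavelengths, np.full(28, 0.5))
        with pytest.raises(DegeneracyError):
            fit_so2(od, flat, model28)

    def test_negative_amplitude_flagged_degenerate(self, extinction, model28):
        od = synthetic_od(extinction, model28.fit_wavelengths, 0.5, kappa=-1.0)
        res = fit_so2(od, extinction, model28)
        assert res.degenerate
        assert np.isnan(res.so2)

    def test_raw_clipping_policy_reports_unclipped(self, extinction, model28):
        eps = resample(extinction, model28.fit_wavelengths)
        od = ODSpectrum(
            0, model28.fit_wavelengths, 1.1 * eps.eps_oxy - 0.1 * eps.eps_deoxy
        )
        raw_model = OximetryModel(
            fit_wavelengths=model28.fit_wavelengths, clipping="raw"
        )
        res = fit_so2(od, extinction, raw_model)
        assert res.clipped and res.so2 > 1.0
        clip_res = fit_so2(od, extinction, model28)
        assert clip_res.so2 == 1.0 and clip_res.clipped


class TestSaturationMap:
    def test_segment_value_painted_on_all_vessel_pixels(self, clean_cube, extinction, model28):
        segs = segments_from_truth(clean_cube)
        smap = so2_map(clean_cube, segs, extinction, model28)
        for seg in segs:
            vals = smap[seg.vessel_pixels]
            assert np.allclose(vals, vals[0])
            assert vals[0] == pytest.approx(seg.true_so2, abs=1e-6)

    def test_empty_segment_list_gives_all_sentinel(self, clean_cube, extinction, model28):
        smap = so2_map(clean_cube, [], extinction, model28)
        assert np.isnan(smap).all()

    def test_extreme_saturations_paint_exact_values(self, bands76, extinction, model28):
        scene = medullary_ray_scene(
            {
                ("artery", "temporal"): 1.0, ("vein", "temporal"): 0.0,
                ("artery", "nasal"): 1.0, ("vein", "nasal"): 0.0,
            },
            noise_kind="none",
        )
        cube = render_cube(scene, bands76, extinction)
        smap = so2_map(cube, segments_from_truth(cube), extinction, model28)
        finite = smap[np.isfinite(smap)]
        assert set(np.round(finite, 9)) == {0.0, 1.0}

    def test_per_pixel_mode_agrees_on_noise_free_scene(self, clean_cube, extinction, model28):
        segs = segments_from_truth(clean_cube)[:1]
        seg_map = so2_map(clean_cube, segs, extinction, model28)
        pix_map = so2_map(clean_cube, segs, extinction, model28, per_pixel=True)
        m = np.isfinite(seg_map)
        assert np.allclose(pix_map[m], seg_map[m], atol=1e-6)
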