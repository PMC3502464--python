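import numpy as np
import pandas as pd
import pytest

from oximap.exceptions import GeometryError
from oximap.hb_spectra import resample
from oximap.synthetic_fundus import (
    CohortSpec,
    SceneSpec,
    VesselSpec,
    make_band_grid,
    make_rvo_cohort,
    medullary_ray_scene,
    render_cube,
    rvo_baseline_cohort,
    vessel_exponent,
)
from oximap.vessel_extraction import compute_od, segments_from_truth


def straight_vessel(so2=0.7, diameter=100.0, **kw):
    return VesselSpec(
        kind="vein",
        region="temporal",
        centerline=[(30, 10), (30, 80)],
        diameter_um=diameter,
        true_so2=so2,
        **kw,
    )


class TestBandGrid:
    def test_default_76_bands_spanning_450_700(self):
        g = make_band_grid(450, 700, 76)
        assert len(g) == 76
        assert g.wavelengths[0] == 450.0 and g.wavelengths[-1] == 700.0

    def test_spacing_is_range_over_intervals(self):
        g = make_band_grid(450, 700, 76)
        assert np.allclose(np.diff(g.wavelengths), 250.0 / 75.0)

    def test_two_point_grid(self):
        g = make_band_grid(500.0, 503.5, 2)
        assert np.array_equal(g.wavelengths, [500.0, 503.5])

    @pytest.mark.parametrize("args", [(700, 450, 10), (450, 700, 1)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            make_band_grid(*args)


class TestRenderCube:
    def test_no_vessels_gives_flat_background(self, bands76, extinction):
        scene = SceneSpec(shape=(20, 30), vessels=[], noise_kind="none")
        cube = render_cube(scene, bands76, extinction)
        expected = scene.illumination * scene.background_reflectance
        assert np.allclose(cube.intensities, expected, rtol=0, atol=0)

    def test_zero_hemoglobin_and_zero_scatter_is_invisible(self, bands76, extinction):
        v = straight_vessel(hb_concentration=0.0, scatter_offset=0.0, scatter_slope=0.0)
        scene = SceneSpec(shape=(60, 90), vessels=[v], noise_kind="none")
        cube = render_cube(scene, bands76, extinction)
        assert np.allclose(cube.intensities, cube.intensities[0, 0, :], rtol=0, atol=1e-15)

    def test_noise_free_od_matches_analytic_exponent(self, bands76, extinction):
        v = straight_vessel()
        scene = SceneSpec(shape=(60, 90), vessels=[v], noise_kind="none")
        cube = render_cube(scene, bands76, extinction)
        (seg,) = segments_from_truth(cube)
        od = compute_od(cube, seg)
        assert np.allclose(od.od, vessel_exponent(v, bands76, extinction), atol=1e-9)

    def test_same_seed_bit_identical_different_seed_differs(self, bands76, extinction):
        mk = lambda seed: render_cube(
            SceneSpec(shape=(60, 90), vessels=[straight_vessel()], seed=seed),
            bands76,
            extinction,
        ).intensities
        assert np.array_equal(mk(5), mk(5))
        assert not np.array_equal(mk(5), mk(6))

    def test_attenuation_is_monotone(self, bands76, extinction):
        """Noise-free intensities stay in (0, illumination]; more absorber
        never brightens any band."""
        scenes = [
            SceneSpec(
                shape=(60, 90),
                vessels=[straight_vessel(hb_concentration=c)],
                noise_kind="none",
            )
            for c in (1e-3, 2e-3)
        ]
        lo, hi = (render_cube(s, bands76, extinction) for s in scenes)
        assert lo.intensities.min() > 0
        assert lo.intensities.max() <= scenes[0].illumination
        assert np.all(hi.intensities <= lo.intensities + 1e-15)

    def test_isosbestic_od_independent_of_saturation(self, extinction):
        """Where eps_oxy == eps_deoxy the vessel OD cannot depend on s."""
        from oximap.hb_spectra import isosbestic_wavelength

        iso = isosbestic_wavelength(extinction)
        bands = make_band_grid(iso - 50, iso + 50, 5)  # includes iso at center
        assert iso in bands.wavelengths
        j = list(bands.wavelengths).index(iso)
        eps = resample(extinction, [iso])
        assert eps.eps_oxy[0] == eps.eps_deoxy[0]
        e_low = vessel_exponent(straight_vessel(so2=0.1), bands, extinction)
        e_high = vessel_exponent(straight_vessel(so2=0.9), bands, extinction)
        assert e_low[j] == pytest.approx(e_high[j], abs=1e-12)
        assert abs(e_low[0] - e_high[0]) > 1e-3  # non-isosbestic bands do differ

    def test_vessel_outside_bounds_is_geometry_error(self, bands76, extinction):
        v = VesselSpec(
            kind="vein", region="nasal",
            centerline=[(10, 10), (10, 500)], diameter_um=100, true_so2=0.5,
        )
        with pytest.raises(GeometryError):
            render_cube(SceneSpec(shape=(40, 60), vessels=[v]), bands76, extinction)

    def test_sub_resolution_vessels_rejected(self):
        with pytest.raises(ValueError):
            straight_vessel(diameter=30.0)


class TestRvoCohort:
    def test_zero_delta_keeps_truth_identical_across_timepoints(self):
        spec = rvo_baseline_cohort(n_animals=4, fixed=True, seed=1)
        spec.occlusion_deltas = {}
        truth = make_rvo_cohort(spec).truth
        wide = truth.pivot_table(
            index=["animal", "kind", "region"], columns="timepoint", values="true_so2"
        )
        assert np.allclose(wide["baseline"], wide["1h"])

    def test_recannulation_restores_baseline_truth(self):
        spec = CohortSpec(
            n_animals=3,
            timepoints=("baseline", "1h", "2wk"),
            occlusion_deltas={"1h": {"vein": -0.074}, "2wk": {"vein": -0.074}},
            recannulation_timepoint="2wk",
            seed=9,
        )
        truth = make_rvo_cohort(spec).truth
        tv = truth[(truth.kind == "vein") & (truth.region == "temporal")]
        wide = tv.pivot_table(index="animal", columns="timepoint", values="true_so2")
        assert np.allclose(wide["2wk"], wide["baseline"], atol=0)
        assert (wide["1h"] < wide["baseline"]).all()

    def test_fixed_assignments_give_identical_animals(self):
        cohort = make_rvo_cohort(rvo_baseline_cohort(n_animals=20, fixed=True, seed=0))
        per_animal = cohort.truth.pivot_table(
            index="animal", columns=["timepoint", "kind", "region"], values="true_so2"
        )
        assert len(per_animal) == 20
        assert (per_animal.nunique(axis=0) == 1).all()

    def test_occlusion_applies_only_to_temporal_side(self):
        truth = make_rvo_cohort(rvo_baseline_cohort(n_animals=5, fixed=True)).truth
        wide = truth.pivot_table(
            index=["kind", "region"], columns="timepoint", values="true_so2"
        )
        diff = wide["baseline"] - wide["1h"]
        assert diff.loc[("vein", "temporal")] == pytest.approx(0.074)
        assert diff.loc[("artery", "temporal")] == pytest.approx(0.045)
        assert diff.loc[("vein", "nasal")] == 0.0
        assert diff.loc[("artery", "nasal")] == 0.0

    def test_cohort_is_seed_deterministic(self):
        t1 = make_rvo_cohort(rvo_baseline_cohort(n_animals=3, seed=11)).truth
        t2 = make_rvo_cohort(rvo_baseline_cohort(n_animals=3, seed=11)).truth
        pd.testing.assert_frame_equal(t1, t2)
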