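"""Generator contracts: seeded determinism, conservation, zero-noise exactness."""

import numpy as np
import pytest

from lentikit.strain_relaxation import (
    compute_strains,
    punch_area_mm2,
    strain_exc_iso,
    strain_extr,
)
from lentikit.synthetic_data import (
    SceneSpec,
    generate_growth_series,
    generate_lenticel_core_pairs,
    generate_russet_population,
    generate_strain_samples,
    generate_surface_scene,
    logistic_area,
)


class TestSurfaceScene:
    def test_empty_scene(self):
        spec = SceneSpec(lenticel_frequency_per_mm2=0.0, seed=1)
        bf, fl, truth = generate_surface_scene(spec)
        assert truth.count == 0
        # background only: bright-field stays bright, fluorescence stays dark
        assert bf.pixels.min() > 0.7
        assert fl.pixels.max() < 0.1

    def test_seeded_determinism(self):
        spec = SceneSpec(lenticel_frequency_per_mm2=0.1, seed=42)
        first = generate_surface_scene(spec)
        second = generate_surface_scene(spec)
        assert np.array_equal(first[0].pixels, second[0].pixels)
        assert np.array_equal(first[1].pixels, second[1].pixels)
        assert first[2] == second[2]

    def test_planted_count_matches_density(self):
        spec = SceneSpec(
            lenticel_frequency_per_mm2=0.5,
            core_area_mean_mm2=0.03,
            halo_fraction=0.2,
            seed=3,
        )
        _, _, truth = generate_surface_scene(spec)
        assert truth.count == round(0.5 * spec.field_area_mm2) == 50
        assert truth.frequency_per_mm2 == pytest.approx(0.5)

    def test_truth_conservation(self, default_scene):
        _, _, _, truth = default_scene
        frame = truth.to_frame()
        assert len(frame) == truth.count
        planted_halo = sum(
            l.halo_area_mm2 for l in truth.lenticels if l.halo_area_mm2
        )
        assert frame["halo_area_mm2"].sum() == pytest.approx(planted_halo)
        for l in truth.lenticels:
            assert 0 < l.pore_area_mm2 < l.core_area_mm2

    def test_no_overlap(self, default_scene):
        _, _, _, truth = default_scene
        ls = truth.lenticels
        for i in range(len(ls)):
            for j in range(i + 1, len(ls)):
                d = np.hypot(ls[i].x_mm - ls[j].x_mm, ls[i].y_mm - ls[j].y_mm)
                r_i = np.sqrt(ls[i].core_area_mm2 * ls[i].aspect / np.pi)
                r_j = np.sqrt(ls[j].core_area_mm2 * ls[j].aspect / np.pi)
                assert d > r_i + r_j

    def test_overcrowded_field_errors(self):
        spec = SceneSpec(
            field_width_mm=3,
            field_height_mm=3,
            lenticel_frequency_per_mm2=5.0,
            core_area_mean_mm2=0.5,
            seed=0,
        )
        with pytest.raises(ValueError, match="crowded"):
            generate_surface_scene(spec)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scale_um_per_px": 0.0},
            {"halo_fraction": 1.5},
            {"pore_to_core_ratio": 1.0},
            {"background_noise_sd": -0.1},
        ],
    )
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ValueError):
            SceneSpec(**kwargs)


class TestGrowthSeries:
    def test_noiseless_series_is_exact_logistic(self):
        series = generate_growth_series(400, 0.04, 100, [60, 100, 140, 500])
        areas = dict(series)
        assert areas[100] == pytest.approx(200.0, abs=1e-12)
        assert areas[500] == pytest.approx(400.0, rel=1e-6)
        for t, a in series:
            assert a == pytest.approx(float(logistic_area(t, 400, 0.04, 100)))

    def test_noise_is_seeded(self):
        kwargs = dict(times=range(20, 180, 10), noise_sd=5.0, seed=9)
        assert generate_growth_series(400, 0.04, 100, **kwargs) == (
            generate_growth_series(400, 0.04, 100, **kwargs)
        )

    def test_negative_noise_errors(self):
        with pytest.raises(ValueError):
            generate_growth_series(400, 0.04, 100, [1, 2], noise_sd=-1)


class TestStrainSamples:
    def test_zero_cv_round_trip_is_exact(self):
        for s in generate_strain_samples(12.6, 28.1, cv=0.0, n=5, seed=0):
            assert strain_exc_iso(s) == pytest.approx(12.6, abs=1e-12)
            assert strain_extr(s) == pytest.approx(28.1, abs=1e-12)

    def test_zero_strain_gives_equal_areas(self):
        (s,) = generate_strain_samples(0.0, 0.0, cv=0.0, n=1, seed=0)
        assert s.a_initial_mm2 == pytest.approx(s.a_cm_mm2)
        assert s.a_cm_mm2 == pytest.approx(s.a_dcm_mm2)
        assert s.a_initial_mm2 == pytest.approx(punch_area_mm2(8.0))

    def test_sample_means_close_to_truth_under_noise(self):
        samples = generate_strain_samples(12.6, 28.1, cv=0.05, n=1000, seed=1)
        e1 = np.array([strain_exc_iso(s) for s in samples])
        e2 = np.array([strain_extr(s) for s in samples])
        for vals, truth in ((e1, 12.6), (e2, 28.1)):
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth) < 3 * se

    def test_nonpositive_punch_errors(self):
        with pytest.raises(ValueError):
            generate_strain_samples(10, 10, punch_diameter_mm=0.0)


class TestLenticelCorePairs:
    def test_noiseless_pairs_lie_on_slope(self):
        pairs = generate_lenticel_core_pairs(n=10, slope=0.74, noise_sd_mm2=0.0, seed=2)
        for p in pairs:
            assert p.a_core_dewaxed_mm2 == pytest.approx(0.74 * p.a_core_isolated_mm2)


class TestRussetPopulation:
    def test_degenerate_population_is_all_zero(self):
        assert generate_russet_population(0.0, 0.0, 10, seed=0) == [0.0] * 10

    def test_seeded_and_bounded(self):
        a = generate_russet_population(30, 15, 200, seed=5)
        b = generate_russet_population(30, 15, 200, seed=5)
        assert a == b
        assert all(0 <= f <= 100 for f in a)

    def test_negative_sd_errors(self):
        with pytest.raises(ValueError):
            generate_russet_population(30, -1, 10)
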