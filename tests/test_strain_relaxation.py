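"""Apparent-strain calculus: worked values, additivity, scale invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lentikit.strain_relaxation import (
    LenticelStrainSample,
    StrainSample,
    compare_groups,
    compute_strains,
    dcm_area_from_holes,
    strain_exc_iso,
    strain_extr,
    strain_lenticel,
    strain_total,
)
from lentikit.synthetic_data import (
    generate_lenticel_core_pairs,
    generate_strain_samples,
)

areas = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestHolePattern:
    def test_equal_holes_no_relaxation(self):
        assert dcm_area_from_holes(1.2, 0.5, 0.5) == pytest.approx(1.2)

    def test_hole_ratio_scales_area(self):
        assert dcm_area_from_holes(1.20, 1.0, 0.80) == pytest.approx(0.96)

    def test_half_ratio_gives_100pct_extraction_strain(self):
        s = StrainSample(
            a_initial_mm2=2.0, a_cm_mm2=2.0, holes_cm_mm2=1.0, holes_dcm_mm2=0.5
        )
        assert strain_extr(s) == pytest.approx(100.0)

    def test_nonpositive_input_errors(self):
        with pytest.raises(ValueError):
            dcm_area_from_holes(1.0, 0.0, 0.5)


class TestStrainComponents:
    def test_no_shrinkage_no_strain(self):
        s = StrainSample(46.0, 46.0, 40.0)
        assert strain_exc_iso(s) == 0.0
        s2 = StrainSample(50.0, 40.0, 40.0)
        assert strain_extr(s2) == 0.0

    def test_worked_example(self):
        s = StrainSample(50.27, 46.0, 40.0)
        assert strain_exc_iso(s) == pytest.approx(10.675, abs=1e-3)
        assert strain_extr(s) == pytest.approx(15.0, abs=1e-12)

    def test_generator_round_trip(self):
        for s in generate_strain_samples(12.6, 28.1, cv=0.0, n=3, seed=0):
            assert strain_exc_iso(s) == pytest.approx(12.6, abs=1e-12)
            assert strain_extr(s) == pytest.approx(28.1, abs=1e-12)

    def test_total_is_component_sum(self):
        assert strain_total(12.6, 28.1) == pytest.approx(40.7, abs=1e-12)
        assert strain_total(0.0, 0.0) == 0.0

    def test_negative_strain_not_clamped(self):
        s = StrainSample(40.0, 46.0, 45.0)  # disc grew on isolation
        assert strain_exc_iso(s) < 0

    def test_nonpositive_dcm_errors(self):
        s = StrainSample(50.0, 46.0, -1.0)
        with pytest.raises(ValueError):
            strain_exc_iso(s)


class TestAlgebraicProperties:
    @given(a=areas, a_cm=areas, a_dcm=areas)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_additivity_identity(self, a, a_cm, a_dcm):
        s = StrainSample(a, a_cm, a_dcm)
        res = compute_strains(s)
        direct = (a - a_dcm) / a_dcm * 100.0
        assert res.eps_tot_pct == pytest.approx(direct, rel=1e-12, abs=1e-9)

    @given(a=areas, a_cm=areas, a_dcm=areas, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_scale_invariance(self, a, a_cm, a_dcm, c):
        base = compute_strains(StrainSample(a, a_cm, a_dcm))
        scaled = compute_strains(StrainSample(c * a, c * a_cm, c * a_dcm))
        assert scaled.eps_exc_iso_pct == pytest.approx(base.eps_exc_iso_pct, rel=1e-9, abs=1e-9)
        assert scaled.eps_extr_pct == pytest.approx(base.eps_extr_pct, rel=1e-9, abs=1e-9)

    def test_zero_strain_fixed_point(self):
        res = compute_strains(StrainSample(5.0, 5.0, 5.0))
        assert res.eps_exc_iso_pct == res.eps_extr_pct == res.eps_tot_pct == 0.0


class TestLenticelStrain:
    def test_equal_areas_zero(self):
        assert strain_lenticel(LenticelStrainSample(0.5, 0.5)) == 0.0

    def test_worked_example(self):
        assert strain_lenticel(LenticelStrainSample(0.60, 0.50)) == pytest.approx(20.0)

    def test_proportional_shrinkage_mean_strain(self):
        # dewaxed = 0.74 x isolated with zero intercept => strain (1/0.74 - 1)*100
        pairs = generate_lenticel_core_pairs(n=50, slope=0.74, noise_sd_mm2=0.0, seed=1)
        strains = [strain_lenticel(p) for p in pairs]
        assert np.mean(strains) == pytest.approx((1 / 0.74 - 1) * 100, rel=1e-9)


class TestCompareGroups:
    def test_identical_groups_unit_ratio(self):
        samples = generate_strain_samples(10, 20, cv=0, n=3, seed=0, has_lenticels=True)
        samples += generate_strain_samples(10, 20, cv=0, n=3, seed=0, has_lenticels=False)
        table = compare_groups(samples)
        row = table.loc["ratio_with_over_without"]
        assert row["eps_tot_pct_mean"] == pytest.approx(1.0)

    def test_group_truth_ratio(self):
        samples = generate_strain_samples(12.6, 28.1, cv=0, n=5, seed=0, has_lenticels=True)
        samples += generate_strain_samples(8.5, 15.8, cv=0, n=5, seed=0, has_lenticels=False)
        table = compare_groups(samples)
        assert table.loc["with_lenticels", "eps_tot_pct_mean"] == pytest.approx(40.7)
        assert table.loc["without_lenticels", "eps_tot_pct_mean"] == pytest.approx(24.3)
        assert table.loc["ratio_with_over_without", "eps_tot_pct_mean"] == pytest.approx(
            40.7 / 24.3, rel=1e-9
        )

    def test_noisy_groups_recover_truth(self):
        samples = generate_strain_samples(12.6, 28.1, cv=0.05, n=30, seed=3, has_lenticels=True)
        samples += generate_strain_samples(8.5, 15.8, cv=0.05, n=30, seed=4, has_lenticels=False)
        table = compare_groups(samples)
        for group, truth in (("with_lenticels", 40.7), ("without_lenticels", 24.3)):
            mean = table.loc[group, "eps_tot_pct_mean"]
            se = table.loc[group, "eps_tot_pct_se"]
            assert abs(mean - truth) < 3 * se

    def test_missing_group_errors(self):
        samples = generate_strain_samples(10, 20, cv=0, n=4, seed=0, has_lenticels=True)
        with pytest.raises(ValueError, match="without_lenticels"):
            compare_groups(samples)
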