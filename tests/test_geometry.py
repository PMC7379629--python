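"""Field sizing: FWHM, centre finding, equivalent square, central ROI dose."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smallfield as sf
from smallfield.errors import BoundsError, DegenerateFieldError


def make_gaussian_map(center=(0.0, 0.0), sigma=3.0, pitch=0.1, n=150, peak=2.0):
    coords = pitch * np.arange(-n, n + 1)
    xx, yy = np.meshgrid(coords, coords)
    vals = peak * np.exp(-(((xx - center[0]) ** 2 + (yy - center[1]) ** 2)
                           / (2 * sigma**2)))
    return sf.DoseMap2D(values=vals, spacing_x=pitch, spacing_y=pitch)


class TestFWHM:
    def test_rectangular_profile_width(self):
        pos = np.arange(-10.0, 10.01, 0.1)
        vals = np.where(np.abs(pos) <= 3.0, 5.0, 0.0)
        w = sf.fwhm(sf.DoseProfile(pos, vals))
        assert w == pytest.approx(6.0, abs=0.1)

    def test_gaussian_profile_matches_analytic(self):
        pos = np.arange(-15.0, 15.01, 0.1)
        vals = np.exp(-(pos**2) / (2 * 3.0**2))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 3.0
        assert sf.fwhm(sf.DoseProfile(pos, vals)) == pytest.approx(
            expected, rel=0.005)

    def test_triangular_profile_half_width(self):
        # peak D at 0, linear to zero at +-w: half-max crossings at +-w/2
        w = 8.0
        pos = np.arange(-w, w + 0.01, 0.05)
        vals = np.maximum(0.0, 1.0 - np.abs(pos) / w)
        assert sf.fwhm(sf.DoseProfile(pos, vals)) == pytest.approx(w, abs=0.05)

    def test_monotone_profile_raises(self):
        pos = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(DegenerateFieldError):
            sf.fwhm(sf.DoseProfile(pos, pos.copy()))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_positive_scaling(self, scale):
        pos = np.arange(-15.0, 15.01, 0.1)
        vals = np.exp(-(pos**2) / (2 * 2.5**2))
        base = sf.fwhm(sf.DoseProfile(pos, vals))
        scaled = sf.fwhm(sf.DoseProfile(pos, vals * scale))
        assert scaled == pytest.approx(base, rel=1e-12)


class TestLocateFieldCenter:
    def test_symmetric_field_centred_at_origin(self):
        cx, cy = sf.locate_field_center(make_gaussian_map())
        assert abs(cx) < 0.01 and abs(cy) < 0.01

    def test_translated_field_recovers_offset(self):
        m = sf.simulate_dose_map(1.0, 1.9, pitch_mm=0.1)
        shifted = sf.DoseMap2D(values=m.values, spacing_x=0.1, spacing_y=0.1,
                               origin=(m.origin[0] + 1.3, m.origin[1] - 0.7))
        cx, cy = sf.locate_field_center(shifted)
        assert cx == pytest.approx(1.3, abs=0.02)
        assert cy == pytest.approx(-0.7, abs=0.02)

    def test_uniform_map_is_degenerate(self):
        m = sf.DoseMap2D(values=np.ones((21, 21)), spacing_x=0.5, spacing_y=0.5)
        with pytest.raises(DegenerateFieldError):
            sf.locate_field_center(m)

    @pytest.mark.parametrize("nominal_cm", [0.5, 1.0, 3.0, 10.0])
    def test_recentred_fwhm_matches_construction(self, nominal_cm):
        # centre finding + FWHM reproduces the model's analytic width
        sigma = 1.9
        pitch = 0.25
        m = sf.simulate_dose_map(nominal_cm, sigma, pitch_mm=pitch)
        cx, cy = sf.locate_field_center(m)
        measured = sf.fwhm(m.profile_x(cy))
        expected = sf.analytic_fwhm(nominal_cm * 10.0, sigma)
        assert measured == pytest.approx(expected, abs=pitch)


class TestEquivalentSquare:
    def test_known_values(self):
        assert sf.equivalent_square(2.0, 2.0) == pytest.approx(2.0)
        assert sf.equivalent_square(0.5, 0.72) == pytest.approx(0.6)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            sf.equivalent_square(0.0, 1.0)

    @given(a=st.floats(min_value=0.1, max_value=20.0),
           b=st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=50, deadline=None)
    def test_geometric_mean_and_symmetry(self, a, b):
        import math
        assert sf.equivalent_square(a, b) == pytest.approx(math.sqrt(a * b))
        assert sf.equivalent_square(a, b) == sf.equivalent_square(b, a)
        assert sf.equivalent_square(a, a) == pytest.approx(a)


class TestCentralROIDose:
    def test_uniform_map_returns_dose_and_zero_sd(self):
        m = sf.DoseMap2D(values=np.full((51, 51), 3.5), spacing_x=0.2,
                         spacing_y=0.2)
        mean, sd = sf.central_roi_dose(m, (0.0, 0.0), diameter=0.5)
        assert mean == pytest.approx(3.5)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_roi_mean_bounded_by_extremes(self):
        m = make_gaussian_map(sigma=3.0, peak=2.0)
        mean, _ = sf.central_roi_dose(m, (0.0, 0.0), diameter=0.5)
        lower = 2.0 * np.exp(-(0.25**2) / (2 * 9.0))
        assert lower <= mean <= 2.0

    def test_coarse_grid_triggers_resampling(self):
        # 1 mm pitch leaves a single pixel inside a 0.5 mm ROI
        m = make_gaussian_map(sigma=3.0, pitch=1.0, n=15)
        mean, sd = sf.central_roi_dose(m, (0.0, 0.0), diameter=0.5)
        assert 1.9 < mean <= 2.0
        assert sd >= 0.0

    def test_roi_larger_than_map_is_bounds_error(self):
        m = make_gaussian_map(n=10, pitch=0.1)
        with pytest.raises(BoundsError):
            sf.central_roi_dose(m, (0.0, 0.0), diameter=10.0)


class TestDoseMapInvariants:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            sf.DoseMap2D(values=np.ones((2, 5)), spacing_x=0.1, spacing_y=0.1)
        with pytest.raises(ValueError):
            sf.DoseMap2D(values=np.ones((5, 5)), spacing_x=-0.1, spacing_y=0.1)
        with pytest.raises(ValueError):
            sf.DoseMap2D(values=-np.ones((5, 5)), spacing_x=0.1, spacing_y=0.1)

    def test_field_size_geometric_mean_invariant(self):
        fs = sf.FieldSize(A=0.5, B=0.72)
        assert fs.s_clin == pytest.approx(0.6, abs=1e-9)
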