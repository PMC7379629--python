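"""Volume-averaging corrections: Gaussian fits, closed form vs quadrature."""

import numpy as np
import pytest

import smallfield as sf
from smallfield.errors import FitError


def leggauss_kvol(d, b, c, order=80):
    """Independent oracle: 2D Gauss-Legendre quadrature of the Gaussian over
    the centred d x d square, numerator d^2 (amplitude cancels)."""
    x, w = np.polynomial.legendre.leggauss(order)
    h = d / 2.0
    xs = h * x
    wx = h * w
    gx = np.exp(-0.5 * (xs / b) ** 2)
    gy = np.exp(-0.5 * (xs / c) ** 2)
    integral = (wx @ gx) * (wx @ gy)
    return d**2 / integral


def make_gaussian_map(a=2.0, b=3.0, c=4.0, pitch=0.1, n=40, rng=None,
                      noise=0.0):
    coords = pitch * np.arange(-n, n + 1)
    xx, yy = np.meshgrid(coords, coords)
    vals = a * np.exp(-0.5 * ((xx / b) ** 2 + (yy / c) ** 2))
    if noise:
        vals = vals * (1.0 + noise * rng.standard_normal(vals.shape))
    return sf.DoseMap2D(values=vals, spacing_x=pitch, spacing_y=pitch)


class TestFitCentralGaussian:
    def test_exact_gaussian_recovered(self):
        m = make_gaussian_map(a=2.0, b=3.0, c=4.0)
        fit = sf.fit_central_gaussian(m, (0.0, 0.0))
        assert fit.a == pytest.approx(2.0, rel=1e-6)
        assert fit.b == pytest.approx(3.0, rel=1e-6)
        assert fit.c == pytest.approx(4.0, rel=1e-6)

    def test_noisy_gaussian_recovered_within_2pct(self):
        rng = np.random.default_rng(42)
        m = make_gaussian_map(a=2.0, b=3.0, c=4.0, rng=rng, noise=0.005)
        fit = sf.fit_central_gaussian(m, (0.0, 0.0))
        assert fit.a == pytest.approx(2.0, rel=0.02)
        assert fit.b == pytest.approx(3.0, rel=0.02)
        assert fit.c == pytest.approx(4.0, rel=0.02)
        assert fit.residual_rms > 0

    def test_uniform_region_is_fit_error(self):
        m = sf.DoseMap2D(values=np.full((61, 61), 2.0), spacing_x=0.1,
                         spacing_y=0.1)
        with pytest.raises(FitError):
            sf.fit_central_gaussian(m, (0.0, 0.0))


class TestEquivalentDetectorSide:
    @pytest.mark.parametrize("name, expected_d", [
        ("W1 PSD", 0.8862),          # r = 0.5 mm fibre
        ("SN EDGE Detector", 0.8),   # square chip, side unchanged
        ("EBT3 ROI", 0.4431),        # 0.5 mm diameter analysis ROI
        ("PTW 60012 Diode E", 1.0635),
        ("PTW 60019 mD", 1.9497),  # 1.1 * sqrt(pi)
    ])
    def test_equal_area_square_sides(self, name, expected_d):
        from smallfield.beams import detector
        d = sf.equivalent_detector_side(detector(name))
        assert d == pytest.approx(expected_d, abs=1e-4)

    def test_rejects_unknown_shape(self):
        with pytest.raises(ValueError):
            sf.DetectorGeometry("bad", "hexagonal", 1.0)


class TestKvol:
    def test_small_detector_limit_is_unity(self):
        fit = sf.BivariateGaussianFit(a=1.0, b=3.0, c=3.0)
        assert sf.kvol_closed_form(1e-4, fit) == pytest.approx(1.0, abs=1e-8)

    def test_w1_on_3mm_gaussian(self):
        fit = sf.BivariateGaussianFit(a=1.0, b=3.0, c=3.0)
        k = sf.kvol_closed_form(0.8862, fit)
        assert k == pytest.approx(leggauss_kvol(0.8862, 3.0, 3.0), rel=1e-6)
        assert k == pytest.approx(1.0077, abs=5e-4)

    def test_symmetric_under_bc_swap(self):
        f1 = sf.BivariateGaussianFit(a=1.0, b=2.0, c=5.0)
        f2 = sf.BivariateGaussianFit(a=1.0, b=5.0, c=2.0)
        assert sf.kvol_closed_form(1.0, f1) == sf.kvol_closed_form(1.0, f2)

    def test_closed_form_matches_quadrature_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            d = rng.uniform(0.2, 3.0)
            b = rng.uniform(0.5, 10.0)
            c = rng.uniform(0.5, 10.0)
            fit = sf.BivariateGaussianFit(a=rng.uniform(0.5, 3.0), b=b, c=c)
            closed = sf.kvol_closed_form(d, fit)
            assert closed == pytest.approx(leggauss_kvol(d, b, c), rel=1e-6)
            assert closed >= 1.0 - 1e-9

    def test_numeric_path_agrees_with_closed_form(self):
        fit = sf.BivariateGaussianFit(a=1.0, b=1.0, c=1.0)
        assert sf.kvol_numeric(1.0, fit) == pytest.approx(
            sf.kvol_closed_form(1.0, fit), rel=1e-9)
        wide = sf.BivariateGaussianFit(a=1.0, b=500.0, c=500.0)
        assert sf.kvol_numeric(1.0, wide) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_d_and_in_scales(self):
        fit = sf.BivariateGaussianFit(a=1.0, b=3.0, c=3.0)
        ds = np.linspace(0.2, 3.0, 15)
        ks = [sf.kvol_closed_form(d, fit) for d in ds]
        assert np.all(np.diff(ks) > 0)
        bs = np.linspace(1.0, 10.0, 15)
        ks_b = [sf.kvol_closed_form(1.5, sf.BivariateGaussianFit(1.0, b, 3.0))
                for b in bs]
        assert np.all(np.diff(ks_b) < 0)

    def test_detector_ordering_by_footprint(self):
        # EBT3 ROI < EDGE <= W1 < 1.2 mm diodes < microdiamond
        from smallfield.beams import detector
        fit = sf.BivariateGaussianFit(a=1.0, b=2.8, c=3.1)
        names = ["EBT3 ROI", "SN EDGE Detector", "W1 PSD",
                 "PTW 60012 Diode E", "PTW 60019 mD"]
        ks = [sf.kvol_closed_form(detector(n).equivalent_side_d, fit)
              for n in names]
        for lo, hi in zip(ks, ks[1:]):
            assert lo <= hi + 1e-12
        assert ks[0] < ks[-1]

    def test_no_volume_averaging_at_2cm_and_above(self):
        # simulated fields >= 2 cm: k_vol rounds to 1.000 for every detector
        from smallfield.beams import DETECTORS
        for nominal in (2.0, 5.0):
            m = sf.simulate_dose_map(nominal, 1.9, pitch_mm=0.25)
            try:
                fit = sf.fit_central_gaussian(m, (0.0, 0.0))
            except FitError:
                continue  # flat centre: no volume averaging at all
            for geom in DETECTORS:
                k = sf.kvol_closed_form(geom.equivalent_side_d, fit)
                assert round(k, 3) == 1.000
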