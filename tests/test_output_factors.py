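"""Sauer-Wilbert output-factor model: evaluation, fitting, tabulation."""

import numpy as np
import pytest

import smallfield as sf
from smallfield.beams import MEASURED_SCLIN, REFERENCE_CURVES
from smallfield.errors import CoverageError

ELEKTA_6WFF = REFERENCE_CURVES[("Elekta Versa HD", "6 MV WFF")]


def synthetic_points(params, s_values, noise=0.0, sd=0.005, seed=0,
                     n_repeats=3):
    """Corrected readings generated from a known curve for both detectors.

    Each point is the mean of ``n_repeats`` noisy readings, matching the
    three-measurements-per-field protocol of a real campaign.
    """
    rng = np.random.default_rng(seed)
    pts = []
    for det in ("EBT3", "W1"):
        for s in s_values:
            val = sf.sauer_wilbert(s, params)
            if noise:
                val = np.mean(val * (1.0 + noise
                                     * rng.standard_normal(n_repeats)))
            pts.append(sf.CorrectedReading(s_clin=s, detector=det,
                                           value=float(val), sd=sd))
    return pts


class TestSauerWilbertEvaluation:
    def test_large_field_asymptote(self):
        p = sf.SauerWilbertParams(0.8, 2.0, 0.5, 0.2, 0.1)
        assert sf.sauer_wilbert(1e6, p) == pytest.approx(1.0, rel=1e-6)

    def test_half_saturation_at_l(self):
        p = sf.SauerWilbertParams(0.8, 2.5, 0.7, 1e-12, 0.1)
        # S_inf ~ 0: at S = l the saturating term sits at P_inf/2
        assert sf.sauer_wilbert(0.7, p) == pytest.approx(0.4, rel=1e-9)

    def test_reference_beam_value_at_10cm(self):
        # fitted 6 MV curve evaluates near unity at the reference field
        assert sf.sauer_wilbert(10.0, ELEKTA_6WFF) == pytest.approx(
            1.0003, abs=5e-4)

    def test_overflow_guard_for_large_n(self):
        p = sf.SauerWilbertParams(0.8, 500.0, 0.5, 0.2, 0.1)
        val = sf.sauer_wilbert(20.0, p)
        assert np.isfinite(val)


class TestNormalizedCurve:
    def test_unity_at_reference_field_for_any_params(self):
        for p in REFERENCE_CURVES.values():
            curve = sf.OutputFactorCurve(params=p)
            assert sf.evaluate_output_factor(curve, 10.0) == pytest.approx(
                1.0, abs=1e-15)

    @pytest.mark.parametrize("key, s, expected", [
        (("Elekta Versa HD", "6 MV WFF"), 1.03, 0.678),
        (("Varian TrueBeam", "10 MV FFF"), 1.99, 0.828),
    ])
    def test_published_discrete_values(self, key, s, expected):
        curve = sf.OutputFactorCurve(params=REFERENCE_CURVES[key])
        assert float(curve(s)) == pytest.approx(expected, abs=0.002)

    def test_monotone_increase_for_all_reference_beams(self):
        S = np.linspace(0.5, 10.0, 200)
        for p in REFERENCE_CURVES.values():
            curve = sf.OutputFactorCurve(params=p)
            vals = curve(S)
            assert np.all(np.diff(vals) > 0)


class TestCorrectFilmReading:
    def test_product(self):
        assert sf.correct_film_reading(0.455, 1.002) == pytest.approx(0.45591)

    def test_identity_at_unit_kvol(self):
        assert sf.correct_film_reading(0.7, 1.0) == pytest.approx(0.7)

    def test_ratio_property(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sig, kv = rng.uniform(0.1, 1.0), rng.uniform(1.0, 1.05)
            assert sf.correct_film_reading(sig, kv) / sig == pytest.approx(kv)


class TestFitOutputFactorCurve:
    S_VALUES = sorted(MEASURED_SCLIN[("Elekta Versa HD", "10 MV FFF")].values())

    def test_noiseless_recovery_within_0p1pct(self):
        truth = REFERENCE_CURVES[("Elekta Versa HD", "10 MV FFF")]
        pts = synthetic_points(truth, self.S_VALUES)
        curve = sf.fit_output_factor_curve(pts, seed=1, n_bootstrap=0)
        grid = np.arange(0.5, 10.5, 0.5)
        fitted = curve(grid)
        expected = sf.sauer_wilbert(grid, truth) / sf.sauer_wilbert(10.0, truth)
        assert np.max(np.abs(fitted / expected - 1.0)) < 1e-3

    def test_noisy_recovery_within_1pct_above_0p8cm(self):
        truth = REFERENCE_CURVES[("Elekta Versa HD", "10 MV FFF")]
        pts = synthetic_points(truth, self.S_VALUES, noise=0.01, sd=0.008,
                               seed=4)
        curve = sf.fit_output_factor_curve(pts, seed=2, n_bootstrap=0)
        grid = np.arange(0.8, 10.1, 0.2)
        fitted = curve(grid)
        expected = sf.sauer_wilbert(grid, truth) / sf.sauer_wilbert(10.0, truth)
        assert np.max(np.abs(fitted / expected - 1.0)) < 0.01

    def test_single_field_is_coverage_error(self):
        pts = [sf.CorrectedReading(s_clin=1.0, detector="EBT3", value=0.7,
                                   sd=0.005) for _ in range(8)]
        with pytest.raises(CoverageError):
            sf.fit_output_factor_curve(pts, seed=0)


class TestTabulateOutputFactors:
    def test_reference_row_is_exact(self):
        curve = sf.OutputFactorCurve(params=ELEKTA_6WFF)
        table = sf.tabulate_output_factors(curve, [10.0])
        row = table.iloc[0]
        assert row["omega"] == pytest.approx(1.0)
        assert row["sd"] == 0.0

    def test_reference_beam_matches_published_table(self):
        # discrete values for the 6 MV beam agree with the published
        # output-factor column to 0.003 at measured sizes >= 1 cm
        published = {1.03: 0.678, 1.51: 0.763, 2.04: 0.804, 3.06: 0.849,
                     4.04: 0.880, 5.04: 0.907, 10.04: 1.001}
        curve = sf.OutputFactorCurve(params=ELEKTA_6WFF)
        table = sf.tabulate_output_factors(curve, list(published))
        for s, expected in published.items():
            got = float(table.loc[table["s_clin_cm"] == s, "omega"].iloc[0])
            assert got == pytest.approx(expected, abs=0.003)

    def test_bootstrap_sd_grows_toward_small_fields(self):
        truth = REFERENCE_CURVES[("Elekta Versa HD", "6 MV WFF")]
        S = sorted(MEASURED_SCLIN[("Elekta Versa HD", "6 MV WFF")].values())
        pts = synthetic_points(truth, S, noise=0.008, sd=0.006, seed=9)
        curve = sf.fit_output_factor_curve(pts, seed=3, n_bootstrap=120)
        sd_small = float(curve.sd(0.5))
        sd_large = float(curve.sd(5.0))
        assert sd_small > sd_large
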