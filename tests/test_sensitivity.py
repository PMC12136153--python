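import numpy as np
import pytest

from specsense import (
    NakaRushtonFit,
    Spectrum,
    VLogICurve,
    fit_lambda_max,
    fit_naka_rushton,
    kde_mode_count,
    naka_rushton,
    normalize_peak,
    responses_to_sensitivity,
    template_value,
)

WLS = np.arange(310.0, 631.0, 10.0)  # measurement grid


def vlogi(v_max=40.0, log10_K=13.7, n=1.0, noise=0.0, rng=None, levels=9):
    """9-level series over 4 log units of attenuation below the standard
    intensity; the default half-saturation sits 1.5 log units down, as in
    the simulated protocol."""
    li = np.linspace(11.18, 15.18, levels)
    v = naka_rushton(10.0**li, v_max, 10.0**log10_K, n)
    if noise:
        v = v + rng.normal(0, noise, levels)
    return VLogICurve(log10_intensity=li, response=v, wavelength=390.0)


class TestNakaRushton:
    def test_noiseless_parameter_recovery(self):
        fit = fit_naka_rushton(vlogi(40.0, 14.5, 1.0))
        assert fit.v_max == pytest.approx(40.0, abs=1e-6)
        assert fit.log10_K == pytest.approx(14.5, abs=1e-6)
        assert fit.n == pytest.approx(1.0, abs=1e-6)

    def test_half_saturation_definition(self):
        fit = fit_naka_rushton(vlogi(40.0, 14.5, 1.3))
        assert fit.predict(10.0**fit.log10_K) == pytest.approx(fit.v_max / 2)

    def test_noisy_vmax_recovery_within_5pct(self, rng):
        errs = []
        for _ in range(100):
            fit = fit_naka_rushton(vlogi(noise=1.0, rng=rng))
            errs.append(abs(fit.v_max - 40.0) / 40.0)
        assert np.median(errs) < 0.05

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_naka_rushton(vlogi(levels=4))

    def test_degenerate_curve_flagged(self):
        curve = VLogICurve(
            log10_intensity=np.linspace(11.2, 15.2, 9),
            response=np.array([5.0, 1.0, 4.0, 0.5, 3.0, 1.5, 2.0, 0.2, 1.0]),
            wavelength=390.0,
        )
        assert not fit_naka_rushton(curve).ok


class TestResponsesToSensitivity:
    def nr(self, v_max=40.0, log10_K=13.7, n=1.0):
        return NakaRushtonFit(v_max=v_max, log10_K=log10_K, n=n, rss=0.0)

    def test_half_saturation_everywhere_gives_flat_curve(self):
        nr = self.nr()
        v = np.full(WLS.size, nr.v_max / 2)
        spec, _ = responses_to_sensitivity(WLS, v, nr, iso_intensity=10.0**nr.log10_K)
        np.testing.assert_allclose(spec.values, 1.0)

    def test_forward_inverse_round_trip(self):
        nr = self.nr()
        i0 = 1.5e15
        s_true = template_value(390.0, WLS)
        s_true = s_true / s_true.max()
        v = nr.predict(s_true * i0)
        spec, flags = responses_to_sensitivity(WLS, v, nr, iso_intensity=i0)
        np.testing.assert_allclose(spec.values, s_true, atol=1e-3)
        assert not flags["clamped"]

    def test_ratio_identity_for_unit_exponent(self):
        nr = self.nr(n=1.0)
        v = np.array([10.0, 25.0])
        spec, _ = responses_to_sensitivity(
            np.array([350.0, 390.0]), v, nr, iso_intensity=1e15
        )
        expected_ratio = (v[0] / (nr.v_max - v[0])) / (v[1] / (nr.v_max - v[1]))
        assert spec.values[0] / spec.values[1] == pytest.approx(expected_ratio)

    def test_hyperpolarizing_maps_to_zero_with_annotation(self):
        nr = self.nr()
        v = np.array([30.0, -8.0, 5.0])
        spec, flags = responses_to_sensitivity(
            np.array([390.0, 550.0, 430.0]), v, nr, iso_intensity=1e15
        )
        assert spec(550.0) == 0.0
        assert flags["hyperpolarizing"] == [550.0]

    def test_saturated_response_clamped_and_logged(self):
        nr = self.nr()
        v = np.array([41.0, 20.0, 5.0, 2.0, 1.0])
        spec, flags = responses_to_sensitivity(
            np.array([390.0, 420.0, 450.0, 480.0, 510.0]), v, nr, iso_intensity=1e15
        )
        assert flags["clamped"] == [390.0]
        assert np.isfinite(spec.values).all()


def template_spectrum(lmax, noise=0.0, rng=None, mix=None):
    vals = template_value(lmax, WLS)
    if mix is not None:
        vals = 0.5 * vals / vals.max() + 0.5 * template_value(mix, WLS) / template_value(mix, WLS).max()
    if noise:
        vals = vals / vals.max() + rng.normal(0, noise, WLS.size)
        vals = np.clip(vals, 1e-9, None)
    return normalize_peak(Spectrum(WLS, vals, kind="sensitivity"))


class TestFitLambdaMax:
    def test_self_fit_recovers_exactly(self):
        fit = fit_lambda_max(template_spectrum(355.0))
        assert fit.lambda_max == pytest.approx(355.0, abs=0.5)
        assert fit.r2 > 0.999

    def test_mixture_lands_between_components(self):
        sens = template_spectrum(355.0, mix=390.0)
        fit = fit_lambda_max(sens)
        assert 355.0 < fit.lambda_max < 390.0
        # brute-force 1 nm grid scan oracle
        grid = np.arange(330.0, 651.0, 1.0)
        s = sens.values / sens.values.max()

        def sse(lm):
            t = template_value(lm, WLS)
            return np.sum((s - t / t.max()) ** 2)

        brute = grid[int(np.argmin([sse(g) for g in grid]))]
        assert fit.lambda_max == pytest.approx(brute, abs=1.0)

    def test_noisy_rmse_within_3nm(self, rng):
        errs = []
        for _ in range(60):
            lmax = rng.uniform(345, 404)
            fit = fit_lambda_max(template_spectrum(lmax, noise=0.05, rng=rng))
            errs.append(fit.lambda_max - lmax)
        assert np.sqrt(np.mean(np.square(errs))) <= 3.0

    def test_poor_fit_flagged_unreliable(self, rng):
        vals = rng.random(WLS.size) + 0.2
        fit = fit_lambda_max(Spectrum(WLS, vals, kind="sensitivity"))
        assert not fit.reliable

    def test_homogeneous_population_unimodal(self, rng):
        lmaxes = [
            fit_lambda_max(template_spectrum(375.0, noise=0.05, rng=rng)).lambda_max
            for _ in range(80)
        ]
        # bandwidth set to the scale that would resolve distinct opsin
        # populations (UV1/UV2 peaks are ~35 nm apart)
        assert kde_mode_count(lmaxes, bandwidth=5.0) == 1
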