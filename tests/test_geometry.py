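"""Vessel diametry: Gaussian fits, width closed forms, fallback, coverage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.integrate import quad

from pericap import geometry as ge
from pericap import synthetic as sy

FWHM_COEF = 2 * math.sqrt(2 * math.log(2))


class TestFitProfile:
    def test_noiseless_parameters_recovered_to_1e6(self, clean_profile):
        fit = ge.fit_profile(clean_profile)
        assert fit.success
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.mu == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma == pytest.approx(2.0, rel=1e-6)
        assert fit.baseline == pytest.approx(10.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_profile_flagged_not_nan(self):
        prof = ge.LineProfile(np.arange(20.0), np.full(20, 50.0))
        fit = ge.fit_profile(prof)
        assert not fit.success
        assert fit.r_squared == 0.0
        assert np.isfinite(fit.sigma)

    def test_noisy_sigma_matches_grid_search_oracle(self):
        prof = sy.gen_profile(
            sy.ProfileSpec(amplitude=100, sigma_um=2.0, noise_sd=5.0), seed=11
        )
        fit = ge.fit_profile(prof)
        # oracle: grid over (mu, sigma) with (A, b) solved by linear LSQ
        pos, inten = prof.positions, prof.intensities
        best = (np.inf, None, None)
        for mu in np.linspace(-1.0, 1.0, 81):
            for sigma in np.linspace(1.0, 3.0, 161):
                g = np.exp(-((pos - mu) ** 2) / (2 * sigma**2))
                design = np.column_stack([g, np.ones_like(g)])
                coef, res, *_ = np.linalg.lstsq(design, inten, rcond=None)
                ss = float(res[0]) if res.size else float(
                    np.sum((inten - design @ coef) ** 2)
                )
                if ss < best[0]:
                    best = (ss, mu, sigma)
        assert fit.sigma == pytest.approx(best[2], abs=0.02)  # grid resolution
        assert fit.mu == pytest.approx(best[1], abs=0.05)


class TestWidthAtFraction:
    @pytest.mark.parametrize(
        "sigma,fraction,expected",
        [
            (1.0, 0.5, 2.3548200450309493),
            (1.0, 0.25, 3.3302184446307908),
            (2.5, 0.25, 8.325546111576977),
        ],
    )
    def test_closed_form_widths(self, sigma, fraction, expected):
        fit = ge.GaussianFit(100.0, 0.0, sigma, 10.0, 1.0)
        assert ge.width_at_fraction(fit, fraction) == pytest.approx(expected, rel=1e-12)

    def test_fwqm_over_fwhm_is_sqrt2_machine_precision(self):
        fit = ge.GaussianFit(37.0, 1.2, 3.3, 4.0, 0.99)
        ratio = ge.width_at_fraction(fit, 0.25) / ge.width_at_fraction(fit, 0.5)
        assert ratio == pytest.approx(math.sqrt(2), rel=1e-15)

    @given(
        f1=hst.floats(0.01, 0.99),
        f2=hst.floats(0.01, 0.99),
        sigma=hst.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_width_strictly_decreasing_in_fraction(self, f1, f2, sigma):
        fit = ge.GaussianFit(10.0, 0.0, sigma, 0.0, 1.0)
        w1, w2 = ge.width_at_fraction(fit, f1), ge.width_at_fraction(fit, f2)
        if f1 < f2:
            assert w1 > w2 or f1 == f2
        elif f1 > f2:
            assert w1 < w2

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            ge.width_at_fraction(ge.GaussianFit(1, 0, 1, 0, 1), bad)


class TestMeasureDiameter:
    def test_clean_lumen_fwqm(self):
        prof = sy.gen_profile(sy.ProfileSpec(sigma_um=1.5, noise_sd=0.0), seed=0)
        m = ge.measure_diameter(prof)
        assert m.method == "gaussian"
        assert m.mode == "FWQM"
        assert m.value_um == pytest.approx(3.3302184446307908 * 1.5, rel=1e-9)

    def test_mural_fwhm_smaller_than_lumen_fwqm(self):
        spec = sy.ProfileSpec(sigma_um=1.5, noise_sd=0.0)
        lumen = ge.measure_diameter(sy.gen_profile(spec, 0, label_kind="lumen"))
        mural = ge.measure_diameter(sy.gen_profile(spec, 0, label_kind="mural"))
        assert mural.value_um < lumen.value_um
        assert mural.mode == "FWHM"

    def test_edge_accumulation_profile_uses_fallback(self):
        prof = sy.gen_edge_accumulation_profile(
            sy.ProfileSpec(sigma_um=1.0, noise_sd=0.0, n_pixels=121), seed=0
        )
        m = ge.measure_diameter(prof)
        assert m.method == "fallback"
        # oracle: direct threshold-crossing width of the smoothed profile
        kernel = np.ones(3) / 3
        sm = np.convolve(prof.intensities, kernel, mode="same")
        sm[0] = prof.intensities[:2].mean()
        sm[-1] = prof.intensities[-2:].mean()
        base = np.percentile(sm, 10)
        level = base + 0.25 * (sm.max() - base)
        xs = np.linspace(prof.positions[0], prof.positions[-1], 200001)
        dense = np.interp(xs, prof.positions, sm)
        # outermost crossings around the global maximum
        imax = np.argmax(dense)
        left = xs[: imax + 1][dense[: imax + 1] >= level][0]
        right = xs[imax:][dense[imax:] >= level][-1]
        assert m.value_um == pytest.approx(right - left, abs=0.01)

    def test_diameter_invariant_to_intensity_offset_and_gain(self):
        prof = sy.gen_profile(sy.ProfileSpec(sigma_um=2.0, noise_sd=2.0), seed=5)
        ref = ge.measure_diameter(prof).value_um
        shifted = ge.LineProfile(prof.positions, 3.7 * prof.intensities + 55.0)
        assert ge.measure_diameter(shifted).value_um == pytest.approx(ref, rel=1e-9)

    def test_flat_profile_raises_no_vessel(self):
        prof = ge.LineProfile(np.arange(20.0), np.full(20, 5.0))
        with pytest.raises(ge.NoVesselError):
            ge.measure_diameter(prof)

    def test_constriction_recovered_from_disease_contrast_scenes(self):
        # healthy vs constricted cohorts (true diameter ratio 0.79) at SNR 20
        fwqm_coef = 3.3302184446307908
        wt_sigma = sy.WT_SOMA_DIAMETER_UM / fwqm_coef
        means = {}
        for name, sigma in (("wt", wt_sigma), ("ad", wt_sigma * 0.79)):
            vals = []
            for seed in range(150):
                prof = sy.gen_profile(
                    sy.ProfileSpec(amplitude=100, sigma_um=sigma, noise_sd=5.0,
                                   n_pixels=121),
                    seed=seed + (0 if name == "wt" else 10_000),
                )
                vals.append(ge.measure_diameter(prof).value_um)
            means[name] = np.mean(vals)
        constriction = 100.0 * (1 - means["ad"] / means["wt"])
        assert constriction == pytest.approx(21.0, abs=2.0)


class TestCoverageProfile:
    def test_constant_field_gives_flat_profile(self):
        pos = np.linspace(-16, 16, 500)
        cov = ge.coverage_profile(pos, np.full_like(pos, 7.0), soma_center_um=0.0)
        np.testing.assert_allclose(cov.mean_intensity, 7.0)
        assert cov.bin_centers_um.size == 15

    def test_exponential_decay_matches_bin_average_oracle(self):
        pos = np.linspace(0, 15.5, 40000)
        inten = np.exp(-pos / 5.0)
        cov = ge.coverage_profile(pos, inten, soma_center_um=0.0)
        for k in range(15):
            expected = quad(lambda x: np.exp(-x / 5.0), k, k + 1)[0]
            assert cov.mean_intensity[k] == pytest.approx(expected, rel=0.01)

    def test_empty_bin_is_nan_not_zero(self):
        pos = np.array([0.5, 1.5, 3.5, 16.0])  # nothing in the 2-3 um bin
        cov = ge.coverage_profile(pos, np.ones_like(pos), soma_center_um=0.0)
        assert np.isnan(cov.mean_intensity[2])

    def test_insufficient_span_reports_range(self):
        pos = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="10"):
            ge.coverage_profile(pos, np.ones_like(pos), soma_center_um=0.0)
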