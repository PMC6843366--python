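import numpy as np
import pytest

from cyclofit import (
    Spectrum,
    ValidationError,
    VoigtPeak,
    fit_bands,
    percent_areas,
    second_derivative_minima,
    subtract_overlap,
)
from cyclofit.bands import OH_SIX_CENTERS, Deconvolution
from cyclofit.synthetic import DEFAULT_OH_SUBBANDS, gen_oh_series

GRID = np.arange(3000.0, 3801.0, 2.0)


def make_envelope(peaks, grid=GRID, noise=0.0, seed=0):
    y = np.zeros_like(grid)
    for p in peaks:
        y = y + p(grid)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + noise * y.max() * rng.standard_normal(y.size)
    return Spectrum(grid, np.clip(y, 0, None))


def six_band_truth(jitter=0.0, rng=None):
    peaks = []
    weights = [0.14, 0.17, 0.21, 0.17, 0.17, 0.14]
    for (c, s, g, _, _), w in zip(DEFAULT_OH_SUBBANDS, weights):
        dc = rng.uniform(-jitter, jitter) if (rng is not None and jitter) else 0.0
        peaks.append(VoigtPeak(center=c + dc, area=w, sigma=s, gamma=g))
    return peaks


class TestSecondDerivative:
    def test_single_gaussian_minimum_at_center(self, gaussian_spectrum):
        mins = second_derivative_minima(gaussian_spectrum)
        assert mins.size == 1
        assert mins[0] == pytest.approx(3400.0, abs=2.0)  # one grid step

    def test_six_component_envelope_shows_six_minima(self):
        s = make_envelope(six_band_truth())
        mins = second_derivative_minima(s)
        assert mins.size == 6
        for found, true in zip(mins, sorted(OH_SIX_CENTERS)):
            assert found == pytest.approx(true, abs=10.0)

    def test_flat_line_yields_no_minima(self):
        s = Spectrum(GRID, np.zeros_like(GRID) + 0.0)
        assert second_derivative_minima(s).size == 0

    def test_window_longer_than_trace_rejected(self):
        s = Spectrum(GRID[:9], np.ones(9))
        with pytest.raises(ValidationError):
            second_derivative_minima(s, smooth_window=21)


class TestVoigtFit:
    def test_noiseless_six_band_round_trip(self):
        truth = six_band_truth()
        s = make_envelope(truth)
        dec = fit_bands(s, [p.center for p in truth])
        assert dec.r_squared >= 0.99999
        true_areas = np.array([p.area for p in truth])
        true_pct = 100 * true_areas / true_areas.sum()
        np.testing.assert_allclose(dec.percent_areas, true_pct, atol=1.0)

    def test_noisy_fit_reaches_r_squared_regime(self):
        s = make_envelope(six_band_truth(), noise=0.01, seed=4)
        dec = fit_bands(s, list(OH_SIX_CENTERS))
        assert dec.r_squared >= 0.999

    def test_single_gaussian_recovered_with_vanishing_lorentzian(self, gaussian_spectrum):
        dec = fit_bands(gaussian_spectrum, [3400.0])
        p = dec.peaks[0]
        assert p.center == pytest.approx(3400.0, abs=0.1)
        assert p.sigma == pytest.approx(40.0, rel=1e-2)
        assert p.gamma == pytest.approx(0.0, abs=0.5)
        assert p.area == pytest.approx(1.0, rel=1e-3)

    def test_scale_equivariance(self):
        truth = six_band_truth()
        s = make_envelope(truth)
        scaled = s.with_intensity(s.intensity * 100.0)
        d1 = fit_bands(s, [p.center for p in truth])
        d2 = fit_bands(scaled, [p.center for p in truth])
        np.testing.assert_allclose(d2.percent_areas, d1.percent_areas, atol=1e-6)
        assert d2.r_squared == pytest.approx(d1.r_squared, abs=1e-9)
        a1 = sum(p.area for p in d1.peaks)
        a2 = sum(p.area for p in d2.peaks)
        assert a2 == pytest.approx(100.0 * a1, rel=1e-6)

    def test_jittered_envelope_round_trip_property(self, rng):
        # randomized six-band geometries around the O-H scheme, noiseless
        for _ in range(12):
            truth = six_band_truth(jitter=15.0, rng=rng)
            s = make_envelope(truth)
            dec = fit_bands(s, [p.center for p in truth])
            true_areas = np.array(sorted((p.area for p in truth)))
            got = np.array(sorted(p.area for p in dec.peaks))
            total = true_areas.sum()
            np.testing.assert_allclose(100 * got / total, 100 * true_areas / total, atol=1.0)


class TestPercentAreas:
    def make_deconv(self, areas):
        peaks = tuple(
            VoigtPeak(center=3600 - 100 * i, area=a, sigma=30.0) for i, a in enumerate(areas)
        )
        return Deconvolution(model=None, peaks=peaks, baseline=(0.0, 0.0), r_squared=1.0)

    def test_equal_areas_split_evenly(self):
        dec = self.make_deconv([2.0] * 6)
        np.testing.assert_allclose(dec.percent_areas, 100 / 6, rtol=1e-12)

    def test_dominant_band_share(self):
        dec = self.make_deconv([1, 1, 1, 1, 1, 5])
        assert dec.percent_areas[-1] == pytest.approx(50.0)

    def test_sum_is_hundred(self, rng):
        dec = self.make_deconv(rng.uniform(0.1, 3.0, size=6))
        assert dec.percent_areas.sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_areas_rejected(self):
        dec = self.make_deconv([0.0, 0.0])
        with pytest.raises(ValidationError):
            percent_areas(dec)


class TestOverlapSubtraction:
    def ch_doublet(self):
        return [
            VoigtPeak(center=2922.0, area=0.3, sigma=18.0, gamma=5.0),
            VoigtPeak(center=2848.0, area=0.2, sigma=16.0, gamma=4.0),
        ]

    def test_ch_contamination_removed_from_oh_window(self):
        grid = np.arange(2600.0, 3801.0, 2.0)
        oh = [VoigtPeak(center=c, area=w, sigma=s, gamma=g)
              for (c, s, g, _, w) in DEFAULT_OH_SUBBANDS]
        full = make_envelope(oh + self.ch_doublet(), grid=grid)
        cleaned = subtract_overlap(full, overlap_window=(2700, 3000), n_overlap_peaks=2)
        pure_oh = make_envelope(oh, grid=grid)
        mask = grid >= 3000
        ch_area = 0.5
        contamination = np.trapezoid(
            np.abs(cleaned.intensity[mask] - pure_oh.intensity[mask]), grid[mask]
        )
        assert contamination < 0.01 * ch_area

    def test_silent_window_returns_input_unchanged(self):
        grid = np.arange(2600.0, 3801.0, 2.0)
        oh_only = make_envelope(
            [VoigtPeak(center=3400, area=1.0, sigma=30.0)], grid=grid
        )
        with pytest.warns(UserWarning):
            out = subtract_overlap(oh_only, overlap_window=(2700, 2950))
        np.testing.assert_array_equal(out.intensity, oh_only.intensity)

    def test_pure_doublet_self_subtracts_to_noise(self):
        grid = np.arange(2600.0, 3201.0, 2.0)
        s = make_envelope(self.ch_doublet(), grid=grid)
        out = subtract_overlap(s, overlap_window=(2700, 3000))
        assert out.intensity.max() < 0.02 * s.intensity.max()


def test_r_squared_not_decreasing_with_more_restart_rounds():
    series = gen_oh_series(noise=0.01, seed=2)
    s = series.spectra[0]
    from cyclofit.bands import VoigtBandModel

    r2_one = VoigtBandModel(s, OH_SIX_CENTERS).fit(max_rounds=1).r_squared
    r2_three = VoigtBandModel(s, OH_SIX_CENTERS).fit(max_rounds=3).r_squared
    assert r2_three >= r2_one - 1e-12
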