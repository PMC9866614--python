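"""Amplitude spectra, band features and the half-energy frequency.

The DFT path is checked against an independent O(N^2) direct summation and
against closed forms for cosines at exact bin frequencies.
"""

import numpy as np
import pytest

from edafreq import (
    EmptyBandError,
    FrequencyBand,
    Segment,
    ZeroEnergySegmentError,
    amplitude_spectrum,
    band_bins,
    band_max,
    band_mean,
    band_std,
    energy_profile,
    extract_segment_features,
    half_energy_frequency,
    normalize_spectrum,
)
from edafreq.spectral import DEFAULT_BANDS, feature_names


def make_segment(values, fs=4.0):
    return Segment("s0", "stress", 0, np.asarray(values, float), fs)


def cosine_segment(freq_hz, n=48, fs=4.0, amplitude=1.0):
    k = np.arange(n)
    return make_segment(amplitude * np.cos(2 * np.pi * freq_hz * k / fs), fs)


def direct_dft_magnitudes(x):
    """Brute-force one-sided DFT, independent of any FFT library."""
    n = len(x)
    out = np.empty(n // 2 + 1)
    for b in range(n // 2 + 1):
        out[b] = abs(sum(x[k] * np.exp(-2j * np.pi * b * k / n) for k in range(n)))
    return out


class TestAmplitudeSpectrum:
    def test_zero_segment_has_zero_spectrum(self):
        spec = amplitude_spectrum(make_segment(np.zeros(48)))
        np.testing.assert_allclose(spec.magnitudes, 0.0)

    def test_unit_cosine_at_exact_bin(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        assert spec.resolution == pytest.approx(1 / 12)
        assert spec.magnitudes[12] == pytest.approx(24.0, abs=1e-9)
        rest = np.delete(spec.magnitudes, 12)
        assert np.all(rest < 1e-9)

    def test_matches_direct_summation(self):
        for trial in range(10):
            x = np.random.default_rng(trial).normal(size=48)
            spec = amplitude_spectrum(make_segment(x))
            np.testing.assert_allclose(spec.magnitudes, direct_dft_magnitudes(x), atol=1e-9)

    def test_parseval_one_sided(self, rng):
        x = rng.normal(size=48)
        m = amplitude_spectrum(make_segment(x)).magnitudes
        spectral = (m[0] ** 2 + 2 * np.sum(m[1:-1] ** 2) + m[-1] ** 2) / 48
        assert spectral == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            amplitude_spectrum(make_segment([1.0]))


class TestNormalizeSpectrum:
    def test_single_bin_becomes_unit(self):
        spec = normalize_spectrum(amplitude_spectrum(cosine_segment(1.0)))
        assert spec.magnitudes[12] == pytest.approx(1.0, abs=1e-9)

    def test_none_is_identity(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        assert normalize_spectrum(spec, "none") is spec

    def test_unit_energy_after_normalization(self, rng):
        spec = amplitude_spectrum(make_segment(rng.normal(size=48)))
        out = normalize_spectrum(spec, "energy")
        assert np.sum(out.magnitudes**2) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_returned_unchanged(self):
        spec = amplitude_spectrum(make_segment(np.zeros(48)))
        out = normalize_spectrum(spec, "energy")
        np.testing.assert_array_equal(out.magnitudes, spec.magnitudes)


class TestBandBins:
    def test_unit_band_holds_twelve_bins(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        bins = band_bins(spec, FrequencyBand(1.0, 2.0))
        np.testing.assert_array_equal(bins, np.arange(12, 24))

    def test_full_half_open_band_misses_only_nyquist(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        bins = band_bins(spec, FrequencyBand(0.0, 2.0))
        np.testing.assert_array_equal(bins, np.arange(24))

    def test_adjacent_half_open_bands_partition(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        low = band_bins(spec, FrequencyBand(0.0, 1.0))
        high = band_bins(spec, FrequencyBand(1.0, 2.0))
        assert not set(low) & set(high)
        assert sorted(set(low) | set(high)) == list(range(24))

    def test_closed_rule_includes_both_edges(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        bins = band_bins(spec, FrequencyBand(1.0, 2.0, edge_rule="closed"))
        np.testing.assert_array_equal(bins, np.arange(12, 25))

    def test_empty_band_is_structured_error(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        with pytest.raises(EmptyBandError):
            band_bins(spec, FrequencyBand(0.01, 0.02))


class TestBandFeatures:
    band = FrequencyBand(1.0, 2.0)

    def test_mean_of_single_tone(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        assert band_mean(spec, self.band) == pytest.approx(2.0, abs=1e-9)

    def test_std_of_single_tone(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        # magnitudes (24, 0 x 11): sum of squared deviations 528, divisor 11
        assert band_std(spec, self.band) == pytest.approx(np.sqrt(48.0), abs=1e-9)

    def test_max_of_single_tone(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        assert band_max(spec, self.band) == pytest.approx(24.0, abs=1e-9)

    def test_zero_band(self):
        spec = amplitude_spectrum(cosine_segment(1.0))
        other = FrequencyBand(0.0, 1.0)
        assert band_mean(spec, other) == pytest.approx(0.0, abs=1e-9)
        assert band_max(spec, other) == pytest.approx(0.0, abs=1e-9)

    def test_std_matches_two_pass_formula(self, rng):
        spec = amplitude_spectrum(make_segment(rng.normal(size=48)))
        m = spec.magnitudes[12:24]
        expected = np.sqrt(np.sum((m - m.mean()) ** 2) / (len(m) - 1))
        assert band_std(spec, self.band) == pytest.approx(expected, abs=1e-12)


class TestEnergyProfile:
    def test_single_tone_cumulative_jump(self):
        profile = energy_profile(amplitude_spectrum(cosine_segment(1.0)))
        assert profile.psi_cum[10] == pytest.approx(0.0, abs=1e-12)
        assert profile.psi_cum[11] == pytest.approx(1.0, abs=1e-9)  # bin 12, DC dropped

    def test_cumulative_is_monotone_and_ends_at_one(self, rng):
        profile = energy_profile(amplitude_spectrum(make_segment(rng.normal(size=48))))
        assert np.all(np.diff(profile.psi_cum) >= -1e-15)
        assert profile.psi_cum[-1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_running_sum_oracle(self, rng):
        spec = amplitude_spectrum(make_segment(rng.normal(size=48)))
        profile = energy_profile(spec)
        psi = spec.magnitudes[1:] ** 2
        running = [psi[: i + 1].sum() / psi.sum() for i in range(len(psi))]
        np.testing.assert_allclose(profile.psi_cum, running, atol=1e-12)

    def test_zero_energy_raises(self):
        with pytest.raises(ZeroEnergySegmentError):
            energy_profile(amplitude_spectrum(make_segment(np.zeros(48))))

    def test_include_dc_keeps_bin_zero(self):
        spec = amplitude_spectrum(make_segment(np.ones(48) * 5.0))
        profile = energy_profile(spec, include_dc=True)
        assert profile.frequencies[0] == 0.0
        assert profile.psi_cum[0] == pytest.approx(1.0, abs=1e-9)


class TestHalfEnergyFrequency:
    def test_single_tone(self):
        profile = energy_profile(amplitude_spectrum(cosine_segment(1.0)))
        assert half_energy_frequency(profile) == pytest.approx(1.0)

    def test_equal_energy_tones_pick_lower_bin(self):
        seg = cosine_segment(0.5)
        seg.values = seg.values + cosine_segment(1.5).values
        profile = energy_profile(amplitude_spectrum(seg))
        assert half_energy_frequency(profile) == pytest.approx(0.5)

    def test_flat_spectrum(self):
        from edafreq import AmplitudeSpectrum

        mags = np.zeros(25)
        mags[1:] = 1.0
        profile = energy_profile(AmplitudeSpectrum(mags, fs=4.0, N=48))
        assert half_energy_frequency(profile) == pytest.approx(1.0)

    def test_invariant_under_rescaling(self, rng):
        x = rng.normal(size=48)
        f1 = half_energy_frequency(energy_profile(amplitude_spectrum(make_segment(x))))
        f2 = half_energy_frequency(energy_profile(amplitude_spectrum(make_segment(x * 137.5))))
        assert f1 == f2


class TestExtractSegmentFeatures:
    def test_default_two_bands_give_seven_features(self, rng):
        features = extract_segment_features(make_segment(rng.normal(size=48)))
        assert list(features) == feature_names(DEFAULT_BANDS)
        assert len(features) == 7

    def test_one_band_gives_four_features(self, rng):
        features = extract_segment_features(
            make_segment(rng.normal(size=48)), bands=[FrequencyBand(0.0, 1.0)]
        )
        assert len(features) == 4

    def test_single_tone_features_hand_computed(self):
        features = extract_segment_features(cosine_segment(1.0))
        assert features["mean_1.0_2.0"] == pytest.approx(2.0, abs=1e-9)
        assert features["std_1.0_2.0"] == pytest.approx(np.sqrt(48.0), abs=1e-9)
        assert features["max_1.0_2.0"] == pytest.approx(24.0, abs=1e-9)
        assert features["fhalf"] == pytest.approx(1.0)

    def test_zero_energy_propagates(self):
        with pytest.raises(ZeroEnergySegmentError):
            extract_segment_features(make_segment(np.zeros(48)))

    def test_band_partition_conserves_energy(self, rng):
        # contiguous half-open bands covering [0, fs/2) account for all
        # non-Nyquist energy exactly once
        spec = amplitude_spectrum(make_segment(rng.normal(size=48)))
        bands = [FrequencyBand(0.0, 0.5), FrequencyBand(0.5, 1.3), FrequencyBand(1.3, 2.0)]
        per_band = sum(np.sum(spec.magnitudes[band_bins(spec, b)] ** 2) for b in bands)
        assert per_band == pytest.approx(np.sum(spec.magnitudes[:-1] ** 2), rel=1e-12)
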