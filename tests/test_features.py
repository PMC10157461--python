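"""Feature catalog arithmetic, time/frequency descriptors, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorglyc import (DEFAULT_CATALOG, DEFAULT_DROP, BandSpec, PsdEstimate,
                        extract, extract_matrix, freq_features,
                        select_features, time_features, welch_psd)
from tremorglyc.features import CHANNELS, _count_peaks

from conftest import window_from_channels


def tone_window(freq, rate=64.0, n=192, amplitude=1.0):
    t = np.arange(n) / rate
    return window_from_channels(amplitude * np.sin(2 * np.pi * freq * t),
                                rate=rate)


class TestCatalog:
    def test_counts_are_86_split_42_and_44(self):
        assert len(DEFAULT_CATALOG.time_names) == 42
        assert len(DEFAULT_CATALOG.freq_names) == 44
        assert len(DEFAULT_CATALOG.names) == 86

    def test_names_unique(self):
        assert len(set(DEFAULT_CATALOG.names)) == 86

    def test_default_drop_leaves_60(self):
        assert len(DEFAULT_DROP) == 26
        assert set(DEFAULT_DROP) <= set(DEFAULT_CATALOG.names)


class TestTimeFeatures:
    def test_hand_computed_statistics(self):
        w = window_from_channels([1.0, 2.0, 3.0])
        f = time_features(w)
        assert f["x_mean"] == pytest.approx(2.0)
        assert f["x_range"] == pytest.approx(2.0)
        assert f["x_var"] == pytest.approx(2.0 / 3.0)  # population convention
        assert f["x_max"] == 3.0 and f["x_min"] == 1.0

    def test_constant_channel_degenerates_to_zero(self):
        w = window_from_channels(np.full(32, 5.0), y=np.arange(32.0))
        f = time_features(w)
        for name in ["x_sd", "x_var", "x_range", "x_nop", "x_skew", "x_kurt",
                     "corr_x_y"]:
            assert f[name] == 0.0

    def test_peak_count_example(self):
        # peaks at 1 and 2 both exceed the window mean 0.6
        w = window_from_channels([0.0, 1.0, 0.0, 2.0, 0.0])
        assert time_features(w)["x_nop"] == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=3,
                    max_size=100))
    def test_peak_count_matches_brute_force_scan(self, values):
        x = np.asarray(values)
        mean = x.mean()
        brute = sum(1 for i in range(1, len(x) - 1)
                    if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] > mean)
        assert _count_peaks(x[None])[0] == brute

    def test_correlation_of_identical_channels_is_one(self):
        x = np.sin(np.arange(64.0))
        w = window_from_channels(x, y=x)
        assert time_features(w)["corr_x_y"] == pytest.approx(1.0)


class TestWelch:
    @pytest.mark.parametrize("freq", [1.0, 5.0, 8.0, 17.0, 30.0])
    def test_fmax_recovers_tone_frequency_within_one_bin(self, freq):
        psd = welch_psd(tone_window(freq), "x")
        fmax = psd.frequencies[np.argmax(psd.power)]
        assert abs(fmax - freq) <= psd.resolution

    def test_parseval_total_power_matches_variance(self, rng):
        """Integrated PSD of white noise ~ its variance (15%, averaged)."""
        sigma = 0.3
        totals = []
        for _ in range(60):
            x = rng.normal(0, sigma, 192)
            psd = welch_psd(window_from_channels(x), "x")
            totals.append(np.trapezoid(psd.power, psd.frequencies))
        assert np.mean(totals) == pytest.approx(sigma ** 2, rel=0.15)

    def test_zero_signal_gives_zero_psd(self):
        psd = welch_psd(window_from_channels(np.zeros(192)), "x")
        assert np.all(psd.power == 0.0)

    def test_grid_resolution_is_one_hz_at_defaults(self):
        psd = welch_psd(tone_window(8.0), "x")
        assert psd.resolution == pytest.approx(1.0)
        assert psd.frequencies[-1] == pytest.approx(32.0)

    def test_window_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            welch_psd(window_from_channels(np.zeros(32)), "x")


class TestFreqFeatures:
    @staticmethod
    def _psds(power, f=None):
        f = np.arange(33.0) if f is None else f
        p = np.asarray(power, dtype=float)
        return [PsdEstimate(f, p, 1.0) for _ in CHANNELS]

    def test_flat_psd_nabp_equals_band_fraction(self):
        """Uniform density: NABP is the non-DC bandwidth fraction."""
        f = freq_features(self._psds(np.ones(33)))
        assert f["x_nabp"] == pytest.approx(31.0 / 32.0)
        assert f["x_abp"] == pytest.approx(1.0)
        assert f["x_htfr_abp"] == pytest.approx(1.0)

    def test_tone_in_band_dominates_htfr_power(self):
        w = tone_window(8.0)
        vec = extract(w)
        # complement-band average power, from total minus the tremor band
        psd = welch_psd(w, "x")
        total = np.trapezoid(psd.power, psd.frequencies)
        in_band = vec["x_htfr_abp"] * 10.0
        out_band = (total - in_band) / 22.0
        assert vec["x_htfr_abp"] > 50 * out_band

    def test_tone_outside_band_leaves_htfr_empty(self):
        vec = extract(tone_window(20.0))
        assert vec["x_fmax"] == pytest.approx(20.0, abs=1.0)
        assert vec["x_htfr_abp"] < 1e-3 * vec["x_psd_max"]

    def test_zero_power_nabp_emitted_as_zero(self):
        f = freq_features(self._psds(np.zeros(33)))
        assert f["x_nabp"] == 0.0


class TestExtract:
    def test_vector_has_86_features_in_catalog_order(self, rng):
        w = window_from_channels(rng.normal(size=192))
        vec = extract(w)
        assert list(vec.index) == DEFAULT_CATALOG.names
        assert len(vec) == 86
        assert np.all(np.isfinite(vec.to_numpy()))

    def test_identical_windows_give_identical_vectors(self, rng):
        x = rng.normal(size=192)
        a = extract(window_from_channels(x))
        b = extract(window_from_channels(x.copy()))
        pd.testing.assert_series_equal(a, b)

    def test_scale_equivariance(self, rng):
        """Scaling a window by c scales each feature by its known power."""
        x = rng.normal(size=(192, 4)) + 1.0
        c = 2.5
        from tremorglyc import Window
        a = extract(Window("T", 0.0, x, 64.0))
        b = extract(Window("T", 0.0, c * x, 64.0))
        linear = [f"{ch}_{s}" for s in ("mean", "sd", "max", "min", "range")
                  for ch in CHANNELS]
        quadratic = ([f"{ch}_var" for ch in CHANNELS]
                     + [f"{ch}_{s}" for s in ("psd_mean", "psd_max", "psd_sd",
                                              "abp", "htfr_mean", "htfr_max",
                                              "htfr_sd", "htfr_abp")
                        for ch in CHANNELS])
        invariant = ([f"{ch}_{s}" for s in ("nop", "skew", "kurt", "psd_nop",
                                            "nabp", "fmax")
                      for ch in CHANNELS]
                     + [n for n in a.index if n.startswith("corr_")])
        assert np.allclose(b[linear], c * a[linear], rtol=1e-9)
        assert np.allclose(b[quadratic], c ** 2 * a[quadratic], rtol=1e-9)
        assert np.allclose(b[invariant], a[invariant], rtol=1e-9)

    def test_batch_extraction_matches_single_windows(self, rng):
        samples = rng.normal(size=(5, 192, 4))
        batch = extract_matrix(samples, 64.0)
        from tremorglyc import Window
        for i in range(5):
            single = extract(Window("T", 0.0, samples[i], 64.0))
            assert np.allclose(batch.iloc[i].to_numpy(), single.to_numpy())


class TestSelection:
    def test_default_drop_yields_60(self, rng):
        vec = extract(window_from_channels(rng.normal(size=192)))
        assert len(select_features(vec)) == 60

    def test_empty_drop_is_identity(self, rng):
        vec = extract(window_from_channels(rng.normal(size=192)))
        pd.testing.assert_series_equal(select_features(vec, ()), vec)

    def test_unknown_name_rejected(self, rng):
        vec = extract(window_from_channels(rng.normal(size=192)))
        with pytest.raises(KeyError, match="no_such_feature"):
            select_features(vec, ("no_such_feature",))

    def test_order_preserved_after_drop(self, rng):
        df = extract_matrix(rng.normal(size=(3, 192, 4)), 64.0)
        out = select_features(df)
        kept = [n for n in DEFAULT_CATALOG.names if n not in DEFAULT_DROP]
        assert list(out.columns) == kept
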