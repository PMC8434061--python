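import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.regression.linear_model import burg as sm_burg

from microbehavior import (
    FeatureSpec,
    WindowSample,
    burg_ar,
    cross_features,
    feature_names,
    feature_vector,
    freq_features,
    spectrum,
    time_features,
)
from microbehavior.features import default_bands, extract_features

import _bruteforce as bf


def random_slices(n=100, width=32, seed=2024):
    rng = np.random.default_rng(seed)
    return [rng.normal(0, rng.uniform(0.1, 10), size=width) for _ in range(n)]


class TestTimeFeatures:
    def test_two_point_slice(self):
        f = time_features(np.array([1.0, 3.0]), ar_order=1)
        assert f["mean"] == 2.0
        assert f["std"] == 1.0
        assert f["range"] == 2.0

    def test_energy_and_rms(self):
        f = time_features(np.array([1.0, 2.0, 3.0]), ar_order=1)
        assert f["energy"] == pytest.approx(14 / 3)
        assert f["rms"] == pytest.approx(math.sqrt(14 / 3))

    def test_mad_robust_to_outlier(self):
        f = time_features(np.array([1.0, 2.0, 3.0, 100.0]), ar_order=1)
        assert f["mad"] == 1.0

    def test_entropy_of_uniform_positive_slice(self):
        f = time_features(np.array([5.0, 5.0, 5.0, 5.0]), ar_order=1)
        assert f["entropy"] == pytest.approx(math.log(1 / 4))

    def test_iqr_linear_interpolation(self):
        f = time_features(np.array([1.0, 2.0, 3.0, 4.0]), ar_order=1)
        assert f["iqr"] == pytest.approx(bf.iqr([1, 2, 3, 4]))
        assert f["iqr"] == pytest.approx(1.5)

    def test_too_short_slice_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_features(np.array([1.0, 2.0, 3.0]), ar_order=4)

    @pytest.mark.parametrize(
        "name,oracle",
        [
            ("mean", bf.mean),
            ("std", bf.pop_std),
            ("mad", bf.mad),
            ("max", max),
            ("min", min),
            ("energy", bf.energy),
            ("entropy", bf.entropy),
            ("iqr", bf.iqr),
            ("range", bf.value_range),
            ("rms", bf.rms),
        ],
    )
    def test_scalars_match_bruteforce(self, name, oracle):
        for s in random_slices():
            assert time_features(s)[name] == pytest.approx(
                oracle(s.tolist()), abs=1e-9
            )

    def test_rms_squared_equals_energy(self):
        for s in random_slices(20):
            f = time_features(s)
            assert f["rms"] ** 2 == pytest.approx(f["energy"], rel=1e-12)

    @given(c=st.floats(0.1, 100))
    @settings(max_examples=30, derandomize=True)
    def test_positive_scaling_covariance(self, c):
        s = np.array([0.3, -1.2, 2.5, 0.0, 4.1, -0.7, 1.1, 2.2])
        base = time_features(s, ar_order=2)
        scaled = time_features(c * s, ar_order=2)
        for name in ("mean", "std", "mad", "max", "min", "range", "rms"):
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-9)
        assert scaled["energy"] == pytest.approx(c * c * base["energy"], rel=1e-9)


class TestBurgAR:
    def test_constant_slice_degenerates_to_zero(self):
        np.testing.assert_array_equal(burg_ar(np.full(32, 3.3)), np.zeros(4))

    def test_recovers_known_ar4_process(self):
        # x_t = 0.9 x_{t-1} - 0.5 x_{t-2} + 0.3 x_{t-3} - 0.1 x_{t-4} + e_t
        phi = np.array([0.9, -0.5, 0.3, -0.1])
        rng = np.random.default_rng(7)
        x = np.zeros(4096 + 200)
        e = rng.normal(size=x.shape[0])
        for t in range(4, x.shape[0]):
            x[t] = phi @ x[t - 4 : t][::-1] + e[t]
        a = burg_ar(x[200:], order=4)
        np.testing.assert_allclose(a, -phi, atol=0.1)

    def test_matches_reference_implementation(self):
        for s in random_slices(100):
            a = burg_ar(s, 4)
            rho, _ = sm_burg(s, order=4, demean=False)
            np.testing.assert_allclose(a, -np.asarray(rho), atol=1e-6)

    def test_order_must_be_below_length(self):
        with pytest.raises(ValueError):
            burg_ar(np.arange(4.0), order=4)


class TestSpectrum:
    def test_constant_slice_gives_zero_bins(self):
        np.testing.assert_allclose(spectrum(np.full(32, 7.0)), np.zeros(16))

    def test_pure_sinusoid_peaks_at_its_bin(self):
        t = np.arange(32)
        for k in (1, 5, 11):
            s = np.sin(2 * np.pi * k * t / 32)
            assert np.argmax(spectrum(s)) + 1 == k

    def test_matches_naive_dft(self):
        for s in random_slices(30):
            np.testing.assert_allclose(
                spectrum(s), bf.dft_magnitudes(s.tolist()), atol=1e-6
            )

    def test_parseval_relation(self):
        # full two-sided power of the mean-subtracted slice; for real input
        # interior bins count twice, the Nyquist bin once
        s = random_slices(1, seed=5)[0]
        mags = spectrum(s)
        power = 2 * np.sum(mags[:-1] ** 2) + mags[-1] ** 2
        assert power / len(s) == pytest.approx(np.sum((s - s.mean()) ** 2))


class TestFreqFeatures:
    BANDS = ((1, 5), (6, 10), (11, 16))

    def run(self, bins):
        return freq_features(np.asarray(bins, dtype=float), self.BANDS, 29.97)

    def test_max_freq_index_is_one_based(self):
        bins = np.zeros(16)
        bins[1] = 5.0
        assert self.run(bins)["maxfreqind"] == 2

    def test_mean_freq_of_flat_bins(self):
        assert self.run(np.ones(16))["meanfreq"] == pytest.approx(8.5)

    def test_symmetric_bins_have_zero_skewness(self):
        bins = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0] * 2)
        assert self.run(bins)["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_energy_band_of_unit_bins(self):
        assert self.run(np.ones(16))["energyband_1_5"] == pytest.approx(1.0)

    def test_zero_spectrum_degenerate_rules(self):
        f = self.run(np.zeros(16))
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["meanfreq"] == 0.0

    def test_band_outside_bins_rejected(self):
        with pytest.raises(ValueError, match="band"):
            freq_features(np.ones(8), ((1, 16),), 29.97)

    @pytest.mark.parametrize(
        "name,oracle",
        [
            ("skewness", bf.skewness),
            ("kurtosis", bf.kurtosis),
            ("maxfreqind", bf.max_freq_ind),
            ("meanfreq", bf.mean_freq),
        ],
    )
    def test_spectral_scalars_match_bruteforce(self, name, oracle):
        rng = np.random.default_rng(3)
        for _ in range(100):
            bins = rng.uniform(0, 10, size=16)
            assert self.run(bins)[name] == pytest.approx(
                oracle(bins.tolist()), abs=1e-6
            )

    def test_band_energy_and_psd_match_bruteforce(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            bins = rng.uniform(0, 10, size=16)
            f = self.run(bins)
            for a, b in self.BANDS:
                assert f[f"energyband_{a}_{b}"] == pytest.approx(
                    bf.energy_band(bins.tolist(), a, b), abs=1e-9
                )
            assert f["psd"] == pytest.approx(np.sum(bins**2) / 29.97, rel=1e-12)


class TestCrossFeatures:
    def test_sma_of_constant_ones(self):
        ones = np.ones(32)
        assert cross_features(ones, ones, ones)["sma"] == pytest.approx(32.0)

    def test_perfectly_correlated_signals(self):
        s = np.arange(32, dtype=float)
        assert cross_features(s, 2 * s, s)["correlation"] == pytest.approx(1.0)

    def test_zero_variance_correlation_is_zero(self):
        s = np.arange(32, dtype=float)
        assert cross_features(s, np.ones(32), s)["correlation"] == 0.0

    def test_angle_zero_when_mean_parallel_to_reference(self):
        ones = np.ones(8)
        f = cross_features(0 * ones, 0 * ones, 2 * ones, v=(0, 0, 1))
        assert f["angle"] == pytest.approx(0.0)


class TestFeatureVector:
    def _window(self, width=32, channels=("pose_Rx", "lip_62_66"), seed=0):
        rng = np.random.default_rng(seed)
        return WindowSample(
            "p1", 0, width, 0,
            {ch: rng.normal(size=width) for ch in channels},
        )

    def test_default_vector_has_60_features(self):
        vec = feature_vector(self._window(), FeatureSpec())
        assert len(vec.names) == 60
        assert vec.values.shape == (60,)

    def test_single_channel_vector_has_30_features(self):
        spec = FeatureSpec(channels=("pose_Rx",))
        vec = feature_vector(self._window(channels=("pose_Rx",)), spec)
        assert len(vec.names) == 30
        for banned in ("sma", "correlation", "angle"):
            assert not any(banned in n for n in vec.names)

    def test_deterministic_on_identical_windows(self):
        spec = FeatureSpec()
        v1 = feature_vector(self._window(seed=5), spec)
        v2 = feature_vector(self._window(seed=5), spec)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert v1.names == v2.names

    def test_names_unique_and_spec_determined(self):
        names = feature_names(FeatureSpec(), 32)
        assert len(set(names)) == len(names) == 60
        assert names == feature_names(FeatureSpec(), 32)

    def test_missing_channel_named_in_error(self):
        with pytest.raises(KeyError, match="lip_62_66"):
            feature_vector(self._window(channels=("pose_Rx",)), FeatureSpec())

    def test_extract_features_table_shape(self):
        windows = [self._window(seed=s) for s in range(3)]
        table = extract_features(windows, FeatureSpec())
        assert table.shape == (3, 64)
        assert list(table.columns[:4]) == ["participant", "start", "end", "label"]


class TestDefaultBands:
    def test_sixteen_bins_reproduce_canonical_bands(self):
        assert default_bands(16) == ((1, 5), (6, 10), (11, 16))

    @pytest.mark.parametrize("n_bins", [3, 8, 16, 32, 33])
    def test_bands_partition_all_bins(self, n_bins):
        bands = default_bands(n_bins)
        covered = [i for a, b in bands for i in range(a, b + 1)]
        assert covered == list(range(1, n_bins + 1))
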