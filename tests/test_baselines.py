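"""Autocorrelation features, histograms + PCA, spectral images, classifiers."""

import numpy as np
import pytest

from apneaflow import baselines
from apneaflow.baselines import AutocorrSeries, HistogramSequence, MovementSignal
from apneaflow.flowproc import MagnitudeSequence
from apneaflow.windowing import ApneaEvent


def _mags(values):
    return MagnitudeSequence(np.asarray(values, dtype=np.float32), fps=2.0)


class TestMeanMovementSignal:
    def test_constant_field(self):
        mags = _mags(np.full((6, 4, 4), 0.3))
        sig = baselines.mean_movement_signal(mags)
        assert np.allclose(sig.values, 0.3)
        assert len(sig.values) == 6

    def test_half_zeros_half_point_four(self):
        frame = np.zeros((4, 4), dtype=np.float32)
        frame[:2] = 0.4
        sig = baselines.mean_movement_signal(_mags(frame[None]))
        assert np.isclose(sig.values[0], 0.2)

    def test_event_span_slicing(self):
        mags = _mags(np.zeros((40, 2, 2)))
        event = ApneaEvent("r", 5.0, 15.0, "CA")
        sig = baselines.mean_movement_signal(mags, event)
        assert len(sig.values) == 20  # 10 s at 2 Hz

    def test_empty_span_rejected(self):
        mags = _mags(np.zeros((4, 2, 2)))
        with pytest.raises(ValueError, match="cover"):
            baselines.mean_movement_signal(mags, ApneaEvent("r", 50.0, 60.0, "CA"))


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(100) / 2.0
        sig = MovementSignal(np.sin(2 * np.pi * 0.25 * t), fps=2.0)
        out = baselines.bandpass(sig)
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(out.values) >= 0.9 * rms(sig.values)

    def test_dc_rejected(self):
        sig = MovementSignal(np.full(100, 0.7), fps=2.0)
        out = baselines.bandpass(sig)
        assert np.sqrt(np.mean(out.values**2)) <= 0.05 * 0.7

    def test_zero_in_zero_out(self):
        out = baselines.bandpass(MovementSignal(np.zeros(50), fps=2.0))
        assert np.allclose(out.values, 0.0)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="short"):
            baselines.bandpass(MovementSignal(np.ones(10), fps=2.0))


class TestAutocorrelation:
    def test_sinusoid_matches_cosine_closed_form(self):
        t = np.arange(200) / 2.0
        sig = MovementSignal(np.sin(2 * np.pi * 0.25 * t), fps=2.0)
        series = baselines.autocorrelation(sig)
        lags = np.arange(17)  # up to 8 s
        expected = np.cos(2 * np.pi * 0.25 * lags / 2.0)
        # biased estimator shrinks slightly with lag; 0.05 absolute agreement
        assert np.max(np.abs(series.r[:17] - expected * (1 - lags / 200))) < 0.05
        assert series.r[0] == pytest.approx(1.0)
        assert series.r[8] == pytest.approx(1.0, abs=0.05)  # one period = 4 s

    def test_white_noise_bound(self):
        rng = np.random.default_rng(7)
        series = baselines.autocorrelation(MovementSignal(rng.normal(0, 1, 200), fps=2.0))
        assert np.max(np.abs(series.r[1:])) < 3 / np.sqrt(200)

    def test_constant_signal_is_all_zero(self):
        series = baselines.autocorrelation(MovementSignal(np.full(30, 0.4), fps=2.0))
        assert np.all(series.r == 0.0)
        assert series.max_lag == 29


class TestPeakFeatures:
    def test_known_peaks_zero_padded(self):
        r = np.array([1.0, 0.0, 0.8, 0.0, 0.5, 0.0, 0.3, 0.0, 0.0, 0.0])
        feats = baselines.peak_features(AutocorrSeries(r, fps=2.0))
        assert np.allclose(feats, [0.8, 0.5, 0.3, 0, 0, 0, 0, 0, 0, 0])

    def test_monotone_decay_gives_zeros(self):
        r = np.exp(-np.arange(30) / 5.0)
        feats = baselines.peak_features(AutocorrSeries(r, fps=2.0))
        assert np.allclose(feats, 0.0)

    def test_many_peaks_keeps_first_ten_in_lag_order(self):
        lags = np.arange(61)
        r = 0.5 * np.cos(np.pi * lags / 2) * np.exp(-lags / 100)  # peaks at 4, 8, ...
        feats = baselines.peak_features(AutocorrSeries(r, fps=2.0))
        # brute-force scan: strict local maxima in increasing lag order
        brute = [
            r[l]
            for l in range(1, 60)
            if r[l - 1] < r[l] > r[l + 1]
        ][:10]
        assert len(feats) == 10
        assert np.allclose(feats, brute)

    def test_output_always_length_ten(self):
        rng = np.random.default_rng(0)
        for n in (5, 12, 200):
            feats = baselines.peak_features(
                AutocorrSeries(rng.normal(0, 1, n), fps=2.0)
            )
            assert feats.shape == (10,)


class TestBaseline1Fit:
    @pytest.fixture
    def blobs(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(-2, 0.3, (20, 10))
        x1 = rng.normal(+2, 0.3, (20, 10))
        return np.vstack([x0, x1]), np.repeat([0, 1], 20)

    @pytest.mark.parametrize("name", ["linear-svm", "logistic", "random-forest"])
    def test_separable_clusters_perfect_cv(self, blobs, name):
        x, y = blobs
        clf = baselines.fit_baseline1(x, y, classifier=name, seed=0)
        assert clf.best_score_ == 1.0
        assert np.array_equal(clf.predict(x), y)

    def test_permuted_labels_near_chance(self, blobs):
        x, y = blobs
        y_perm = np.random.default_rng(3).permutation(y)
        clf = baselines.fit_baseline1(x, y_perm, classifier="logistic", seed=0)
        assert abs(clf.best_score_ - 0.5) <= 0.15

    def test_unknown_classifier(self, blobs):
        with pytest.raises(ValueError, match="classifier"):
            baselines.fit_baseline1(*blobs, classifier="mlp")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            baselines.fit_baseline1(np.zeros((10, 3)), np.zeros(10), "logistic")


class TestHistograms:
    def test_zero_frame_all_in_first_bin(self):
        hists = baselines.movement_histograms(_mags(np.zeros((1, 8, 8))))
        assert hists.counts[0, 0] == 64
        assert hists.counts[0, 1:].sum() == 0

    def test_near_cap_value_in_last_bin(self):
        frame = np.full((1, 2, 2), 0.49975, dtype=np.float32)
        hists = baselines.movement_histograms(_mags(frame))
        assert hists.counts[0, -1] == 4

    def test_counts_conserve_pixels(self):
        rng = np.random.default_rng(5)
        mags = _mags(np.clip(rng.normal(0.2, 0.1, (7, 6, 9)), 0, 0.5))
        hists = baselines.movement_histograms(mags)
        assert np.all(hists.counts.sum(axis=1) == 54)
        assert hists.feature.shape == (1000,)
        assert np.allclose(hists.feature, hists.counts.mean(axis=0))


class TestPCA:
    def test_hundred_components(self):
        rng = np.random.default_rng(0)
        pca, proj = baselines.pca_reduce(rng.normal(0, 1, (200, 1000)))
        assert proj.shape == (200, 100)
        gram = pca.components_ @ pca.components_.T
        assert np.allclose(gram, np.eye(100), atol=1e-6)

    def test_reconstruction_error_non_increasing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (60, 40))
        errors = []
        for k in (1, 5, 10, 20, 40):
            pca, proj = baselines.pca_reduce(x, k=k)
            recon = pca.inverse_transform(proj)
            errors.append(np.linalg.norm(x - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_bad_k(self):
        with pytest.raises(ValueError):
            baselines.pca_reduce(np.zeros((5, 5)), k=0)


class TestSpectralImage:
    def test_constant_histograms_are_dc_only(self):
        hists = HistogramSequence(
            counts=np.full((10, 1000), 3.0), feature=np.full(1000, 3.0), fps=2.0
        )
        img = baselines.build_spectral_image(hists)
        total = img.sum()
        off_center = total - img[64, 64]
        assert off_center <= 0.01 * total

    def test_temporal_sinusoid_peaks_at_matching_row(self):
        t = np.arange(64)
        counts = 100 + 50 * np.sin(2 * np.pi * 8 * t / 64)[:, None] * np.ones((1, 1000))
        img = baselines.build_spectral_image(
            HistogramSequence(counts=counts, feature=counts.mean(0), fps=2.0)
        )
        masked = img.copy()
        masked[64, 64] = 0  # ignore DC
        peak = np.unravel_index(np.argmax(masked), masked.shape)
        # 8 cycles across the image stay 8 cycles after the 64 -> 128 resize
        assert peak[1] == 64
        assert peak[0] in (64 - 8, 64 + 8)

    @pytest.mark.parametrize("n_frames", [5, 40, 500])
    def test_output_always_128(self, n_frames):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (n_frames, 1000)).astype(float)
        img = baselines.build_spectral_image(
            HistogramSequence(counts=counts, feature=counts.mean(0), fps=2.0)
        )
        assert img.shape == (128, 128)
        assert np.isfinite(img).all()


class TestBaseline3:
    def test_forward_probability(self):
        net = baselines.build_darknet(width=0.125)
        net.initialize(np.random.default_rng(0))
        img = np.random.default_rng(1).normal(0, 1, (1, 128, 128)).astype(np.float32)
        p = net.predict_proba(img[..., None, None])
        assert p.shape == (1,)
        assert 0.0 < p[0] < 1.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="128"):
            baselines.fit_baseline3_cnn(np.zeros((4, 64, 64)), [0, 0, 1, 1])

    def test_separable_spectra_learned_and_deterministic(self):
        """DC-only (CA-like) vs wide-band (OA-like) spectra are separable."""
        rng = np.random.default_rng(0)
        images, labels = [], []
        for i in range(32):
            ca_like = i % 2 == 1
            img = np.zeros((128, 128), dtype=np.float32)
            img[64, 64] = 10.0
            if not ca_like:  # broadband ring, as breathing effort produces
                img += 2.0 * rng.random((128, 128))
            img += 0.1 * rng.random((128, 128))
            images.append(img)
            labels.append(int(ca_like))
        images, labels = np.stack(images), np.array(labels)
        from apneaflow.nn import TrainConfig

        cfg = baselines.Baseline3Config(
            width=0.125,
            train=TrainConfig(batch_size=8, max_epochs=8, patience=8),
        )
        trained = baselines.fit_baseline3_cnn(images[:24], labels[:24], cfg, seed=0)
        preds = baselines.predict_baseline3(trained, images[24:]) > 0.5
        assert (preds.astype(int) == labels[24:]).mean() >= 0.9
        rerun = baselines.fit_baseline3_cnn(images[:24], labels[:24], cfg, seed=0)
        assert trained.history["loss"] == rerun.history["loss"]
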