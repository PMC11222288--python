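"""Wavelet features, Fisher selection, classifiers, cross-validation."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from pursuitlock import (EpochSet, FeatureSet, PipelineConfig, RLDA,
                         crossvalidate, cwt_band_power, cwt_power_features,
                         fisher_scores, fit_pipeline,
                         greedy_channel_selection, pca_compress,
                         train_classifier)


def feature_set(X, y, n_channels=1, labels=None):
    X = np.asarray(X, float)
    nt = X.shape[1] // n_channels
    return FeatureSet(X, y, labels or [f"ch{i}" for i in range(n_channels)],
                      nt, 200.0)


def toy_epochs(data, fs=200.0, labels=None):
    data = np.asarray(data, float)
    labels = labels if labels is not None else np.ones(data.shape[0], int)
    return EpochSet(data, labels, fs,
                    [f"ch{i}" for i in range(data.shape[1])])


class TestFeatures:
    def test_dimensionality_law(self, rng):
        for ch, sec in ((3, 1.0), (2, 0.5)):
            ep = toy_epochs(rng.normal(size=(2, ch, int(200 * sec))))
            f = cwt_power_features(ep)
            assert f.n_features == ch * int(200 * sec)
            assert (np.bincount(f.feature_channel) == int(200 * sec)).all()

    def test_zero_epoch_gives_zero_features(self):
        f = cwt_power_features(toy_epochs(np.zeros((1, 2, 100))))
        assert not f.X.any()

    def test_in_band_frequency_carries_more_power(self):
        t = np.arange(200) / 200.0
        in_band = np.sin(2 * np.pi * 8 * t)[None, None, :]
        out_band = np.sin(2 * np.pi * 30 * t)[None, None, :]
        p_in = cwt_power_features(toy_epochs(in_band)).X.sum()
        p_out = cwt_power_features(toy_epochs(out_band)).X.sum()
        assert p_in > p_out

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cwt_band_power(np.zeros((1, 100)), 200.0, band_hz=(1.0, 150.0))


def fisher_oracle(X, y):
    """Straight-from-the-definition Fisher score, feature by feature."""
    out = np.empty(X.shape[1])
    n = len(y)
    for i in range(X.shape[1]):
        m = X[:, i].mean()
        sb = sum((y == k).sum() / n * (X[y == k, i].mean() - m) ** 2
                 for k in np.unique(y))
        sw = sum(((X[y == k, i] - X[y == k, i].mean()) ** 2).sum()
                 for k in np.unique(y)) / n
        out[i] = sb / sw
    return out


class TestFisher:
    def test_hand_worked_example(self):
        # class A {0,1}, class B {2,3}: S_B = 1, S_W = 0.25 → J = 4
        f = feature_set([[0.0], [1.0], [2.0], [3.0]], [0, 0, 1, 1])
        j, per_ch = fisher_scores(f)
        assert j[0] == pytest.approx(4.0, abs=1e-9)
        assert per_ch[0] == pytest.approx(4.0, abs=1e-9)

    def test_equal_class_means_score_zero(self):
        f = feature_set([[1.0], [-1.0], [1.0], [-1.0]], [0, 0, 1, 1])
        j, _ = fisher_scores(f)
        assert j[0] == pytest.approx(0.0, abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        j0, _ = fisher_scores(feature_set(X, y, 4))
        j1, _ = fisher_scores(feature_set(X + 7.3, y, 4))
        j2, _ = fisher_scores(feature_set(X * -2.5, y, 4))
        assert np.allclose(j0, j1, atol=1e-9)
        assert np.allclose(j0, j2, rtol=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 10))
            y = np.r_[np.zeros(14, int), np.ones(16, int)]
            j, _ = fisher_scores(feature_set(X, y, 10))
            assert np.allclose(j, fisher_oracle(X, y), atol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fisher_scores(feature_set([[1.0], [2.0]], [1, 1]))


def informative_features(rng, n=48, n_noise=3, nt=5, copy_informative=False):
    """Channel 0 carries the class signal; the rest are pure noise."""
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    sig = rng.normal(size=(n, nt)) * 0.3 + y[:, None] * 2.0
    blocks = [sig] + ([sig.copy()] if copy_informative else [])
    blocks += [rng.normal(size=(n, nt)) for _ in range(n_noise)]
    X = np.hstack(blocks)
    return feature_set(X, y, n_channels=len(blocks)), y


class TestChannelSelection:
    def test_informative_channel_ranked_first_and_kept(self, rng):
        discarded_noise = kept_noise = 0
        for seed in range(5):
            f, _ = informative_features(rng)
            sel = greedy_channel_selection(f, seed=seed)
            assert sel.ranked[0] == 0
            assert 0 in sel.kept
            kept_noise += sum(1 for c in sel.kept if c != 0)
            discarded_noise += sum(1 for c in range(1, 4) if c not in sel.kept)
        assert discarded_noise >= 0.8 * (discarded_noise + kept_noise)

    def test_duplicate_informative_channel_discarded(self, rng):
        f, _ = informative_features(rng, copy_informative=True)
        sel = greedy_channel_selection(f, seed=0)
        assert 0 in sel.kept and 1 not in sel.kept  # copy adds no accuracy

    def test_single_channel_kept_unconditionally(self, rng):
        f, _ = informative_features(rng, n_noise=0)
        sel = greedy_channel_selection(f, seed=0)
        assert sel.kept == [0]

    def test_gate_trace_accuracy_non_decreasing_on_kept(self, rng):
        f, _ = informative_features(rng)
        sel = greedy_channel_selection(f, seed=1)
        kept_accs = [a for _, a, kept in sel.gate_trace if kept]
        assert all(b > a for a, b in zip(kept_accs, kept_accs[1:])) or \
            len(kept_accs) == 1


class TestPca:
    def test_dominant_direction_compressed_to_one_component(self, rng):
        t = rng.normal(size=200)
        X = np.outer(t, [1.0, 0.5]) + rng.normal(size=(200, 2)) * 0.05
        _, pca = pca_compress(X, 0.90)
        assert pca.n_components_ == 1

    def test_threshold_one_keeps_all_components(self, rng):
        X = rng.normal(size=(50, 6))
        _, pca = pca_compress(X, 1.0)
        assert pca.n_components_ == 6

    def test_training_projection_explains_threshold_variance(self, rng):
        X = rng.normal(size=(80, 20))
        _, pca = pca_compress(X, 0.90)
        assert pca.explained_variance_ratio_.sum() >= 0.90

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_compress(np.zeros((1, 5)), 0.9)


class TestClassifiers:
    def _toy(self, rng, n=30):
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(size=(n, 2)) * 0.3 + y[:, None] * np.array([3.0, -2.0])
        return X, y

    def test_all_kinds_fit_separable_data(self, rng):
        X, y = self._toy(rng)
        for kind in ("svm", "rlda", "xgboost"):
            clf = train_classifier(X, y, kind, seed=0)
            assert (clf.predict(X) == y).all()

    def test_rlda_at_zero_shrinkage_matches_lda_oracle(self, rng):
        X, y = self._toy(rng, n=20)
        ours = RLDA(shrinkage=0.0).fit(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        Xq = rng.normal(size=(50, 2)) * 2
        assert (ours.predict(Xq) == sk.predict(Xq)).all()

    def test_rlda_handles_singular_covariance_with_shrinkage(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([0, 0, 1, 1])
        clf = RLDA(shrinkage=0.9).fit(X, y)  # rank-1 scatter
        assert (clf.predict(X) == y).all()

    def test_xgboost_deterministic_given_seed(self, rng):
        X, y = self._toy(rng)
        Xq = rng.normal(size=(40, 2))
        a = train_classifier(X, y, "xgboost", seed=5).predict(Xq)
        b = train_classifier(X, y, "xgboost", seed=5).predict(Xq)
        assert (a == b).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((4, 2)), np.zeros(4, int), "svm")


class TestCrossValidation:
    def test_folds_partition_the_samples(self, rng):
        f, _ = informative_features(rng, n=36)
        rep = crossvalidate(f, "rlda", 6, seed=0)
        all_idx = np.concatenate(rep.test_indices)
        assert sorted(all_idx) == list(range(36))

    def test_metrics_within_bounds_and_separable_data_decodable(self, rng):
        f, _ = informative_features(rng, n=48)
        rep = crossvalidate(f, "svm", 6, seed=0)
        assert 0.9 <= rep.mean_acc <= 1.0
        assert 0 <= rep.mean_fpr <= 0.2

    def test_too_few_samples_per_class_rejected(self, rng):
        f, _ = informative_features(rng, n=8)
        with pytest.raises(ValueError):
            crossvalidate(f, "svm", 6, seed=0)

    def test_training_transforms_blind_to_test_labels(self, rng):
        """Corrupting held-out labels must not change fitted transforms."""
        f, y = informative_features(rng, n=40)
        train = FeatureSet(f.X[:30], f.y[:30], f.channel_labels, f.n_times,
                           f.fs)
        pipe_a = fit_pipeline(train, "svm", seed=0)
        f.y[30:] = 1 - f.y[30:]  # corrupt test labels
        pipe_b = fit_pipeline(train, "svm", seed=0)
        assert np.array_equal(pipe_a.scaler.mean_, pipe_b.scaler.mean_)
        assert np.array_equal(pipe_a.pca.components_, pipe_b.pca.components_)
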