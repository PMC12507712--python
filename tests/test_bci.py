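"""CSP filters, log-variance features, shrinkage LDA, and Monte Carlo CV."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from mi_erd import SimulationConfig, generate_recording, epoch_and_reject
from mi_erd.preprocess import EpochSet
from mi_erd.bci_csp_lda import (
    fit_csp,
    csp_features,
    shrinkage_lda,
    monte_carlo_cv,
    prepare_bci_epochs,
)


def _two_source_epochs(rng, n_trials=40, n_channels=8, n_samples=250,
                       var_a=(4.0, 1.0), var_b=(1.0, 4.0)):
    """Two orthogonal-topography sources whose variances swap between classes."""
    mixing = np.zeros((n_channels, 2))
    mixing[0, 0] = 1.0  # source A projects to channel 0
    mixing[1, 1] = 1.0  # source B projects to channel 1
    data, labels = [], []
    for k in range(n_trials):
        label = "left" if k % 2 == 0 else "right"
        va, vb = var_a if label == "left" else var_b
        s = np.vstack([
            rng.normal(0, np.sqrt(va), n_samples),
            rng.normal(0, np.sqrt(vb), n_samples),
        ])
        noise = rng.normal(0, 0.1, (n_channels, n_samples))
        data.append(mixing @ s + noise)
        labels.append(label)
    t = np.arange(n_samples) / 125.0
    return EpochSet(data=np.stack(data), labels=np.array(labels), time_axis=t,
                    sampling_rate=125.0,
                    channel_names=[f"ch{i}" for i in range(n_channels)])


class TestCSP:
    def test_top_filter_unmixes_the_discriminative_source(self, rng):
        """Applying the top filter recovers the class-modulated source signal."""
        epochs = _two_source_epochs(rng)
        model = fit_csp(epochs)
        # source A lives on channel 0 (identity mixing, low additive noise),
        # so the filtered trace must correlate ~1 with that channel's signal
        corrs = []
        for trial in epochs.data:
            filtered = model.filters[0] @ trial
            corrs.append(abs(np.corrcoef(filtered, trial[0])[0, 1]))
        assert np.mean(corrs) > 0.95

    def test_class_swap_reverses_filter_order(self, rng):
        epochs = _two_source_epochs(rng)
        model = fit_csp(epochs)
        swapped = epochs.select()
        swapped.labels = np.where(epochs.labels == "left", "right", "left")
        model_sw = fit_csp(swapped)
        reordered = np.vstack([model_sw.filters[3:], model_sw.filters[:3]])
        for a, b in zip(model.filters, reordered):
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_identical_classes_give_half_eigenvalues(self, rng):
        epochs = _two_source_epochs(rng, var_a=(1.0, 1.0), var_b=(1.0, 1.0),
                                    n_trials=60)
        model = fit_csp(epochs)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.1)

    def test_two_classes_required(self, rng):
        epochs = _two_source_epochs(rng)
        epochs.labels[:] = "left"
        with pytest.raises(ValueError, match="2 classes"):
            fit_csp(epochs)


class TestFeatures:
    def test_scale_invariance(self, rng):
        epochs = _two_source_epochs(rng)
        model = fit_csp(epochs)
        doubled = epochs.select()
        doubled.data = 2.0 * doubled.data
        np.testing.assert_allclose(csp_features(model, epochs),
                                   csp_features(model, doubled), atol=1e-12)

    def test_deterministic(self, rng):
        epochs = _two_source_epochs(rng)
        model = fit_csp(epochs)
        f1 = csp_features(model, epochs)
        f2 = csp_features(model, epochs)
        np.testing.assert_array_equal(f1, f2)

    def test_separable_classes_separate_on_extreme_filters(self, rng):
        epochs = _two_source_epochs(rng)
        model = fit_csp(epochs)
        feats = csp_features(model, epochs)
        left = feats[epochs.labels == "left"]
        right = feats[epochs.labels == "right"]
        pooled_sd = np.sqrt((left.var(axis=0) + right.var(axis=0)) / 2)
        gap = np.abs(left.mean(axis=0) - right.mean(axis=0)) / pooled_sd
        assert gap[0] >= 1.0 and gap[3] >= 1.0

    def test_channel_mismatch_rejected(self, rng):
        epochs = _two_source_epochs(rng)
        model = fit_csp(epochs)
        other = _two_source_epochs(rng, n_channels=6)
        with pytest.raises(ValueError, match="channel"):
            csp_features(model, other)


class TestShrinkageLDA:
    def test_separable_clouds_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 6)), rng.normal(6, 1, (20, 6))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = shrinkage_lda(x, y)
        assert clf.score(x, y) == 1.0
        assert 0.0 <= clf.shrinkage_intensity <= 1.0

    def test_small_sample_beats_plain_lda_on_average(self, rng):
        """n=8 with 6 features: shrinkage stabilizes the covariance estimate."""
        wins_shrunk, wins_plain = 0.0, 0.0
        for _ in range(100):
            mu = np.zeros(6)
            mu2 = np.full(6, 1.0)
            xtr = np.vstack([rng.normal(mu, 1, (4, 6)), rng.normal(mu2, 1, (4, 6))])
            ytr = np.array(["a"] * 4 + ["b"] * 4)
            xte = np.vstack([rng.normal(mu, 1, (50, 6)), rng.normal(mu2, 1, (50, 6))])
            yte = np.array(["a"] * 50 + ["b"] * 50)
            wins_shrunk += shrinkage_lda(xtr, ytr).score(xte, yte)
            plain = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
            plain.fit(xtr, ytr)
            wins_plain += (plain.predict(xte) == yte).mean()
        assert wins_shrunk / 100 > wins_plain / 100

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            shrinkage_lda(rng.normal(size=(8, 6)), ["a"] * 8)


class TestMonteCarloCV:
    def test_same_seed_identical_result(self, rng):
        epochs = _two_source_epochs(rng)
        r1 = monte_carlo_cv(epochs, seed=3, prepare=False)
        r2 = monte_carlo_cv(epochs, seed=3, prepare=False)
        assert r1.fold_accuracies == r2.fold_accuracies
        assert r1.mean_accuracy == pytest.approx(np.mean(r1.fold_accuracies))

    def test_no_leakage_test_corruption_cannot_change_fit(self, rng):
        """Filters and classifier are functions of the training split only."""
        epochs = _two_source_epochs(rng)
        train = epochs.select()
        train.data = train.data[:30]
        train.labels = train.labels[:30]
        model = fit_csp(train)
        clf = shrinkage_lda(csp_features(model, train), train.labels)
        test = epochs.select()
        test.data = test.data[30:].copy()
        test.labels = test.labels[30:]
        before = model.filters.copy()
        test.data *= 100.0  # corrupt test data after fitting
        np.testing.assert_array_equal(model.filters, before)
        preds = clf.predict(csp_features(model, test))
        assert len(preds) == 10  # classifier unchanged, still applicable

    def test_permuted_labels_near_chance(self, rng):
        epochs = _two_source_epochs(rng, n_trials=30)
        inside = 0
        reps = 20
        for r in range(reps):
            labels = rng.permutation(epochs.labels)
            cv = monte_carlo_cv(epochs, seed=r, prepare=False, labels=labels)
            inside += 0.35 <= cv.mean_accuracy <= 0.65
        assert inside / reps >= 0.80

    def test_accuracy_monotone_in_erd_contrast(self):
        """More contralateral suppression gives more discriminable epochs."""
        accs = {}
        for contrast in (0.0, -20.0, -40.0):
            cfg = SimulationConfig(seed=11, erd_contra_pct=contrast,
                                   erd_ipsi_pct=0.0, alpha_amplitude_uv=12.0,
                                   noise_amplitude_uv=3.0)
            rec, _ = generate_recording(cfg)
            epochs = epoch_and_reject(rec)
            accs[contrast] = monte_carlo_cv(epochs, seed=5).mean_accuracy
        assert accs[-40.0] >= accs[-20.0] - 0.05
        assert accs[-20.0] >= accs[0.0] - 0.10
        assert accs[-40.0] >= 0.85

    def test_too_few_trials_rejected(self, rng):
        epochs = _two_source_epochs(rng, n_trials=6)
        with pytest.raises(ValueError, match=">= 5 trials"):
            monte_carlo_cv(epochs, prepare=False)


def test_prepare_restricts_window_and_band(clean_epochs):
    prepared = prepare_bci_epochs(clean_epochs)
    assert prepared.time_axis.min() >= 1.0
    assert prepared.time_axis.max() < 5.0
    assert prepared.meta["bci_band"] == (8.0, 28.0)
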