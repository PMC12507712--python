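"""Left/right MI discriminability: CSP features + shrinkage LDA + Monte Carlo CV.

Epochs are band-pass filtered 8-28 Hz (alpha + beta) and restricted to the
1-5 s MI window. Common spatial patterns are obtained from per-class,
trial-averaged, trace-normalized covariances: the composite covariance is
whitened, the whitened class covariance eigendecomposed, and the three
eigenvectors from each spectral extreme retained (six filters). Features are
log variance fractions of the filtered signals; classification uses LDA with
Ledoit-Wolf shrinkage of the pooled covariance. Accuracy is estimated by
Monte Carlo cross-validation: 10 seeded stratified 80/20 splits, with CSP and
LDA fitted on the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from .preprocess import EpochSet

__all__ = [
    "CSPModel",
    "CVResult",
    "prepare_bci_epochs",
    "fit_csp",
    "csp_features",
    "shrinkage_lda",
    "monte_carlo_cv",
]

DEFAULT_BAND = (8.0, 28.0)
DEFAULT_WINDOW = (1.0, 5.0)
RIDGE = 1e-6


@dataclass
class CSPModel:
    """Spatial filters (n_filters x channels) sorted by discriminability."""

    filters: np.ndarray
    eigenvalues: np.ndarray
    class_order: tuple
    channel_names: list
    band: tuple = DEFAULT_BAND

    def __post_init__(self):
        if not np.isfinite(self.filters).all():
            raise ValueError("non-finite CSP filters")


@dataclass
class CVResult:
    fold_accuracies: list
    mean_accuracy: float
    test_fraction: float
    n_iterations: int
    seed: int
    meta: dict = field(default_factory=dict)


def prepare_bci_epochs(epochs: EpochSet, band=DEFAULT_BAND,
                       window=DEFAULT_WINDOW) -> EpochSet:
    """Band-pass the epochs and crop to the MI analysis window."""
    import mne

    out = epochs.crop(*window)
    data = mne.filter.filter_data(
        out.data, sfreq=out.sampling_rate, l_freq=band[0], h_freq=band[1],
        phase="zero", verbose="error",
    )
    out.data = data
    out.meta["bci_band"] = tuple(band)
    return out


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Uncentered per-trial channel covariances, trials x ch x ch."""
    return np.einsum("tcs,tds->tcd", data, data) / data.shape[2]


def _fit_csp_from_covs(covs: np.ndarray, labels: np.ndarray, n_filters: int,
                       channel_names) -> CSPModel:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"CSP requires exactly 2 classes; got {classes.tolist()}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"need >= 2 trials of class {c!r}")

    traces = np.trace(covs, axis1=1, axis2=2)
    normed = covs / traces[:, None, None]
    c1 = normed[labels == classes[0]].mean(axis=0)
    c2 = normed[labels == classes[1]].mean(axis=0)
    comp = c1 + c2

    n = comp.shape[0]
    evals, evecs = np.linalg.eigh(comp)
    if evals[-1] <= 0:
        raise ValueError("composite covariance not positive semidefinite")
    # rank tolerance must reject near-null directions (e.g. the common-average
    # reference null space), whose whitened eigenvalues are pure noise
    keep = evals > evals[-1] * 1e-6
    if keep.sum() < max(n_filters, 2):  # rank deficient: ridge and retry once
        comp = comp + RIDGE * np.trace(comp) / n * np.eye(n)
        evals, evecs = np.linalg.eigh(comp)
        keep = evals > evals[-1] * 1e-6
        if keep.sum() < max(n_filters, 2):
            raise ValueError("covariance singular even after ridge regularization")
    whiten = (evecs[:, keep] / np.sqrt(evals[keep])).T  # rank x channels

    s1 = whiten @ c1 @ whiten.T
    w_evals, w_evecs = np.linalg.eigh(s1)  # ascending in [0, 1]
    half = n_filters // 2
    idx = list(range(w_evals.size - 1, w_evals.size - 1 - half, -1)) + list(range(half))
    filters = (w_evecs[:, idx].T @ whiten)

    return CSPModel(
        filters=filters,
        eigenvalues=w_evals[idx],
        class_order=(str(classes[0]), str(classes[1])),
        channel_names=list(channel_names),
    )


def fit_csp(epochs: EpochSet, n_filters: int = 6) -> CSPModel:
    """Fit CSP filters on (already band-passed, MI-window) epochs."""
    covs = _trial_covariances(epochs.data)
    model = _fit_csp_from_covs(covs, epochs.labels, n_filters, epochs.channel_names)
    model.band = epochs.meta.get("bci_band", DEFAULT_BAND)
    return model


def _features_from_covs(model: CSPModel, covs: np.ndarray) -> np.ndarray:
    # variance of the filtered signal equals w C w^T for uncentered covariances
    variances = np.einsum("fc,tcd,fd->tf", model.filters, covs, model.filters)
    if np.any(variances.sum(axis=1) <= 0):
        bad = int(np.flatnonzero(variances.sum(axis=1) <= 0)[0])
        raise ValueError(f"zero-variance trial {bad}: cannot form log-variance features")
    variances = np.maximum(variances, 0.0)  # clip numerical negatives
    fractions = variances / variances.sum(axis=1, keepdims=True)
    return np.log(np.clip(fractions, 1e-300, None))


def csp_features(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Trials x n_filters log variance-fraction feature matrix."""
    if list(epochs.channel_names) != list(model.channel_names):
        raise ValueError("epoch channel set does not match the fitted CSP model")
    return _features_from_covs(model, _trial_covariances(epochs.data))


class ShrinkageLDA:
    """Linear discriminant with Ledoit-Wolf-shrunk pooled covariance."""

    def __init__(self):
        self._lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        self.shrinkage_intensity = None

    def fit(self, features, labels):
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
        if np.unique(labels).size != 2:
            raise ValueError("shrinkage LDA requires exactly 2 classes")
        centered = features.copy()
        for c in np.unique(labels):
            centered[labels == c] -= features[labels == c].mean(axis=0)
        self.shrinkage_intensity = float(ledoit_wolf_shrinkage(centered))
        self._lda.fit(features, labels)
        return self

    def predict(self, features):
        return self._lda.predict(np.asarray(features, dtype=float))

    def score(self, features, labels):
        return float(np.mean(self.predict(features) == np.asarray(labels)))


def shrinkage_lda(features, labels) -> ShrinkageLDA:
    """Fit a shrinkage-LDA classifier; returns an object with ``predict``."""
    return ShrinkageLDA().fit(features, labels)


def monte_carlo_cv(epochs: EpochSet, n_iterations: int = 10,
                   test_fraction: float = 0.2, seed: int = 0,
                   n_filters: int = 6, band=DEFAULT_BAND,
                   window=DEFAULT_WINDOW, prepare: bool = True,
                   labels=None) -> CVResult:
    """Monte Carlo cross-validated CSP + shrinkage-LDA accuracy.

    Each of the ``n_iterations`` seeded folds draws a stratified
    ``test_fraction`` test split; CSP filters and the LDA are fitted on the
    training split only. ``labels`` overrides the epoch labels (e.g. for
    permutation calibration) without touching the data. Set ``prepare=False``
    if the epochs are already band-passed and cropped to the MI window.
    """
    if prepare:
        epochs = prepare_bci_epochs(epochs, band=band, window=window)
    y = np.asarray(labels if labels is not None else epochs.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 5:
        raise ValueError("need two classes with >= 5 trials each")

    covs = _trial_covariances(epochs.data)
    splitter = StratifiedShuffleSplit(
        n_splits=n_iterations, test_size=test_fraction, random_state=seed
    )
    accuracies = []
    for train, test in splitter.split(np.zeros(y.size), y):
        if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
            warnings.warn("degenerate split encountered; redrawn")
            continue
        model = _fit_csp_from_covs(covs[train], y[train], n_filters,
                                   epochs.channel_names)
        clf = shrinkage_lda(_features_from_covs(model, covs[train]), y[train])
        accuracies.append(clf.score(_features_from_covs(model, covs[test]), y[test]))

    return CVResult(
        fold_accuracies=[float(a) for a in accuracies],
        mean_accuracy=float(np.mean(accuracies)),
        test_fraction=test_fraction,
        n_iterations=n_iterations,
        seed=seed,
        meta={"n_trials": int(y.size), "band": tuple(band), "window": tuple(window)},
    )
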