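"""Offline decoding of target vs nontarget epochs.

Feature path: per-channel z-scored epochs → continuous wavelet transform
(complex Morlet) over 1–13 Hz → power summed across in-band scales at each
time sample, giving one value per time sample per channel (200 per channel
at the 1-s/200 Hz defaults), concatenated across channels. Channel
selection ranks channels by Fisher score

    J(i) = S_B(i) / S_W(i),
    S_B(i) = Σ_k (n_k/n)(m̄_{k,i} − m̄_i)²,
    S_W(i) = (1/n) Σ_k Σ_j (x_{k,j,i} − m̄_{k,i})²,

and greedily keeps a channel only when it strictly improves the accuracy
of an SVM gate. Features are then compressed by PCA (90% explained
variance) and classified by SVM (RBF, γ=0.05, C=1), RLDA (shrinkage
λ=0.9, implemented here), or XGBoost (20 dart trees, depth 10, η=0.1),
evaluated by stratified 6-fold cross-validation with every fit confined to
the training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig
from .preprocess import EpochSet

log = logging.getLogger(__name__)

_CWT_WAVELET = "cmor1.5-1.0"
_FISHER_EPS = 1e-12  # guards zero within-class variance


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Flattened time-frequency features: ``n_samples × n_features``.

    ``feature_channel[j]`` maps feature column j back to its channel;
    every channel contributes ``n_times`` consecutive columns.
    """

    X: np.ndarray
    y: np.ndarray
    channel_labels: list[str]
    n_times: int
    fs: float
    feature_channel: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match label count")
        if self.X.shape[1] != len(self.channel_labels) * self.n_times:
            raise ValueError("n_features must equal n_channels × n_times")
        if self.feature_channel is None:
            self.feature_channel = np.repeat(
                np.arange(len(self.channel_labels)), self.n_times)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_channels(self, channel_idx) -> "FeatureSet":
        channel_idx = list(channel_idx)
        mask = np.isin(self.feature_channel, channel_idx)
        return FeatureSet(self.X[:, mask], self.y,
                          [self.channel_labels[i] for i in channel_idx],
                          self.n_times, self.fs)


def zscore_epochs(epochs: np.ndarray) -> np.ndarray:
    """z-score per channel per epoch; zero-variance channels become zeros."""
    mean = epochs.mean(axis=-1, keepdims=True)
    sd = epochs.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (epochs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def cwt_band_power(sig: np.ndarray, fs: float, band_hz: tuple = (1.0, 13.0),
                   freq_step_hz: float = 0.5) -> np.ndarray:
    """Sum of squared CWT magnitude across in-band scales, per time sample.

    ``sig`` is ``channels × samples``; returns the same shape. Scales are
    chosen so the Morlet centre frequencies tile ``band_hz`` with at least
    one voice per ``freq_step_hz``.
    """
    lo, hi = band_hz
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band must lie inside (0, Nyquist)")
    freqs = np.arange(lo, hi + 1e-9, freq_step_hz)
    scales = pywt.frequency2scale(_CWT_WAVELET, freqs / fs)
    coefs, _ = pywt.cwt(sig, scales, _CWT_WAVELET, axis=-1)
    return (np.abs(coefs) ** 2).sum(axis=0)


def cwt_power_features(epochs: EpochSet, band_hz: tuple = (1.0, 13.0),
                       freq_step_hz: float = 0.5) -> FeatureSet:
    """Time-frequency feature vectors for every epoch (see module docs)."""
    z = zscore_epochs(epochs.epochs)
    n, ch, nt = z.shape
    X = np.empty((n, ch * nt))
    for e in range(n):
        X[e] = cwt_band_power(z[e], epochs.fs, band_hz, freq_step_hz).ravel()
    return FeatureSet(X, epochs.labels, list(epochs.channel_labels),
                      nt, epochs.fs)


# --------------------------------------------------------------------------
# Fisher scores and channel selection
# --------------------------------------------------------------------------

def fisher_scores(features: FeatureSet, reduce: str = "mean"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature and per-channel Fisher scores J = S_B / S_W.

    The per-channel score aggregates that channel's feature scores by
    ``reduce`` ("mean" default, "max" selectable).
    """
    X, y = features.X, features.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Fisher score needs two classes")
    n = y.size
    m = X.mean(axis=0)
    sb = np.zeros(X.shape[1])
    sw = np.zeros(X.shape[1])
    for k in classes:
        Xk = X[y == k]
        mk = Xk.mean(axis=0)
        sb += (Xk.shape[0] / n) * (mk - m) ** 2
        sw += ((Xk - mk) ** 2).sum(axis=0) / n
    j = sb / (sw + _FISHER_EPS)
    nch = len(features.channel_labels)
    per_channel = np.empty(nch)
    for c in range(nch):
        jc = j[features.feature_channel == c]
        per_channel[c] = jc.max() if reduce == "max" else jc.mean()
    return j, per_channel


@dataclass
class ChannelSelection:
    """Fisher ranking plus the greedily kept subset and its gate trace."""

    ranked: list[int]                 # channel indices, descending score
    scores: np.ndarray                # per-channel Fisher scores
    kept: list[int]
    gate_trace: list[tuple[str, float, bool]]  # (label, gate acc, kept?)
    channel_labels: list[str]


def _gate_accuracy(X: np.ndarray, y: np.ndarray, config: PipelineConfig,
                   seed: int) -> float:
    folds = min(5, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few samples per class for the gate")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = SVC(kernel="rbf", gamma=config.svm_gamma, C=config.svm_C)
    return float(cross_val_score(clf, X, y, cv=cv).mean())


def greedy_channel_selection(features: FeatureSet,
                             config: PipelineConfig | None = None,
                             seed: int = 0) -> ChannelSelection:
    """Fisher-ranked, accuracy-gated channel subset selection.

    Channels are visited in descending Fisher-score order (ties broken by
    channel index) and a channel joins the feature space only if the SVM
    gate's internal stratified cross-validation accuracy strictly exceeds
    the best seen so far. The first (top-ranked) channel is always kept.
    """
    config = config or PipelineConfig()
    _, per_channel = fisher_scores(features, config.channel_fisher_reduce)
    order = np.argsort(-per_channel, kind="stable")
    ranked = [int(i) for i in order]
    kept: list[int] = []
    trace: list[tuple[str, float, bool]] = []
    best = -np.inf
    for c in ranked:
        candidate = kept + [c]
        mask = np.isin(features.feature_channel, candidate)
        try:
            acc = _gate_accuracy(features.X[:, mask], features.y, config, seed)
        except Exception as exc:  # noqa: BLE001 - degenerate block
            log.warning("gate failed on channel %s (%s); skipped",
                        features.channel_labels[c], exc)
            continue
        take = acc > best
        if take:
            kept.append(c)
            best = acc
        trace.append((features.channel_labels[c], acc, take))
    log.info("channel selection kept %d/%d channels (gate acc %.3f)",
             len(kept), len(ranked), best)
    return ChannelSelection(ranked, per_channel, kept, trace,
                            list(features.channel_labels))


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def pca_compress(X_train: np.ndarray, variance_threshold: float = 0.90
                 ) -> tuple[np.ndarray, PCA]:
    """Fit PCA on training samples; keep the smallest component count whose
    cumulative explained variance reaches the threshold."""
    if X_train.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance threshold must be in (0, 1]")
    n_comp = (None if variance_threshold == 1.0
              else variance_threshold)
    pca = PCA(n_components=n_comp, svd_solver="full")
    Xc = pca.fit_transform(X_train)
    return Xc, pca


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------

class RLDA:
    """Regularized linear discriminant analysis.

    The pooled within-class covariance is shrunk toward a scaled identity,
    ``Σ(λ) = (1 − λ) Σ̂ + λ (tr Σ̂ / d) I``, and classification uses the
    linear discriminant rule with empirical class priors. ``λ = 0`` is
    plain LDA; any ``λ > 0`` guarantees a non-singular covariance.
    """

    def __init__(self, shrinkage: float = 0.9):
        if not 0 <= shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need two classes")
        n, d = X.shape
        self.means_ = np.stack([X[y == k].mean(axis=0) for k in self.classes_])
        self.priors_ = np.array([(y == k).mean() for k in self.classes_])
        scatter = np.zeros((d, d))
        for k, mu in zip(self.classes_, self.means_):
            Xc = X[y == k] - mu
            scatter += Xc.T @ Xc
        cov = scatter / n
        lam = self.shrinkage
        cov = (1 - lam) * cov + lam * (np.trace(cov) / d) * np.eye(d)
        try:
            self._coef = np.linalg.solve(cov, self.means_.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular covariance; use shrinkage > 0") from exc
        self._intercept = (-0.5 * np.einsum("kd,kd->k", self.means_, self._coef)
                           + np.log(self.priors_))
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self._coef.T + self._intercept

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def train_classifier(X: np.ndarray, y: np.ndarray, kind: str,
                     config: PipelineConfig | None = None, seed: int = 0):
    """Fit one of the three supported classifiers with the default
    hyperparameters (overridable through the config)."""
    config = config or PipelineConfig()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain two classes")
    if kind == "svm":
        clf = SVC(kernel="rbf", gamma=config.svm_gamma, C=config.svm_C,
                  random_state=seed)
    elif kind == "rlda":
        clf = RLDA(shrinkage=config.rlda_lambda)
    elif kind == "xgboost":
        from xgboost import XGBClassifier
        clf = XGBClassifier(n_estimators=config.xgb_n_estimators,
                            learning_rate=config.xgb_learning_rate,
                            booster=config.xgb_booster,
                            max_depth=config.xgb_max_depth,
                            random_state=seed, n_jobs=1,
                            eval_metric="logloss")
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return clf.fit(X, y)


# --------------------------------------------------------------------------
# fitted pipeline and cross-validation
# --------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """Training-fold transforms + classifier, applied as one unit.

    PCA components are re-standardized after projection so the fixed RBF
    kernel width (γ = 0.05) operates on a scale-free space; without this
    the kernel degenerates when the raw wavelet-power scale is large.
    """

    kind: str
    scaler: StandardScaler
    pca: PCA | None
    post_scaler: StandardScaler | None
    clf: object
    selection: ChannelSelection | None
    feature_mask: np.ndarray | None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mask is not None:
            X = X[:, self.feature_mask]
        X = self.scaler.transform(X)
        if self.pca is not None:
            X = self.pca.transform(X)
        if self.post_scaler is not None:
            X = self.post_scaler.transform(X)
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.clf.predict(self.transform(X)))


def fit_pipeline(features: FeatureSet, kind: str = "svm",
                 config: PipelineConfig | None = None, seed: int = 0,
                 channel_selection: bool = False,
                 use_pca: bool = True) -> FittedPipeline:
    """Fit selection → standardization → PCA → classifier on the given
    (training) samples only."""
    config = config or PipelineConfig()
    selection = None
    mask = None
    X = features.X
    if channel_selection:
        selection = greedy_channel_selection(features, config, seed)
        mask = np.isin(features.feature_channel, selection.kept)
        X = X[:, mask]
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    pca = None
    post_scaler = None
    if use_pca:
        _, pca = pca_compress(Xs, config.pca_variance)
        Xs = pca.transform(Xs)
        post_scaler = StandardScaler().fit(Xs)
        Xs = post_scaler.transform(Xs)
    clf = train_classifier(Xs, features.y, kind, config, seed)
    return FittedPipeline(kind, scaler, pca, post_scaler, clf, selection, mask)


@dataclass
class DecodeReport:
    """Fold-wise and mean Acc/TPR/FPR for one classifier."""

    classifier: str
    acc: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    seed: int
    hyper: dict
    test_indices: list = field(default_factory=list)

    @property
    def mean_acc(self) -> float:
        return float(self.acc.mean())

    @property
    def sd_acc(self) -> float:
        return float(self.acc.std(ddof=0))

    @property
    def mean_tpr(self) -> float:
        return float(self.tpr.mean())

    @property
    def mean_fpr(self) -> float:
        return float(self.fpr.mean())

    def summary(self) -> dict:
        return {"classifier": self.classifier, "mean_acc": self.mean_acc,
                "sd_acc": self.sd_acc, "mean_tpr": self.mean_tpr,
                "mean_fpr": self.mean_fpr, "seed": self.seed}


def _fold_metrics(y_true, y_pred) -> tuple[float, float, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float((y_true == y_pred).mean())
    pos = y_true == 1
    neg = ~pos
    tpr = float((y_pred[pos] == 1).mean()) if pos.any() else float("nan")
    fpr = float((y_pred[neg] == 1).mean()) if neg.any() else float("nan")
    return acc, tpr, fpr


def crossvalidate(features: FeatureSet, kind: str = "svm",
                  k_folds: int = 6, seed: int = 0,
                  config: PipelineConfig | None = None,
                  channel_selection: bool = False,
                  use_pca: bool = True) -> DecodeReport:
    """Stratified k-fold cross-validation with no leakage.

    All fitting — channel selection, feature standardization, PCA and the
    classifier — happens inside each training fold; the held-out fold is
    only transformed and scored.
    """
    config = config or PipelineConfig()
    counts = np.bincount(features.y)
    if counts[counts > 0].min() < k_folds:
        raise ValueError(f"need ≥ {k_folds} samples per class")
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs, tprs, fprs, tests = [], [], [], []
    for tr, te in cv.split(features.X, features.y):
        train = FeatureSet(features.X[tr], features.y[tr],
                           list(features.channel_labels), features.n_times,
                           features.fs)
        pipe = fit_pipeline(train, kind, config, seed,
                            channel_selection=channel_selection,
                            use_pca=use_pca)
        pred = pipe.predict(features.X[te])
        a, t, f = _fold_metrics(features.y[te], pred)
        accs.append(a)
        tprs.append(t)
        fprs.append(f)
        tests.append(te)
    hyper = {"svm": {"gamma": config.svm_gamma, "C": config.svm_C},
             "rlda": {"lambda": config.rlda_lambda},
             "xgboost": {"n_estimators": config.xgb_n_estimators,
                         "learning_rate": config.xgb_learning_rate,
                         "booster": config.xgb_booster,
                         "max_depth": config.xgb_max_depth}}[kind]
    return DecodeReport(kind, np.array(accs), np.array(tprs), np.array(fprs),
                        seed, hyper, tests)
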