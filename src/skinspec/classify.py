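"""Per-channel feature extraction, classification and cross-validation.

Each of the 24 channels is an independent classification pipeline: class
balancing by downsampling to the smallest class, stratified k-fold
cross-validation (default k=5), dimensionality reduction fitted on the
training folds only (PCA, default 15 components, or a 3-hidden-layer
autoencoder 80/40/80), and an SVM / MLP / LDA classifier.  The whole
sequence, starting from the random balancing draw, is repeated (default 5
times) and the across-repeat accuracy SD is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC

from .datamodel import ConfigError


@dataclass(frozen=True)
class FeatureSpec:
    method: str = "pca"  # pca | autoencoder
    n_components: int = 15
    hidden: tuple = (80, 40, 80)
    activation: str = "relu"
    solver: str = "adam"
    max_iter: int = 400

    def __post_init__(self) -> None:
        if self.method not in ("pca", "autoencoder"):
            raise ConfigError(f"unknown feature method {self.method!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"  # svm | mlp | lda
    kernel: str = "linear"
    C: float = 1.0
    degree: int = 2
    decision_shape: str = "ovr"
    hidden: tuple = (80,)
    max_iter: int = 800

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "mlp", "lda"):
            raise ConfigError(f"unknown classifier {self.kind!r}")


@dataclass
class CvConfig:
    k: int = 5
    n_repeats: int = 5
    seed: int = 0
    feature: FeatureSpec | list = field(default_factory=FeatureSpec)
    classifier: ClassifierSpec | list = field(default_factory=ClassifierSpec)
    clamp_components: bool = True
    store_scores: bool = True


def balance_classes(labels, seed: int) -> np.ndarray:
    """Downsample every class without replacement to the smallest class count.

    Returns sorted indices; a pure function of (labels, seed).  An already
    balanced input returns the identity subset.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ConfigError("balancing requires at least 2 classes")
    if counts.min() == 0:
        raise ConfigError("a class has 0 samples")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if count > m:
            idx = rng.choice(idx, size=m, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of k disjoint folds, stratified by class."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ConfigError(
            f"every class needs >= k={k} samples for stratified folds "
            f"(smallest has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    folds = np.empty(labels.size, dtype=int)
    for f, (_tr, te) in enumerate(skf.split(np.zeros((labels.size, 1)), labels)):
        folds[te] = f
    return folds


# --- feature extraction -------------------------------------------------------

_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


class AutoencoderTransform:
    """Symmetric autoencoder; the encoder output is the bottleneck activation.

    Trained to reconstruct its (mean-centered) input with squared-error loss;
    the transform propagates inputs up to the narrowest hidden layer.
    """

    def __init__(self, hidden=(80, 40, 80), activation="relu", solver="adam",
                 max_iter=400, seed=0):
        self.hidden = tuple(hidden)
        self.activation = activation
        self.solver = solver
        self.max_iter = max_iter
        self.seed = int(seed) % (2**31)
        self._net: MLPRegressor | None = None
        self._mean: np.ndarray | None = None

    @property
    def bottleneck_index(self) -> int:
        return int(np.argmin(self.hidden))

    def fit(self, X: np.ndarray) -> "AutoencoderTransform":
        X = np.asarray(X, dtype=float)
        self._mean = X.mean(axis=0)
        Xc = X - self._mean
        self._net = MLPRegressor(
            hidden_layer_sizes=self.hidden,
            activation=self.activation,
            solver=self.solver,
            max_iter=self.max_iter,
            random_state=self.seed,
            tol=1e-6,
        )
        self._net.fit(Xc, Xc)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("autoencoder is not fitted")
        act = _ACTIVATIONS[self._net.activation]
        h = np.asarray(X, dtype=float) - self._mean
        for i in range(self.bottleneck_index + 1):
            h = act(h @ self._net.coefs_[i] + self._net.intercepts_[i])
        return h

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self._net.activation]
        h = np.asarray(X, dtype=float) - self._mean
        n_layers = len(self._net.coefs_)
        for i in range(n_layers):
            h = h @ self._net.coefs_[i] + self._net.intercepts_[i]
            if i < n_layers - 1:
                h = act(h)
        return h + self._mean


def extract_features(
    train: np.ndarray,
    test: np.ndarray,
    spec: FeatureSpec,
    seed: int = 0,
    clamp: bool = False,
):
    """Fit the dimensionality reduction on ``train`` only and project both sets."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] == 0:
        raise ConfigError("empty training set")
    if spec.method == "pca":
        feasible = min(train.shape)
        n = spec.n_components
        if n > feasible:
            if not clamp:
                raise ConfigError(
                    f"n_components={n} exceeds feasible maximum {feasible}"
                )
            n = feasible
        pca = PCA(n_components=n, svd_solver="full")
        ftr = pca.fit_transform(train)
        fte = pca.transform(test)
        return ftr, fte, pca
    ae = AutoencoderTransform(
        spec.hidden, spec.activation, spec.solver, spec.max_iter, seed
    ).fit(train)
    return ae.transform(train), ae.transform(test), ae


# --- classifiers ----------------------------------------------------------------

def make_classifier(spec: ClassifierSpec, seed: int = 0):
    if spec.kind == "svm":
        return SVC(
            kernel=spec.kernel,
            C=spec.C,
            degree=spec.degree,
            decision_function_shape=spec.decision_shape,
            random_state=int(seed) % (2**31),
        )
    if spec.kind == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=spec.hidden,
            max_iter=spec.max_iter,
            random_state=int(seed) % (2**31),
        )
    return LinearDiscriminantAnalysis()


def _class_scores(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """(n, n_classes) score matrix aligned to ``classes`` order."""
    if hasattr(clf, "decision_function"):
        d = clf.decision_function(X)
        if d.ndim == 1:
            d = np.column_stack([-d, d])
    else:
        d = clf.predict_proba(X)
    out = np.zeros((X.shape[0], classes.size))
    for j, cls in enumerate(clf.classes_):
        out[:, np.flatnonzero(classes == cls)[0]] = d[:, j]
    return out


def _standardize(ftr: np.ndarray, fte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale features on the training statistics.

    Components with (near-)zero training variance — e.g. principal components
    beyond the data's numerical rank — are centered but left unscaled, so
    numerical noise in degenerate directions is not amplified.
    """
    mu = ftr.mean(axis=0)
    sd = ftr.std(axis=0)
    floor = 1e-8 * max(float(sd.max()), 1.0)
    sd = np.where(sd > floor, sd, 1.0)
    return (ftr - mu) / sd, (fte - mu) / sd


# --- cross-validation -----------------------------------------------------------

def make_fold_plan(y, cfg: CvConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per repeat: (balanced index subset, fold id per subset element).

    Repeat r draws from seed + r, so the whole plan is a pure function of
    (y, cfg.seed).
    """
    y = np.asarray(y)
    plan = []
    for r in range(cfg.n_repeats):
        sub = balance_classes(y, cfg.seed + r)
        folds = stratified_folds(y[sub], cfg.k, cfg.seed + r)
        plan.append((sub, folds))
    return plan


def _run_combo(X, y, sample_ids, cfg, fspec, cspec, plan, normalizer, classes):
    rows = []
    rep_accs = []
    for r, (sub, folds) in enumerate(plan):
        hits = 0
        total = 0
        for f in range(cfg.k):
            te = sub[folds == f]
            tr = sub[folds != f]
            if np.unique(y[tr]).size < 2 or te.size == 0:
                raise ConfigError("degenerate single-class fold")
            Xtr, Xte = X[tr], X[te]
            if normalizer is not None:
                Xtr, Xte = normalizer(Xtr, Xte, sample_ids[tr], sample_ids[te])
            ftr, fte, _ = extract_features(
                Xtr, Xte, fspec, seed=cfg.seed + r, clamp=cfg.clamp_components
            )
            # standardize features on the training fold: detector units are
            # arbitrary and scale-sensitive classifiers (SVM margin, MLP)
            # otherwise depend on the channel's intensity scale
            ftr, fte = _standardize(ftr, fte)
            clf = make_classifier(cspec, seed=cfg.seed + r).fit(ftr, y[tr])
            pred = clf.predict(fte)
            scores = (
                _class_scores(clf, fte, classes) if cfg.store_scores else None
            )
            hits += int((pred == y[te]).sum())
            total += te.size
            for i, abs_i in enumerate(te):
                row = {
                    "sample_id": sample_ids[abs_i],
                    "repeat": r,
                    "fold": f,
                    "truth": y[abs_i],
                    "pred": pred[i],
                }
                if scores is not None:
                    for j, cls in enumerate(classes):
                        row[f"score_{cls}"] = scores[i, j]
                rows.append(row)
        rep_accs.append(hits / total)
    return pd.DataFrame(rows), np.asarray(rep_accs)


def crossvalidate_channel(
    X,
    y,
    cfg: CvConfig,
    sample_ids=None,
    normalizer=None,
    fold_plan=None,
):
    """Cross-validate one channel, optionally selecting hyperparameters.

    ``cfg.feature`` / ``cfg.classifier`` may be lists; every combination is
    evaluated by its mean out-of-fold accuracy over all repeats and the best
    one (ties to the earliest = simplest candidate) provides the returned
    decision table.  ``normalizer(Xtr, Xte, train_ids, test_ids)`` lets the
    caller inject fold-dependent normalization without leaking test samples.

    Returns ``(decision_table, metrics)`` where the table holds one
    out-of-fold prediction per (sample, repeat).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if sample_ids is None:
        sample_ids = np.array([str(i) for i in range(y.size)])
    else:
        sample_ids = np.asarray(sample_ids)
    classes = np.unique(y)
    plan = fold_plan if fold_plan is not None else make_fold_plan(y, cfg)

    fspecs = cfg.feature if isinstance(cfg.feature, list) else [cfg.feature]
    cspecs = cfg.classifier if isinstance(cfg.classifier, list) else [cfg.classifier]

    best = None
    for fspec in fspecs:
        for cspec in cspecs:
            table, rep_accs = _run_combo(
                X, y, sample_ids, cfg, fspec, cspec, plan, normalizer, classes
            )
            mean_acc = float(rep_accs.mean())
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, table, rep_accs, fspec, cspec)

    mean_acc, table, rep_accs, fspec, cspec = best
    metrics = {
        "accuracy_mean": mean_acc,
        "accuracy_sd": float(rep_accs.std(ddof=0)),
        "per_repeat_accuracy": rep_accs.tolist(),
        "feature": fspec,
        "classifier": cspec,
        "n_samples": int(len(plan[0][0])),
    }
    return table, metrics
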