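"""Classifiers for closed-set subject identification on fused EEG features.

The deep model is a 1-D CNN: three convolutional blocks with 64, 128 and
256 filters, each followed by batch normalization, ReLU and dropout (rates
0.2/0.2/0.4), max pooling after blocks 2 and 3 only, then dense layers of
256 and 128 units (ReLU, dropout 0.3) and a softmax output over the
enrolled subjects. It trains with Adam (lr 0.001), batch size 16, up to
1000 epochs with patience-15 early stopping on an internal stratified
validation split, restoring the best weights. Kernel size 3, pool size 2
and "same" padding are configurable defaults.

Seven classical baselines (SVM, random forest, gradient boosting, k-NN,
decision tree, Gaussian naive Bayes, logistic regression) come from
scikit-learn with fixed hyperparameters. All models see per-feature
z-scored inputs; the standardizer is fit on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import nn

CLASSICAL_KINDS = ("svm", "rf", "gb", "knn", "dt", "nb", "lr")


@dataclass
class CNNSpec:
    """Architecture and training regime of the 1-D CNN."""

    conv_filters: tuple[int, ...] = (64, 128, 256)
    conv_dropout: tuple[float, ...] = (0.2, 0.2, 0.4)
    pool_after: tuple[bool, ...] = (False, True, True)
    kernel_size: int = 5
    pool_size: int = 2
    dense_units: tuple[int, ...] = (256, 128)
    dense_dropout: float = 0.3
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 1000
    patience: int = 15
    val_frac: float = 0.2

    def __post_init__(self) -> None:
        # non-default stacks are allowed for toy problems; the defaults are
        # the canonical three-block 64/128/256 architecture
        if not (len(self.conv_filters) == len(self.conv_dropout)
                == len(self.pool_after)):
            raise ValueError("conv block lists must have equal lengths")


@dataclass
class ClassicalSpec:
    """One of the seven fixed-hyperparameter classical classifiers."""

    kind: str
    overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSICAL_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self, seed: int | None = None):
        o = self.overrides
        if self.kind == "svm":
            return SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                       random_state=seed, **o)
        if self.kind == "rf":
            return RandomForestClassifier(n_estimators=100, criterion="gini",
                                          max_depth=None, random_state=seed, **o)
        if self.kind == "gb":
            return GradientBoostingClassifier(n_estimators=100,
                                              learning_rate=0.1,
                                              random_state=seed, **o)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=5, metric="euclidean", **o)
        if self.kind == "dt":
            return DecisionTreeClassifier(criterion="gini", max_depth=None,
                                          random_state=seed, **o)
        if self.kind == "nb":
            return GaussianNB(**o)
        # L2 penalty is the sklearn default
        return LogisticRegression(tol=1e-4, solver="lbfgs",
                                  max_iter=2000, random_state=seed, **o)


@dataclass
class TrainedModel:
    """A fitted classifier plus its standardizer and class list."""

    kind: str
    model: Any
    classes: np.ndarray
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    n_features: int
    history: pd.DataFrame | None = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_std


def stratified_split(X: np.ndarray, y: np.ndarray, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test index split.

    Per class, the train fraction is within one sample of ``train_frac``;
    the index sets are disjoint and cover all samples.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_frac, stratify=y,
                              random_state=seed)
    return np.sort(tr), np.sort(te)


def build_cnn(n_classes: int, input_len: int = 287,
              spec: CNNSpec | None = None, seed: int = 0) -> "CNNClassifier":
    """Instantiate the (untrained) CNN for ``n_classes`` subjects."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if input_len < 8:
        raise ValueError("input too short for the conv/pool stack")
    return CNNClassifier(n_classes=n_classes, input_len=input_len,
                         spec=spec or CNNSpec(), seed=seed)


class CNNClassifier:
    """The numpy 1-D CNN with the study's training regime."""

    def __init__(self, n_classes: int, input_len: int, spec: CNNSpec,
                 seed: int = 0):
        self.spec = spec
        self.n_classes = n_classes
        self.input_len = input_len
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.net, self.layer_summary = self._build(self.rng)
        self.history: pd.DataFrame | None = None

    def _build(self, rng: np.random.Generator
               ) -> tuple[nn.Sequential, list[tuple[str, dict]]]:
        s = self.spec
        layers: list[nn.Layer] = []
        summary: list[tuple[str, dict]] = []
        in_ch, length = 1, self.input_len
        for filt, drop, pool in zip(s.conv_filters, s.conv_dropout,
                                    s.pool_after):
            layers.append(nn.Conv1D(in_ch, filt, s.kernel_size, rng))
            summary.append(("conv1d", {"filters": filt,
                                       "kernel": s.kernel_size,
                                       "padding": "same"}))
            layers.append(nn.BatchNorm1D(filt))
            summary.append(("batch_norm", {"channels": filt}))
            layers.append(nn.ReLU())
            summary.append(("relu", {}))
            layers.append(nn.Dropout(drop, self.rng))
            summary.append(("dropout", {"rate": drop}))
            if pool:
                layers.append(nn.MaxPool1D(s.pool_size))
                summary.append(("max_pool", {"size": s.pool_size}))
                length //= s.pool_size
            in_ch = filt
        layers.append(nn.Flatten())
        summary.append(("flatten", {}))
        width = in_ch * length
        for units in s.dense_units:
            layers.append(nn.Dense(width, units, rng))
            summary.append(("dense", {"units": units, "activation": "relu"}))
            layers.append(nn.ReLU())
            layers.append(nn.Dropout(s.dense_dropout, self.rng))
            summary.append(("dropout", {"rate": s.dense_dropout}))
            width = units
        layers.append(nn.Dense(width, self.n_classes, rng, gain=1.0))
        summary.append(("dense", {"units": self.n_classes,
                                  "activation": "softmax"}))
        return nn.Sequential(layers), summary

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def fit(self, X: np.ndarray, y_idx: np.ndarray) -> "CNNClassifier":
        """Train with Adam + early stopping on an internal stratified split.

        ``y_idx`` holds integer class indices. Per-epoch train/validation
        loss and accuracy are recorded in ``self.history``.
        """
        s = self.spec
        tr, va = train_test_split(np.arange(len(y_idx)),
                                  train_size=1 - s.val_frac, stratify=y_idx,
                                  random_state=self.seed)
        Xtr, ytr = X[tr], y_idx[tr]
        Xva, yva = X[va], y_idx[va]
        opt = nn.Adam(self.net, lr=s.lr)
        best_loss, best_state, best_epoch = np.inf, self.net.state(), 0
        rows = []
        for epoch in range(1, s.max_epochs + 1):
            order = self.rng.permutation(len(ytr))
            for start in range(0, len(order), s.batch_size):
                b = order[start : start + s.batch_size]
                logits = self.net.forward(Xtr[b], training=True)
                _, dz = nn.cross_entropy_loss(nn.softmax(logits), ytr[b])
                self.net.backward(dz)
                opt.step()
            tr_loss, tr_acc = self._evaluate(Xtr, ytr)
            va_loss, va_acc = self._evaluate(Xva, yva)
            rows.append({"epoch": epoch, "train_loss": tr_loss,
                         "train_acc": tr_acc, "val_loss": va_loss,
                         "val_acc": va_acc})
            if va_loss < best_loss:
                best_loss, best_state, best_epoch = va_loss, self.net.state(), epoch
            elif epoch - best_epoch >= s.patience:
                break
        self.net.load_state(best_state)
        self.history = pd.DataFrame(rows)
        return self

    def _evaluate(self, X: np.ndarray, y_idx: np.ndarray
                  ) -> tuple[float, float]:
        probs = self.predict_proba(X)
        loss, _ = nn.cross_entropy_loss(probs, y_idx)
        acc = float((probs.argmax(axis=1) == y_idx).mean())
        return loss, acc

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.net.forward(X, training=False))


def count_trainable_parameters(model: Any) -> int:
    """Element count of all trainable tensors (BN scale/shift included,
    running statistics excluded)."""
    if isinstance(model, TrainedModel):
        model = model.model
    if isinstance(model, CNNClassifier):
        return model.n_parameters()
    if isinstance(model, nn.Sequential):
        return model.n_parameters()
    raise TypeError(f"cannot count parameters of {type(model).__name__}")


def train_classifier(X: np.ndarray, y: np.ndarray,
                     spec: CNNSpec | ClassicalSpec | str, seed: int = 0
                     ) -> TrainedModel:
    """Standardize, then fit the requested model on the training set."""
    if isinstance(spec, str):
        spec = CNNSpec() if spec == "cnn" else ClassicalSpec(spec)
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Xs = (X - mean) / std
    y_idx = np.searchsorted(classes, y)

    if isinstance(spec, CNNSpec):
        clf = build_cnn(len(classes), input_len=X.shape[1], spec=spec,
                        seed=seed)
        clf.fit(Xs[:, None, :], y_idx)
        return TrainedModel(kind="cnn", model=clf, classes=classes,
                            scaler_mean=mean, scaler_std=std,
                            n_features=X.shape[1], history=clf.history)
    est = spec.build(seed=seed)
    est.fit(Xs, y_idx)
    return TrainedModel(kind=spec.kind, model=est, classes=classes,
                        scaler_mean=mean, scaler_std=std,
                        n_features=X.shape[1])


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Probabilistic class scores, one row per sample (rows sum to 1);
    ``argmax`` along columns gives the predicted class index."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected width {model.n_features}, got {X.shape[1] if X.ndim == 2 else X.shape}")
    Xs = model.standardize(X)
    if model.kind == "cnn":
        return model.model.predict_proba(Xs[:, None, :])
    return model.model.predict_proba(Xs)


def predict_labels(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    scores = predict_scores(model, X)
    return model.classes[scores.argmax(axis=1)]
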