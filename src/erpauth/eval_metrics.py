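"""Classification metrics and biometric verification error rates.

Identification quality is summarized by accuracy and macro-averaged
precision/recall/F1 with a confusion matrix. Verification error rates
treat every (test sample, claimed identity) pair as an authentication
attempt: the softmax score for the claimed class joins the genuine pool
when the claim is true and the impostor pool otherwise (one-vs-rest
pooling). At a threshold t, FAR is the fraction of impostor scores >= t
(ties count as accepts) and FRR the fraction of genuine scores < t; the
EER is where the two curves cross, linearly interpolated between adjacent
observed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (confusion_matrix as _sk_confusion,
                             precision_recall_fscore_support)


@dataclass
class ScoreSet:
    """Pooled genuine and impostor scores; higher = more likely genuine."""

    genuine: np.ndarray
    impostor: np.ndarray

    def __post_init__(self) -> None:
        self.genuine = np.asarray(self.genuine, float).ravel()
        self.impostor = np.asarray(self.impostor, float).ravel()
        if not (np.isfinite(self.genuine).all()
                and np.isfinite(self.impostor).all()):
            raise ValueError("scores must be finite")


@dataclass
class MetricsReport:
    """All rates as fractions in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    far: float | None = None
    frr: float | None = None
    eer: float | None = None
    eer_threshold: float | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "precision": self.precision,
               "recall": self.recall, "f1": self.f1}
        for k in ("far", "frr", "eer"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def classification_metrics(y_true, y_pred, labels=None) -> MetricsReport:
    """Accuracy, macro precision/recall/F1 and the confusion matrix
    (rows = true class, columns = predicted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    acc = float((y_true == y_pred).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    return MetricsReport(accuracy=acc, precision=float(prec),
                         recall=float(rec), f1=float(f1), confusion=cm)


def verification_scores(score_matrix: np.ndarray, y_true_idx: np.ndarray
                        ) -> ScoreSet:
    """Pool identity-claim scores: for sample i and class c the score joins
    the genuine pool iff c is i's true class. With n samples and k classes
    this yields n genuine and n*(k-1) impostor scores."""
    score_matrix = np.asarray(score_matrix, float)
    y_true_idx = np.asarray(y_true_idx, int)
    n, k = score_matrix.shape
    mask = np.zeros((n, k), dtype=bool)
    mask[np.arange(n), y_true_idx] = True
    return ScoreSet(genuine=score_matrix[mask],
                    impostor=score_matrix[~mask])


def far_frr_at(ss: ScoreSet, threshold: float) -> tuple[float, float]:
    """FAR = share of impostor scores >= threshold (accepted); FRR = share
    of genuine scores < threshold (rejected)."""
    if len(ss.genuine) == 0 or len(ss.impostor) == 0:
        raise ValueError("both score pools must be non-empty")
    far = float((ss.impostor >= threshold).mean())
    frr = float((ss.genuine < threshold).mean())
    return far, frr


def compute_eer(ss: ScoreSet) -> tuple[float, float]:
    """Equal error rate and its threshold.

    Sweeps every observed score value (plus a just-above-max sentinel) as a
    threshold; at the sign change of FAR - FRR the crossing is located by
    linear interpolation between the bracketing thresholds. For separable
    pools the EER is exactly 0.
    """
    if len(ss.genuine) == 0 or len(ss.impostor) == 0:
        raise ValueError("both score pools must be non-empty")
    scores = np.concatenate([ss.genuine, ss.impostor])
    thresholds = np.unique(scores)
    eps = max(1e-12, 1e-9 * max(1.0, abs(float(thresholds[-1]))))
    thresholds = np.append(thresholds, thresholds[-1] + eps)
    far = np.array([(ss.impostor >= t).mean() for t in thresholds])
    frr = np.array([(ss.genuine < t).mean() for t in thresholds])
    diff = far - frr
    # diff starts >= 0 (low t accepts everyone) and ends <= 0
    if diff[0] <= 0:
        return float(max(far[0], frr[0])), float(thresholds[0])
    i = int(np.argmax(diff <= 0))
    if diff[i] == 0:
        return float(far[i]), float(thresholds[i])
    # interpolate between thresholds i-1 (diff > 0) and i (diff < 0)
    d0, d1 = diff[i - 1], diff[i]
    w = d0 / (d0 - d1)
    eer = float((1 - w) * (far[i - 1] + frr[i - 1]) / 2
                + w * (far[i] + frr[i]) / 2)
    thr = float((1 - w) * thresholds[i - 1] + w * thresholds[i])
    return eer, thr


def evaluate_model(model, X_test: np.ndarray, y_test) -> MetricsReport:
    """Full test-set report: identification metrics plus pooled FAR/FRR/EER
    (FAR and FRR reported at the EER threshold)."""
    from .models import predict_scores

    y_test = np.asarray(y_test)
    scores = predict_scores(model, X_test)
    y_idx = np.searchsorted(model.classes, y_test)
    y_pred = model.classes[scores.argmax(axis=1)]
    rep = classification_metrics(y_test, y_pred, labels=model.classes)
    ss = verification_scores(scores, y_idx)
    eer, thr = compute_eer(ss)
    far, frr = far_frr_at(ss, thr)
    rep.far, rep.frr, rep.eer, rep.eer_threshold = far, frr, eer, thr
    return rep


def learning_curves(history: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-epoch train/validation accuracy and loss table."""
    if history is None or len(history) == 0:
        raise ValueError("empty training history")
    required = {"epoch", "train_loss", "train_acc", "val_loss", "val_acc"}
    missing = required - set(history.columns)
    if missing:
        raise ValueError(f"history missing columns {sorted(missing)}")
    out = history.loc[:, ["epoch", "train_loss", "train_acc", "val_loss",
                          "val_acc"]].copy()
    if not out["epoch"].is_monotonic_increasing:
        raise ValueError("epochs must be monotone increasing")
    return out


def plot_learning_curves(history: pd.DataFrame, path) -> None:
    """Accuracy and loss panels over epochs, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbl = learning_curves(history)
    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    ax_acc.plot(tbl["epoch"], tbl["train_acc"], label="train")
    ax_acc.plot(tbl["epoch"], tbl["val_acc"], label="validation")
    ax_acc.set_xlabel("epoch"); ax_acc.set_ylabel("accuracy"); ax_acc.legend()
    ax_loss.plot(tbl["epoch"], tbl["train_loss"], label="train")
    ax_loss.plot(tbl["epoch"], tbl["val_loss"], label="validation")
    ax_loss.set_xlabel("epoch"); ax_loss.set_ylabel("loss"); ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
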