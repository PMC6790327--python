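"""Linear-SVM classification with leave-one-out cross-validation.

Subjects are classified AD vs. NC from their selected connectivity edges
with a linear-kernel soft-margin SVM (cost C = 1, deliberately untuned).
Evaluation is leave-one-out (LOO): each subject in turn is held out, the
SVM is trained on the rest, and the held-out decision value and predicted
label are recorded. Five figures of merit are computed from the pooled LOO
predictions: accuracy, sensitivity, specificity, AUC and F-score, with AD
as the positive class throughout.

Two selection protocols are provided:

* ``nested`` (default) — the edge-wise t-test selection is re-run inside
  every training fold, so the held-out subject never influences its own
  feature set (statistically sound);
* ``whole_cohort`` (a.k.a. ``paper``) — selection runs once on all
  subjects before LOO. This reproduces the common published procedure but
  leaks the test subject into selection and inflates accuracy on null data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .features import edge_ttest, select_edges

POSITIVE_CLASS = "AD"
NEGATIVE_CLASS = "NC"

PROTOCOLS = ("nested", "paper")


@dataclass
class MetricBlock:
    """The five evaluation indices; rate metrics are percentages.

    Undefined ratios (e.g. precision with TP+FP = 0) are NaN, never 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    f_score: float
    auc: float | None

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
            "F_score": self.f_score, "AUC": self.auc,
        }


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_from_rates(
    sen_pct: float, spe_pct: float, n_pos: int, n_neg: int, tol: float = 0.005
) -> tuple[int, int, int, int]:
    """Reconstruct integer (TP, TN, FP, FN) from printed SEN/SPE percentages.

    Requires ``sen/100 * n_pos`` and ``spe/100 * n_neg`` to be within
    ``tol`` of an integer, otherwise the printed rates are inconsistent
    with the class sizes and a ``ValueError`` is raised.
    """
    tp_f = sen_pct / 100.0 * n_pos
    tn_f = spe_pct / 100.0 * n_neg
    tp, tn = round(tp_f), round(tn_f)
    if abs(tp_f - tp) > tol or abs(tn_f - tn) > tol:
        raise ValueError(
            f"SEN={sen_pct}%, SPE={spe_pct}% do not give integer counts for "
            f"classes of size {n_pos}/{n_neg}"
        )
    return tp, tn, n_neg - tn, n_pos - tp


def compute_metrics(
    tp: int, tn: int, fp: int, fn: int,
    scores: np.ndarray | None = None, labels: np.ndarray | None = None,
) -> MetricBlock:
    """Accuracy, sensitivity, specificity, F-score (as percentages) and AUC.

    ACC = 100 (TP+TN)/(TP+TN+FP+FN); SEN = 100 TP/(TP+FN);
    SPE = 100 TN/(TN+FP); F = 100 * 2 * precision * recall /
    (precision + recall) with precision = TP/(TP+FP), recall = TP/(TP+FN).
    AUC is computed from ``scores``/``labels`` when given, else None.
    """
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise ValueError(f"{name} is negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (tp + tn) / total
    sen = 100.0 * _safe_ratio(tp, tp + fn)
    spe = 100.0 * _safe_ratio(tn, tn + fp)
    precision = _safe_ratio(tp, tp + fp)
    recall = _safe_ratio(tp, tp + fn)
    f = 100.0 * _safe_ratio(2 * precision * recall, precision + recall)
    auc = None
    if scores is not None and labels is not None:
        _, auc = roc_points(scores, labels)
    return MetricBlock(tp, tn, fp, fn, acc, sen, spe, f, auc)


def roc_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve over the unique score thresholds, plus trapezoidal AUC.

    Returns the (FPR, TPR) point list from (0, 0) to (1, 1); tied scores
    step simultaneously. Raises if only one class is present.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iufb":
        return labels.astype(int)
    return (labels == POSITIVE_CLASS).astype(int)


@dataclass
class ClassificationResult:
    """LOO classification results for one feature set.

    Carries per-subject predictions and decision scores, the pooled
    confusion matrix, the five metrics and the ROC, in the spirit of a
    fitted-model results object; ``summary()`` renders the standard
    one-row report.
    """

    predictions: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    metrics: MetricBlock
    roc: list[tuple[float, float]]
    protocol: str
    alpha: float
    n_features_per_fold: list[int]
    method: str = "fc"
    extras: dict = field(default_factory=dict)

    @property
    def acc(self) -> float:
        return self.metrics.acc

    @property
    def auc(self) -> float:
        return self.metrics.auc

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"LOO linear-SVM classification — {self.method}",
            f"  protocol={self.protocol}  alpha={self.alpha:g}  "
            f"n={len(self.labels)}  mean features/fold="
            f"{np.mean(self.n_features_per_fold):.1f}",
            f"  confusion: TP={m.tp} FN={m.fn} TN={m.tn} FP={m.fp}",
            f"  ACC={m.acc:.2f}%  SEN={m.sen:.2f}%  SPE={m.spe:.2f}%  "
            f"AUC={m.auc:.4f}  F-score={m.f_score:.2f}",
        ]
        return "\n".join(lines)

    def summary_row(self) -> dict:
        m = self.metrics
        return {
            "method": self.method, "ACC": round(m.acc, 2), "SEN": round(m.sen, 2),
            "SPE": round(m.spe, 2), "AUC": round(m.auc, 4),
            "F_score": round(m.f_score, 2),
        }

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": np.arange(len(self.labels)),
                "label": self.labels,
                "predicted": self.predictions,
                "score": self.scores,
            }
        )


def _select_for_fold(
    features: np.ndarray, y: np.ndarray, edge_index, alpha: float,
    variant: str, min_features: int,
) -> np.ndarray:
    st = edge_ttest(features[y == 1], features[y == 0], edge_index, variant=variant)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        st = select_edges(st, alpha)
    mask = st.selected
    if not mask.any() and min_features > 0:
        # documented fallback: take the k smallest-p edges
        order = np.argsort(st.p, kind="stable")[:min_features]
        mask = np.zeros_like(mask)
        mask[order] = True
    return mask


def loo_svm(
    features: np.ndarray,
    labels: np.ndarray,
    edge_index: list[tuple[str, str]],
    alpha: float,
    protocol: str = "nested",
    c_cost: float = 1.0,
    standardize: bool = False,
    test_variant: str = "pooled",
    min_features: int = 0,
    method: str = "fc",
) -> ClassificationResult:
    """Leave-one-out linear-SVM evaluation of a cohort feature matrix.

    Parameters
    ----------
    features : ndarray, [n_subjects x n_edges]
        Fisher-z connectivity features, all edges (selection happens here).
    labels : array of "AD"/"NC" strings or 1/0 ints
        AD (1) is the positive class.
    alpha : float
        Edge-selection p-value threshold (non-strict).
    protocol : {"nested", "paper"}
        Where selection runs relative to the LOO folds (module docstring).
    c_cost : float
        SVM soft-margin cost (default 1, untuned).
    standardize : bool
        Optionally z-score features on the training fold (off by default;
        Fisher-z features share a scale already).
    min_features : int
        If > 0, an empty selection falls back to the ``min_features``
        smallest-p edges instead of raising.

    Raises
    ------
    ValueError
        If fewer than 4 subjects, one class absent, or a fold's selection
        is empty (naming the fold and alpha) with ``min_features=0``.
    """
    features = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOO")
    if features.shape[0] != n:
        raise ValueError("features and labels disagree on subject count")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if protocol == "whole_cohort":
        protocol = "paper"
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")

    global_mask = None
    if protocol == "paper":
        global_mask = _select_for_fold(
            features, y, edge_index, alpha, test_variant, min_features
        )
        if not global_mask.any():
            raise ValueError(
                f"empty edge selection at alpha={alpha} (whole-cohort protocol)"
            )

    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    n_feat = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if protocol == "paper":
            mask = global_mask
        else:
            mask = _select_for_fold(
                features[train], y[train], edge_index, alpha, test_variant, min_features
            )
            if not mask.any():
                raise ValueError(
                    f"empty edge selection in LOO fold {i} at alpha={alpha}"
                )
        xtr = features[np.ix_(train, mask)]
        xte = features[i, mask][None, :]
        if standardize:
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        clf = SVC(kernel="linear", C=c_cost)
        clf.fit(xtr, y[train])
        preds[i] = int(clf.predict(xte)[0])
        scores[i] = float(clf.decision_function(xte)[0])
        n_feat.append(int(mask.sum()))

    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    mb = compute_metrics(tp, tn, fp, fn, scores=scores, labels=y)
    roc, _ = roc_points(scores, y)
    label_strings = np.where(y == 1, POSITIVE_CLASS, NEGATIVE_CLASS)
    pred_strings = np.where(preds == 1, POSITIVE_CLASS, NEGATIVE_CLASS)
    return ClassificationResult(
        predictions=pred_strings, scores=scores, labels=label_strings, metrics=mb,
        roc=roc, protocol=protocol, alpha=alpha, n_features_per_fold=n_feat,
        method=method,
    )
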