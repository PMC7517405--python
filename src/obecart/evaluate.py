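"""Ordinal classification metrics.

Besides the usual macro F-score / precision / recall / accuracy and
one-vs-rest AUC per class, two metrics exploit the class ordering:
mean squared error on the integer class values V(c_i) = i, and Kendall's
tau-b rank correlation (tie-corrected in both margins) between the true
and predicted class values.  A model that confuses "hours" with "days"
is punished less by these than one that confuses "not absent" with
"weeks", which is exactly the point of ordinal evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import OrdinalDataset, OrdinalTreeModel, ValidationError
from .tree import predict_dataset

AVERAGES = ("macro", "micro", "weighted")


@dataclass
class EvalReport:
    f_score: float
    precision: float
    recall: float
    accuracy: float
    auc_macro: float
    auc_per_class: np.ndarray
    mse: float
    tau_b: float | None
    confusion: np.ndarray
    n_rows: int
    average: str = "macro"

    def to_dict(self) -> dict:
        def clean(x):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            return float(x)

        return {
            "f_score": clean(self.f_score),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "accuracy": clean(self.accuracy),
            "auc_macro": clean(self.auc_macro),
            "auc_per_class": [clean(a) for a in self.auc_per_class],
            "mse": clean(self.mse),
            "tau_b": clean(self.tau_b),
            "confusion": self.confusion.astype(int).tolist(),
            "n_rows": int(self.n_rows),
            "average": self.average,
        }


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n: int
) -> np.ndarray:
    """n x n count matrix indexed [true - 1, pred - 1]."""
    m = np.zeros((n, n), dtype=np.int64)
    np.add.at(m, (np.asarray(y_true) - 1, np.asarray(y_pred) - 1), 1)
    return m


def _prf(conf: np.ndarray, average: str) -> tuple[float, float, float]:
    """Precision/recall/F from a confusion matrix.

    Per-class F is the harmonic mean of per-class P and R; the macro
    F-score is the unweighted mean of per-class F (not the F of macro-P
    and macro-R).  Undefined ratios (no predicted / no true samples for a
    class) count as 0, matching the common zero-division convention.
    """
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / denom, 0.0)
    if average == "macro":
        return float(f1.mean()), float(prec.mean()), float(rec.mean())
    if average == "weighted":
        w = true_tot / true_tot.sum()
        return float((f1 * w).sum()), float((prec * w).sum()), float((rec * w).sum())
    if average == "micro":
        micro = tp.sum() / conf.sum()
        return float(micro), float(micro), float(micro)
    raise ValidationError(f"average must be one of {AVERAGES}")


def kendall_tau_b(
    truth, pred, *, zero_on_degenerate: bool = False
) -> float:
    """Kendall's tau-b between two equal-length value lists.

    Tie-corrected in both margins; lies in [-1, 1].  An all-constant
    vector on either side leaves tau undefined: this raises unless
    ``zero_on_degenerate`` asks for 0 instead.
    """
    x = np.asarray(truth, dtype=float)
    y = np.asarray(pred, dtype=float)
    if len(x) != len(y):
        raise ValidationError("truth and pred must have equal length")
    if len(x) < 2:
        raise ValidationError("tau-b needs at least 2 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        if zero_on_degenerate:
            return 0.0
        raise ValidationError(
            "tau-b undefined for an all-constant vector; "
            "pass zero_on_degenerate=True to report 0"
        )
    return float(stats.kendalltau(x, y, variant="b").statistic)


def auc_ovr(scores, is_positive) -> float:
    """Rank-based (Mann-Whitney) one-vs-rest AUC with midrank ties.

    Equals the fraction of (positive, negative) pairs in which the
    positive scores higher, counting ties as half.
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = len(s) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both positive and negative examples")
    ranks = stats.rankdata(s)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    model: OrdinalTreeModel, data: OrdinalDataset, average: str = "macro"
) -> EvalReport:
    """Score a fitted tree on a dataset.

    Per-class AUC scores each row with the leaf probability of that class.
    A class missing entirely from the data (or present everywhere) has an
    undefined AUC, reported as NaN and skipped by the macro AUC mean.
    Tau-b is None when either the targets or the predictions are constant.
    """
    if data.T == 0:
        raise ValidationError("cannot evaluate on an empty dataset")
    if average not in AVERAGES:
        raise ValidationError(f"average must be one of {AVERAGES}")
    n = model.class_spec.n
    y_pred, probs = predict_dataset(model, data)
    conf = confusion_matrix(data.y, y_pred, n)
    f1, prec, rec = _prf(conf, average)
    acc = float(np.trace(conf) / conf.sum())
    mse = float(np.mean((data.y.astype(float) - y_pred.astype(float)) ** 2))
    aucs = np.full(n, np.nan)
    for i in range(n):
        is_pos = data.y == i + 1
        if 0 < is_pos.sum() < data.T:
            aucs[i] = auc_ovr(probs[:, i], is_pos)
    auc_macro = float(np.nanmean(aucs)) if np.any(~np.isnan(aucs)) else math.nan
    try:
        tau = kendall_tau_b(data.y, y_pred)
    except ValidationError:
        tau = None
    return EvalReport(
        f_score=f1,
        precision=prec,
        recall=rec,
        accuracy=acc,
        auc_macro=auc_macro,
        auc_per_class=aucs,
        mse=mse,
        tau_b=tau,
        confusion=conf,
        n_rows=data.T,
        average=average,
    )


def plot_auc_per_class(report: EvalReport, class_labels, path) -> None:
    """Bar chart of per-class one-vs-rest AUC (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(class_labels), report.auc_per_class, color="#4878a8")
    ax.set_ylim(0, 1)
    ax.set_ylabel("one-vs-rest AUC")
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
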