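"""Ensemble inference, confusion matrices and macro classification
metrics (accuracy, sensitivity, specificity, F-measure).

The final prediction of a multi-exit network is the unweighted average
of the exits' probability rows, f = (1/n) sum_m S_m; averaging the
near-independent exit classifiers reduces the variance of the predicted
probabilities, which is where the ensemble's accuracy gain comes from.
Exit probabilities use the ordinary (temperature 1) softmax at
inference; temperature is a training device only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "softmax", "ensemble_predict", "confusion", "macro_metrics",
    "MacroMetrics", "MetricsReport", "count_parameters", "evaluate_student",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ensemble_predict(exit_probs) -> np.ndarray:
    """Average the per-exit probability rows: f = (1/n) sum_m S_m.

    Rows of the result sum to 1 whenever the inputs do; its argmax is
    the ensemble prediction.
    """
    mats = [np.asarray(p, dtype=np.float64) for p in exit_probs]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"exit probability shapes differ: {shapes}")
    return np.mean(mats, axis=0)


def confusion(predictions, labels, num_classes: int) -> np.ndarray:
    """C x C count matrix; entry (i, j) counts true class i predicted j."""
    p = np.asarray(predictions, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape:
        raise ValueError(f"predictions/labels shapes differ: {p.shape} vs {y.shape}")
    for name, a in (("predictions", p), ("labels", y)):
        if a.size and (a.min() < 0 or a.max() >= num_classes):
            raise ValueError(f"{name} contain classes outside [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (y, p), 1)
    return cm


@dataclass
class MacroMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    f_measure: float

    def as_percent(self) -> dict:
        return {k: 100.0 * v for k, v in vars(self).items()}


def macro_metrics(cm: np.ndarray) -> MacroMetrics:
    """Macro (unweighted class-mean) metrics from a confusion matrix.

    Per class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
    TP/(TP+FP), F = 2*prec*sens/(prec+sens).  Classes with zero support
    are excluded from the macro means (and logged); accuracy is
    trace/total.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    keep = support > 0
    if not keep.all():
        logger.warning("excluding %d zero-support classes from macro metrics",
                       int((~keep).sum()))
    fn = support - tp
    fp = predicted - tp
    tn = total - tp - fn - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f = np.where(prec + sens > 0, 2 * prec * sens / (prec + sens), 0.0)
    return MacroMetrics(
        accuracy=float(tp.sum() / total),
        sensitivity=float(sens[keep].mean()),
        specificity=float(spec[keep].mean()),
        f_measure=float(f[keep].mean()),
    )


def count_parameters(model, only_trainable: bool = False) -> int:
    """Total parameter element count (optionally restricted to tensors
    still marked trainable, which excludes frozen teachers)."""
    return int(sum(p.data.size for p in model.parameters()
                   if p.requires_grad or not only_trainable))


def parameters_in_millions(model) -> float:
    return round(count_parameters(model) / 1e6, 2)


@dataclass
class MetricsReport:
    """Per-exit and ensemble confusion matrices with macro metrics."""

    class_names: list
    per_exit_confusion: list
    ensemble_confusion: np.ndarray
    per_exit_accuracy: list
    ensemble_metrics: MacroMetrics
    n_samples: int
    student_params: int | None = None
    teacher_params: int | None = None

    def to_dict(self) -> dict:
        d = {
            "class_names": list(self.class_names),
            "n_samples": self.n_samples,
            "per_exit_accuracy_pct": [100 * a for a in self.per_exit_accuracy],
            "ensemble": self.ensemble_metrics.as_percent(),
            "per_exit_confusion": [cm.tolist() for cm in self.per_exit_confusion],
            "ensemble_confusion": self.ensemble_confusion.tolist(),
        }
        if self.student_params is not None:
            d["student_params_m"] = round(self.student_params / 1e6, 2)
        if self.teacher_params is not None:
            d["teacher_params_m"] = round(self.teacher_params / 1e6, 2)
        return d


def _forward_logits(student, x_batch):
    bundle = student(x_batch)
    return [z.data for z in bundle.logits_per_exit]


def evaluate_student(student, x: np.ndarray, labels: np.ndarray,
                     class_names, batch_size: int = 64,
                     teacher=None) -> MetricsReport:
    """Run a multi-exit student over preprocessed inputs (N, 3, H, W) and
    assemble a MetricsReport with one confusion matrix per exit plus the
    softmax-average ensemble."""
    student.eval()
    n = x.shape[0]
    all_logits = None
    for start in range(0, n, batch_size):
        batch_logits = _forward_logits(student, x[start:start + batch_size])
        if all_logits is None:
            all_logits = [[bl] for bl in batch_logits]
        else:
            for acc, bl in zip(all_logits, batch_logits):
                acc.append(bl)
    exit_logits = [np.concatenate(acc, axis=0) for acc in all_logits]
    exit_probs = [softmax(z) for z in exit_logits]
    c = len(class_names)
    per_exit_cm = [confusion(p.argmax(axis=1), labels, c) for p in exit_probs]
    ens = ensemble_predict(exit_probs)
    ens_cm = confusion(ens.argmax(axis=1), labels, c)
    report = MetricsReport(
        class_names=list(class_names),
        per_exit_confusion=per_exit_cm,
        ensemble_confusion=ens_cm,
        per_exit_accuracy=[macro_metrics(cm).accuracy for cm in per_exit_cm],
        ensemble_metrics=macro_metrics(ens_cm),
        n_samples=int(n),
        student_params=count_parameters(student),
        teacher_params=count_parameters(teacher) if teacher is not None else None,
    )
    student.train()
    return report


def save_confusion_outputs(report: MetricsReport, out_dir) -> None:
    """Write confusion matrices as CSV and heatmap PNGs plus a metrics
    JSON (used by the `evaluate` command)."""
    import json
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mats = {f"exit{m + 1}": cm for m, cm in enumerate(report.per_exit_confusion)}
    mats["ensemble"] = report.ensemble_confusion
    for name, cm in mats.items():
        np.savetxt(out / f"confusion_{name}.csv", cm, fmt="%d", delimiter=",",
                   header=",".join(report.class_names))
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xticks(range(len(report.class_names)), report.class_names,
                      rotation=45, ha="right", fontsize=7)
        ax.set_yticks(range(len(report.class_names)), report.class_names, fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(name)
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=7)
        fig.colorbar(im, fraction=0.046)
        fig.tight_layout()
        fig.savefig(out / f"confusion_{name}.png", dpi=120)
        plt.close(fig)
    with open(out / "metrics.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
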