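"""Cross-cohort ensembling and evaluation.

The fold models produced by leave-one-participant-out cross-validation are
fused on unseen recordings by a per-frame majority vote: the modal label
across the K models wins; a tie is resolved by the largest per-class sum of
predicted probabilities across all models, and an exactly tied sum (possible
only in contrived inputs) falls back to the lowest class index so the vote is
deterministic.

Metrics are one-vs-rest precision, recall, F1 and accuracy per class, with
macro (unweighted over classes with non-zero support) and support-weighted
averages, all derived from a confusion matrix over the union of truth and
predicted label sets — so a prediction outside the test cohort's repertoire
(e.g. running predicted on a cohort that never runs) appears as a false
positive that depresses the other classes' precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LabelSequence, SignalWindow
from .models import DenseLabeller, FramePredictions


@dataclass(frozen=True)
class VoteInput:
    """Per-model dense predictions: (K, T) labels and (K, T, C) probabilities."""

    per_model_labels: np.ndarray
    per_model_probabilities: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.per_model_labels)
        probs = np.asarray(self.per_model_probabilities, float)
        object.__setattr__(self, "per_model_labels", labels)
        object.__setattr__(self, "per_model_probabilities", probs)
        if labels.ndim != 2:
            raise ValueError("per_model_labels must be K x T")
        if labels.shape[0] == 0:
            raise ValueError("need at least one model's votes")
        if probs.shape[:2] != labels.shape:
            raise ValueError("probabilities must be K x T x C aligned with labels")
        if not np.allclose(probs.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("probability rows must be row-stochastic")


def majority_vote(votes: VoteInput) -> np.ndarray:
    """Per-frame modal label with summed-probability tie-break.

    Returns a length-T integer label vector.  Ties on vote count are resolved
    by the largest sum of per-class probability across models; a residual
    exact tie breaks to the lowest class index.
    """
    labels = votes.per_model_labels
    probs = votes.per_model_probabilities
    K, T = labels.shape
    C = probs.shape[2]
    counts = np.zeros((T, C), dtype=np.int64)
    onehot = np.eye(C, dtype=np.int64)
    for k in range(K):
        counts += onehot[labels[k]]
    max_counts = counts.max(axis=1, keepdims=True)
    winners = counts.argmax(axis=1)
    tied = (counts == max_counts).sum(axis=1) > 1
    if tied.any():
        summed = probs[:, tied, :].sum(axis=0)  # (n_tied, C)
        # restrict the probability tie-break to the classes tied on votes
        masked = np.where(counts[tied] == max_counts[tied], summed, -np.inf)
        winners[tied] = masked.argmax(axis=1)
    return winners


def ensemble_predict(
    models: Sequence[DenseLabeller], recording: SignalWindow
) -> tuple[np.ndarray, VoteInput]:
    """Run every model densely over the recording (one variable-length window
    each) and fuse the per-frame predictions by majority vote."""
    if not models:
        raise ValueError("need at least one model")
    channels = {m.config.input_channels for m in models}
    if len(channels) != 1 or recording.n_channels not in channels:
        raise ValueError(
            f"models expect {sorted(channels)} input channels, "
            f"recording has {recording.n_channels}"
        )
    preds: list[FramePredictions] = [m.predict(recording) for m in models]
    votes = VoteInput(
        per_model_labels=np.stack([p.argmax_labels for p in preds]),
        per_model_probabilities=np.stack([p.probabilities for p in preds]),
    )
    return majority_vote(votes), votes


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Per-class, macro and support-weighted classification metrics."""

    labels: tuple[int, ...]
    label_names: dict[int, str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    class_accuracy: np.ndarray
    support: np.ndarray
    confusion_matrix: np.ndarray  # rows = truth, columns = prediction
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus macro/weighted summary rows, CSV-ready."""
        rows = [
            {
                "class": self.label_names.get(lab, str(lab)),
                "precision": self.precision[i],
                "recall": self.recall[i],
                "f1": self.f1[i],
                "accuracy": self.class_accuracy[i],
                "support": int(self.support[i]),
            }
            for i, lab in enumerate(self.labels)
        ]
        total = int(self.support.sum())
        rows.append({"class": "macro", **self.macro, "support": total})
        rows.append({"class": "weighted", **self.weighted, "support": total})
        return pd.DataFrame(rows)


def compute_metrics(
    pred: LabelSequence | np.ndarray,
    truth: LabelSequence | np.ndarray,
    label_universe: Sequence[int] | None = None,
    label_names: dict[int, str] | None = None,
) -> MetricsReport:
    """One-vs-rest metrics over the union label set.

    Classes with zero truth support are kept in the confusion matrix (their
    false positives count against other classes' precision) but excluded from
    the macro and weighted averages; weighted averages use each class's share
    of truth frames as its weight, so weighted recall over the full label set
    equals overall frame accuracy.
    """
    p = pred.labels if isinstance(pred, LabelSequence) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelSequence) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction length {p.shape} != truth length {t.shape}")
    if p.size == 0:
        raise ValueError("cannot score an empty label sequence")
    universe = sorted(set(np.unique(t)) | set(np.unique(p)) | set(label_universe or ()))
    index = {lab: i for i, lab in enumerate(universe)}
    C = len(universe)
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (np.vectorize(index.get)(t), np.vectorize(index.get)(p)), 1)

    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    class_accuracy = (tp + tn) / total
    support = cm.sum(axis=1)
    accuracy = float(tp.sum() / total)

    present = support > 0
    weights = support[present] / support[present].sum()
    macro = {
        "precision": float(precision[present].mean()),
        "recall": float(recall[present].mean()),
        "f1": float(f1[present].mean()),
        "accuracy": float(class_accuracy[present].mean()),
    }
    weighted = {
        "precision": float(weights @ precision[present]),
        "recall": float(weights @ recall[present]),
        "f1": float(weights @ f1[present]),
        "accuracy": float(weights @ class_accuracy[present]),
    }
    names = dict(label_names or {})
    if isinstance(truth, LabelSequence):
        names = {**truth.label_map, **names}
    return MetricsReport(
        labels=tuple(universe),
        label_names=names,
        precision=precision,
        recall=recall,
        f1=f1,
        class_accuracy=class_accuracy,
        support=support,
        confusion_matrix=cm,
        accuracy=accuracy,
        macro=macro,
        weighted=weighted,
    )


# ---------------------------------------------------------------------------
# significance testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool  # all pairwise differences share one value (sd = 0)


def paired_f1_test(
    scores_a: Sequence[float], scores_b: Sequence[float], alpha: float = 0.05
) -> PairedTestResult:
    """Two-sided paired t-test on matched per-participant F1 scores.

    With zero-variance differences the t statistic is undefined; the result is
    flagged degenerate (t = 0, p = 1 when the scores are identical; otherwise
    the difference is deterministic and reported as +/- infinity, p = 0).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be matched (equal length)")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 matched scores")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTestResult(0.0, 1.0, False, True)
        return PairedTestResult(float(np.sign(d.mean()) * np.inf), 0.0, True, True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha), False
    )


def per_participant_weighted_f1(folds) -> list[float]:
    """Weighted F1 on each fold's held-out participant — the pairing unit for
    significance tests between experimental conditions."""
    return [
        compute_metrics(f.predictions.argmax_labels, f.truth.labels).weighted["f1"]
        for f in folds
    ]


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def metrics_to_csv(report: MetricsReport, path: str | Path) -> Path:
    path = Path(path)
    report.to_frame().to_csv(path, index=False, float_format="%.6f")
    cm_path = path.with_name(path.stem + "_confusion.csv")
    names = [report.label_names.get(lab, str(lab)) for lab in report.labels]
    pd.DataFrame(report.confusion_matrix, index=names, columns=names).to_csv(cm_path)
    return path


def plot_confusion(report: MetricsReport, path: str | Path, title: str = "") -> Path:
    """Row-normalised confusion heatmap (percent of each truth class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion_matrix.astype(float)
    rowsum = cm.sum(axis=1, keepdims=True)
    pct = np.divide(cm, rowsum, out=np.zeros_like(cm), where=rowsum > 0) * 100.0
    names = [report.label_names.get(lab, str(lab)) for lab in report.labels]
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(names),) * 2)
    im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, f"{pct[i, j]:.0f}", ha="center", va="center",
                    color="white" if pct[i, j] > 50 else "black", fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    if title:
        ax.set_title(title)
    fig.colorbar(im, label="% of truth class")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
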