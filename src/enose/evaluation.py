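"""Train/test splitting and confusion-matrix evaluation.

Grades live in {1, 2, 3}. The confusion matrix has true grades in rows and
predicted grades in columns; "per-class accuracy" is the class recall
(diagonal count over row sum), and overall accuracy the trace over the
total — reported as percentages, displayed at 4 decimals overall and 1
decimal per class.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn import metrics as _sk_metrics
from sklearn.model_selection import train_test_split as _sk_split

GRADES = (1, 2, 3)

__all__ = [
    "split_train_test",
    "confusion_matrix",
    "overall_accuracy",
    "per_class_accuracy",
    "report",
    "render_report",
]


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Split row indices into disjoint, exhaustive train and test sets.

    ``ratio`` is the training fraction (the study's 8:2 split is
    ``ratio=0.8``). With ``stratified=True`` each class keeps its
    proportion in both halves to within one sample. Deterministic under
    ``seed``. Returns ``(train_indices, test_indices)``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    y = np.asarray(y)
    n = len(y)
    if len(np.atleast_2d(X)) not in (n,) and len(X) != n:
        raise ValueError("X and y lengths differ")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    indices = np.arange(n)
    if stratified:
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            lonely = classes[counts.argmin()]
            raise ValueError(
                f"class {lonely!r} has fewer than 2 members; stratified split impossible"
            )
        strat = y
    else:
        strat = None
    train_idx, test_idx = _sk_split(
        indices, train_size=ratio, random_state=seed, stratify=strat, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> np.ndarray:
    """3×3 count table: ``counts[i, j]`` = samples of true grade ``i+1``
    predicted as grade ``j+1``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, GRADES).all():
            bad = arr[~np.isin(arr, GRADES)][0]
            raise ValueError(f"{name} contains grade {bad!r} outside {{1, 2, 3}}")
    return _sk_metrics.confusion_matrix(y_true, y_pred, labels=list(GRADES)).astype(np.int64)


def _check_cm(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (3, 3):
        raise ValueError(f"expected a 3x3 confusion matrix, got shape {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    return cm


def overall_accuracy(cm) -> float:
    """Percentage of correctly graded samples: 100 × trace / total."""
    cm = _check_cm(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm)) / float(total)


def per_class_accuracy(cm) -> np.ndarray:
    """Class recalls as percentages: 100 × diagonal / row sum, per grade.

    A grade absent from the data (zero row) is reported as NaN with a
    warning.
    """
    cm = _check_cm(cm)
    row_sums = cm.sum(axis=1)
    out = np.full(3, np.nan)
    for i in range(3):
        if row_sums[i] == 0:
            warnings.warn(f"grade {i + 1} absent from the data; recall undefined")
        else:
            out[i] = 100.0 * float(cm[i, i]) / float(row_sums[i])
    return out


def report(model, test_X: np.ndarray, test_y: Sequence[int]) -> dict:
    """Evaluate a fitted classifier on labeled test data.

    Returns a JSON-serializable dict with the confusion matrix, overall
    and per-class accuracy (full precision and display-rounded), the test
    size, and an echo of the model's configuration and seeds.
    """
    test_y = np.asarray(test_y)
    y_pred = model.predict(test_X)
    cm = confusion_matrix(test_y, y_pred)
    overall = overall_accuracy(cm)
    per_class = per_class_accuracy(cm)
    doc = {
        "n_test": int(len(test_y)),
        "confusion_matrix": cm.tolist(),
        "overall_accuracy_pct": overall,
        "overall_accuracy_pct_display": round(overall, 4),
        "per_class_accuracy_pct": [None if np.isnan(v) else v for v in per_class],
        "per_class_accuracy_pct_display": [
            None if np.isnan(v) else round(v, 1) for v in per_class
        ],
    }
    spec = getattr(model, "spec", None)
    if spec is not None:
        doc["network_spec"] = dict(spec.__dict__)
    ga = getattr(model, "ga_config", None)
    if ga is not None:
        doc["ga_config"] = {**ga.__dict__, "gene_bounds": list(ga.gene_bounds)}
    bp = getattr(model, "bp_config", None)
    if bp is not None:
        doc["bp_config"] = dict(bp.__dict__)
    return doc


def render_report(doc: dict) -> str:
    """Human-readable rendering of :func:`report` output."""
    lines = [
        f"test samples: {doc['n_test']}",
        "confusion matrix (rows true 1..3, cols predicted 1..3):",
    ]
    for row in doc["confusion_matrix"]:
        lines.append("  " + " ".join(f"{c:6d}" for c in row))
    lines.append(f"overall accuracy: {doc['overall_accuracy_pct_display']:.4f}%")
    names = ("fresh", "sub-fresh", "decayed")
    for name, v in zip(names, doc["per_class_accuracy_pct_display"]):
        lines.append(f"  {name:10s} {'n/a' if v is None else f'{v:.1f}%'}")
    return "\n".join(lines) + "\n"
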