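"""Chemometric preprocessing and exploratory analysis.

Min–max normalization, principal component analysis, Pearson correlation
of quality indices against remaining shelf life, Euclidean-distance
k-means clustering of the quality indices, and the loading-angle reading
of a 2-component PCA (acute angle between two variables' loading vectors
= positive relationship, obtuse = negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .quality_indices import DECAYED, grade_series

__all__ = [
    "MinMaxModel",
    "PcaModel",
    "ClusterResult",
    "normalize",
    "apply_normalize",
    "fit_pca",
    "transform",
    "inverse_transform",
    "cumulative_variance",
    "decay_deadline",
    "remaining_shelf_life",
    "correlate_with_shelf_life",
    "euclidean_distance",
    "cluster_quality",
    "loading_angle_signs",
    "save_pca_model",
    "load_pca_model",
]


def _as_matrix(matrix, min_rows: int = 1) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if X.shape[0] < min_rows:
        raise ValueError(f"matrix needs at least {min_rows} rows, got {X.shape[0]}")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")
    return X


@dataclass(frozen=True)
class MinMaxModel:
    """Stored per-feature minima and maxima of a min–max normalization."""

    feature_min: np.ndarray
    feature_max: np.ndarray


def normalize(matrix) -> tuple[np.ndarray, MinMaxModel]:
    """Scale each feature to [0, 1] by its observed range.

    Constant features (zero range) map to all zeros, with a warning: they
    carry no information for the downstream model. Returns the normalized
    matrix and a :class:`MinMaxModel` so the identical transform can be
    applied to held-out data.
    """
    X = _as_matrix(matrix, min_rows=2)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    constant = hi == lo
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) normalized to zero",
            stacklevel=2,
        )
    model = MinMaxModel(feature_min=lo, feature_max=hi)
    return apply_normalize(model, X), model


def apply_normalize(model: MinMaxModel, matrix) -> np.ndarray:
    """Apply a stored min–max transform to new data (values may leave [0, 1])."""
    X = _as_matrix(matrix)
    span = model.feature_max - model.feature_min
    span = np.where(span == 0, 1.0, span)
    return (X - model.feature_min) / span


@dataclass(frozen=True)
class PcaModel:
    """A fitted principal component analysis.

    ``loadings`` holds the orthonormal component vectors as rows, ordered
    by decreasing explained variance, each signed so its largest-magnitude
    entry is positive. ``explained_variance_ratio`` covers the retained
    components only; the fractions of all ``n_features`` components sum
    to 1.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(matrix, n_components: int, standardize: bool = False) -> PcaModel:
    """Fit a PCA by singular-value decomposition of the centered matrix.

    Parameters
    ----------
    matrix:
        Data with observations in rows (normalize first if features have
        incommensurate units).
    n_components:
        Number of leading components to retain, 1..n_features.
    standardize:
        Additionally divide each centered feature by its standard
        deviation before the decomposition.
    """
    X = _as_matrix(matrix, min_rows=2)
    n, p = X.shape
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in [1, {p}], got {n_components}")
    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        scale = np.ones(p)
    Z = (X - center) / scale
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    loadings = vt[:n_components]
    # deterministic sign: largest-magnitude entry of each loading positive
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.abs(loadings).argmax(axis=1)])
    flip = np.where(flip == 0, 1.0, flip)
    loadings = loadings * flip[:, None]
    return PcaModel(
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance_ratio=ratio[:n_components],
    )


def transform(model: PcaModel, matrix) -> np.ndarray:
    """Project data onto the model's retained components (scores)."""
    X = _as_matrix(matrix)
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} features, model expects {model.center.shape[0]}"
        )
    return ((X - model.center) / model.scale) @ model.loadings.T


def inverse_transform(model: PcaModel, scores) -> np.ndarray:
    """Reconstruct data from scores (exact when all components are retained)."""
    S = np.asarray(scores, dtype=float)
    return S @ model.loadings * model.scale + model.center


def cumulative_variance(model: PcaModel, k: int) -> float:
    """Cumulative explained-variance fraction of the first ``k`` components."""
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k must be in [1, {model.n_components}], got {k}")
    return float(model.explained_variance_ratio[:k].sum())


def decay_deadline(records: pd.DataFrame) -> float:
    """First timepoint at which the TVB-N rule grades the sample decayed.

    Falls back to the last timepoint (plus one step) if the series never
    reaches the decayed grade.
    """
    grades = grade_series(records, "tvbn")
    t = records["time_hours"].to_numpy(dtype=float)
    hit = np.flatnonzero(grades == DECAYED)
    if hit.size:
        return float(t[hit[0]])
    step = float(t[-1] - t[-2]) if len(t) > 1 else 1.0
    return float(t[-1] + step)


def remaining_shelf_life(records: pd.DataFrame) -> np.ndarray:
    """Hours until the decay deadline at each quality timepoint."""
    return decay_deadline(records) - records["time_hours"].to_numpy(dtype=float)


def correlate_with_shelf_life(
    quality: pd.DataFrame, shelf_life: Sequence[float] | None = None
) -> dict[str, float]:
    """Pearson correlation of each quality index with remaining shelf life.

    If ``shelf_life`` is omitted it is derived from the table itself as
    the time remaining until the TVB-N decay deadline. Zero-variance
    columns are reported as NaN with a warning.
    """
    if shelf_life is None:
        shelf_life = remaining_shelf_life(quality)
    y = np.asarray(shelf_life, dtype=float)
    cols = [c for c in quality.columns if c != "time_hours"]
    if len(y) != len(quality):
        raise ValueError("shelf_life length does not match the quality table")
    if len(y) < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    out: dict[str, float] = {}
    for col in cols:
        x = quality[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero variance in {col!r} or shelf life; correlation undefined")
            out[col] = float("nan")
            continue
        out[col] = float(pearsonr(x, y).statistic)
    return out


def euclidean_distance(a, b) -> float:
    """Euclidean distance: the root of summed squared coordinate differences."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of Lloyd's k-means: assignments, centers, iterations run,
    and the within-cluster sum of squares after each iteration."""

    assignments: np.ndarray
    centers: np.ndarray
    n_iter: int
    inertia_per_iter: np.ndarray

    @property
    def inertia(self) -> float:
        return float(self.inertia_per_iter[-1])


def cluster_quality(points, k: int, seed: int = 0, max_iter: int = 100) -> ClusterResult:
    """Lloyd-style k-means under the Euclidean distance.

    Centers are initialized as ``k`` distinct points drawn with the given
    seed; iteration alternates nearest-center assignment and centroid
    update until assignments stabilize or ``max_iter`` is reached. The
    within-cluster sum of squares is nonincreasing across iterations. An
    emptied cluster is reseeded to the point farthest from its center.
    """
    X = _as_matrix(points)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    assignments = np.full(n, -1, dtype=np.int64)
    inertias = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = cdist(X, centers, metric="sqeuclidean")
        new_assignments = d2.argmin(axis=1)
        for j in range(k):
            members = X[new_assignments == j]
            if len(members) == 0:
                far = d2[np.arange(n), new_assignments].argmax()
                centers[j] = X[far]
                new_assignments[far] = j
            else:
                centers[j] = members.mean(axis=0)
        inertias.append(
            float(((X - centers[new_assignments]) ** 2).sum())
        )
        if np.array_equal(new_assignments, assignments):
            break
        assignments = new_assignments
    return ClusterResult(
        assignments=assignments,
        centers=centers,
        n_iter=n_iter,
        inertia_per_iter=np.asarray(inertias),
    )


def loading_angle_signs(model: PcaModel, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise variable relationships read from a 2-component loading plot.

    For each pair of variables, the sign of the dot product of their 2-D
    loading vectors: +1 (acute angle, positive relationship) or -1
    (obtuse, negative). A zero dot product (right angle) is reported
    as +1.
    """
    if model.n_components < 2:
        raise ValueError("loading-angle analysis needs a model with at least 2 components")
    V = model.loadings[:2]  # (2, p) — columns are the variables' 2-D vectors
    dot = V.T @ V
    signs = np.where(dot >= 0, 1, -1).astype(np.int64)
    p = V.shape[1]
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length does not match the model")
    return pd.DataFrame(signs, index=names, columns=names)


# ---------------------------------------------------------------------------
# plain-text model persistence


def save_pca_model(model: PcaModel, path: str | Path) -> None:
    """Persist a PCA model as a plain-text key/value + matrix file."""
    path = Path(path)
    lines = [
        "# enose PCA model",
        f"n_components {model.n_components}",
        "center " + " ".join(f"{v:.17g}" for v in model.center),
        "scale " + " ".join(f"{v:.17g}" for v in model.scale),
        "explained_variance_ratio "
        + " ".join(f"{v:.17g}" for v in model.explained_variance_ratio),
    ]
    for row in model.loadings:
        lines.append("loading " + " ".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def load_pca_model(path: str | Path) -> PcaModel:
    fields: dict[str, list[float]] = {}
    loadings = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, *vals = line.split()
        if key == "loading":
            loadings.append([float(v) for v in vals])
        elif key != "n_components":
            fields[key] = [float(v) for v in vals]
    return PcaModel(
        center=np.asarray(fields["center"]),
        scale=np.asarray(fields["scale"]),
        loadings=np.asarray(loadings),
        explained_variance_ratio=np.asarray(fields["explained_variance_ratio"]),
    )
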