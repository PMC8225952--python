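"""Category feature space: standardization, PCA, distances, 2-D embedding.

The descriptor sets mix units (Hz, seconds, bits, dimensionless ratios), so
every distance-based comparison works in z-scored space: each retained
feature has mean 0 and sd 1, and constant features are dropped with a
notice. PCA is the eigendecomposition of the sample covariance of that
standardized table, with explained-variance ratios per component; the
low-dimensional map delegates to an established stochastic-neighbor
implementation (scikit-learn's t-SNE) behind a fixed seed — this module owns
only the preprocessing, seeding and output shaping.

The between-category distance matrix is the analog of comparing each played
sound-object category with each whale-unit category: entry (u, c) is the
mean Euclidean distance over all (unit event, CSE event) pairs, with a
per-column mean row and the grand mean over unit–unit pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .features import FeatureTable

__all__ = [
    "standardize",
    "PcaResult",
    "pca",
    "DistanceMatrix",
    "between_category_distances",
    "embed",
]

logger = logging.getLogger(__name__)


def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score every feature; drop constant features with a logged notice.

    Idempotent: standardizing a standardized table changes nothing (the
    columns already have mean 0 and sd 1).
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    v = table.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=0)
    # constant up to float round-off counts as constant
    keep = sd > 1e-12 * np.maximum(np.abs(mean), 1.0)
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    if dropped:
        logger.info("standardize: dropped %d constant feature(s): %s", len(dropped), dropped)
    z = (v[:, keep] - mean[keep]) / sd[keep]
    return FeatureTable(
        event_ids=table.event_ids,
        labels=table.labels,
        sources=table.sources,
        values=z,
        feature_names=tuple(n for n, k in zip(table.feature_names, keep) if k),
    )


@dataclass(frozen=True)
class PcaResult:
    """Principal components of a standardized feature table.

    ``loadings`` has one column per component (orthonormal); ratios are the
    per-component shares of total variance and sum to 1; ``coordinates``
    are the projections of the rows onto all components, so the full
    projection reconstructs the input exactly.
    """

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    coordinates: np.ndarray
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.coordinates @ self.loadings.T + self.mean


def pca(table: FeatureTable) -> PcaResult:
    """PCA from the eigendecomposition of the sample covariance.

    Components are sorted by decreasing eigenvalue. The sign of each
    component is fixed by making its largest-magnitude loading positive, so
    the result is fully deterministic.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 rows")
    v = table.values
    mean = v.mean(axis=0)
    cov = np.cov(v - mean, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign convention
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        loadings=evecs,
        explained_variance_ratio=ratio,
        coordinates=(v - mean) @ evecs,
        mean=mean,
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Mean Euclidean distances between unit categories and CSE categories.

    ``matrix[i, j]`` is the mean distance over all (unit event of row label
    i, CSE event of column label j) pairs; ``column_means`` is the per-CSE
    mean over unit categories, and ``unit_grand_mean`` the mean distance over
    all unit–unit event pairs across categories.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    matrix: np.ndarray
    column_means: np.ndarray
    unit_grand_mean: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=list(self.row_labels), columns=list(self.col_labels))
        df.loc["Mean"] = self.column_means
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="label")


def between_category_distances(table: FeatureTable) -> DistanceMatrix:
    """Mean Euclidean distance between every unit and CSE category pair.

    Expects a (standardized) table containing both sources; labels without
    events are simply absent. Pure function of the table contents — row
    order does not matter.
    """
    src = np.asarray(table.sources)
    labels = np.asarray(table.labels)
    unit_mask = src == "unit"
    cse_mask = src == "cse"
    if not unit_mask.any() or not cse_mask.any():
        raise ValueError("table must contain both unit and cse rows")
    row_labels = tuple(sorted(set(labels[unit_mask])))
    col_labels = tuple(sorted(set(labels[cse_mask])))
    M = np.empty((len(row_labels), len(col_labels)))
    for i, u in enumerate(row_labels):
        uu = table.values[unit_mask & (labels == u)]
        for j, c in enumerate(col_labels):
            cc = table.values[cse_mask & (labels == c)]
            M[i, j] = cdist(uu, cc).mean()
    unit_rows = table.values[unit_mask]
    grand = float(pdist(unit_rows).mean()) if len(unit_rows) >= 2 else float("nan")
    return DistanceMatrix(
        row_labels=row_labels,
        col_labels=col_labels,
        matrix=M,
        column_means=M.mean(axis=0),
        unit_grand_mean=grand,
    )


def embed(
    table: FeatureTable,
    seed: int = 0,
    perplexity: float | None = None,
    **tsne_kwargs,
) -> pd.DataFrame:
    """2-D stochastic-neighbor embedding of a standardized table.

    Delegates the optimization to scikit-learn's t-SNE under a fixed seed;
    only preprocessing, seeding and output shaping live here. Perplexity is
    capped below the row count so small tables embed without error.

    Returns a DataFrame with event_id, label, source, dim1, dim2.
    """
    n = len(table)
    if n < 5:
        raise ValueError(f"embedding needs ≥ 5 rows, got {n}")
    try:
        from sklearn.manifold import TSNE
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "scikit-learn is required for the 2-D embedding; "
            "the rest of the pipeline works without it"
        ) from exc
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    coords = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
        **tsne_kwargs,
    ).fit_transform(table.values)
    return pd.DataFrame(
        {
            "event_id": table.event_ids,
            "label": table.labels,
            "source": table.sources,
            "dim1": coords[:, 0],
            "dim2": coords[:, 1],
        }
    )
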