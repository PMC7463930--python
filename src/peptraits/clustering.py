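"""K-means clustering of standardized ACC tables with silhouette model selection.

Peptides are clustered on plain Euclidean distance in the standardized
36-dimensional ACC space. Centroids are initialised with k-means++ and the
best-inertia run of ``n_init`` restarts is kept; k is selected between
``kmin`` and ``kmax`` by the best mean silhouette coefficient over all
peptides. Cluster-vs-group composition is tested with a Pearson chi² test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass(frozen=True)
class ClusterModel:
    """A fitted k-means clustering in standardized descriptor space."""

    k: int
    labels: pd.Series  # peptide id -> cluster index
    inertia: float
    mean_silhouette: float
    seed: int


def kmeans(X: pd.DataFrame, k: int, n_init: int = 100, seed: int = 0) -> ClusterModel:
    """Best-of-``n_init`` k-means++ run by inertia; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X)}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        random_state=seed,
        tol=1e-8,
        max_iter=300,
    ).fit(X.to_numpy())
    labels = pd.Series(km.labels_, index=X.index, name="cluster")
    sil = mean_silhouette(X, labels)
    return ClusterModel(k, labels, float(km.inertia_), sil, seed)


def mean_silhouette(X: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette (b−a)/max(a,b) over peptides, Euclidean distance.

    Degenerate coincident points (a = b = 0) score 0 by scikit-learn's
    convention, which we adopt.
    """
    lab = labels.loc[X.index].to_numpy()
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    if np.all(counts == 1):
        raise ValueError("silhouette undefined for singleton-only clusterings")
    return float(silhouette_score(X.to_numpy(), lab, metric="euclidean"))


def select_k(
    X: pd.DataFrame,
    kmin: int = 2,
    kmax: int = 10,
    n_init: int = 100,
    seed: int = 0,
) -> tuple[ClusterModel, pd.Series]:
    """Fit k-means for k in [kmin, kmax], return the best-silhouette model.

    Ties go to the smallest k. The full per-k silhouette table is returned so
    the selection is auditable.
    """
    kmax = min(kmax, len(X) - 1)  # silhouette needs a non-singleton partition
    models = {k: kmeans(X, k, n_init=n_init, seed=seed) for k in range(kmin, kmax + 1)}
    silhouettes = pd.Series(
        {k: m.mean_silhouette for k, m in models.items()}, name="mean_silhouette"
    )
    best_k = int(silhouettes.idxmax())  # idxmax takes the first (smallest) max
    return models[best_k], silhouettes


def composition_table(labels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Contingency table of functional groups (rows) × clusters (columns)."""
    return pd.crosstab(groups.loc[labels.index], labels)


def composition_test(
    labels: pd.Series, groups: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi² (no continuity correction) of group × cluster counts.

    Returns ``(chi2, dof, p, expected_counts)``.
    """
    table = composition_table(labels, groups)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(res.expected_freq, index=table.index, columns=table.columns)
    return float(res.statistic), int(res.dof), float(res.pvalue), expected
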