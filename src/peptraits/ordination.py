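"""PCA of standardized ACC tables, correlation circles, and central hulls.

The peptide physico-chemical space is visualised by projecting peptides onto
the leading principal components of their standardized ACC descriptors.
Variable contributions are summarised as correlation circles (Pearson
correlation of each descriptor with each PC score). Group occupancy in the PC
plane is summarised by the convex hull of the 50% most central peptides of
each group — "central" meaning nearest to the group mean in the displayed
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # peptides × components
    loadings: pd.DataFrame  # variables × components
    explained_variance_ratio: pd.Series
    explained_variance: pd.Series


def pca(X: pd.DataFrame, ncomp: int = 3) -> PCAResult:
    """PCA via eigendecomposition of the sample covariance of ``X``.

    Signs follow a deterministic convention: within each component the
    largest-magnitude loading is positive, so score tables reproduce across
    runs and platforms.
    """
    if len(X) <= ncomp:
        raise ValueError(f"need more than ncomp={ncomp} rows")
    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if ncomp > rank:
        raise ValueError(f"ncomp={ncomp} exceeds data rank {rank}")
    model = PCA(n_components=ncomp, svd_solver="full")
    scores = model.fit_transform(X.to_numpy())
    components = model.components_  # ncomp × nvar
    for c in range(ncomp):
        pivot = np.argmax(np.abs(components[c]))
        if components[c, pivot] < 0:
            components[c] *= -1
            scores[:, c] *= -1
    names = [f"PC{c+1}" for c in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        loadings=pd.DataFrame(components.T, index=X.columns, columns=names),
        explained_variance_ratio=pd.Series(model.explained_variance_ratio_, index=names),
        explained_variance=pd.Series(model.explained_variance_, index=names),
    )


def correlation_circle(X: pd.DataFrame, result: PCAResult) -> pd.DataFrame:
    """Pearson correlation of each descriptor column with each PC score."""
    if (X.std(axis=0, ddof=1) == 0).any():
        raise ValueError("correlation undefined for constant columns")
    out = {}
    for pc in result.scores.columns:
        s = result.scores[pc].to_numpy()
        out[pc] = [float(np.corrcoef(X[c].to_numpy(), s)[0, 1]) for c in X.columns]
    return pd.DataFrame(out, index=X.columns)


def central_convex_area(
    scores: pd.DataFrame, fraction: float = 0.5
) -> np.ndarray:
    """Convex hull of the ``fraction`` most central points of a group.

    Takes the ceil(fraction*n) points nearest (Euclidean) to the group mean in
    the given plane and returns hull vertices in counter-clockwise order.
    Degenerate selections (< 3 points, or collinear) are returned as the
    points themselves (a segment or a point).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pts = scores.to_numpy(dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points in the group")
    center = pts.mean(axis=0)
    dist = np.linalg.norm(pts - center, axis=1)
    nsel = int(np.ceil(fraction * len(pts)))
    sel = pts[np.argsort(dist, kind="stable")[:nsel]]
    if nsel < 3:
        return sel
    try:
        hull = ConvexHull(sel)
    except Exception:  # collinear selection
        order = np.lexsort((sel[:, 1], sel[:, 0]))
        return sel[[order[0], order[-1]]]
    return sel[hull.vertices]  # scipy returns CCW order in 2-D


def group_hulls(
    scores: pd.DataFrame, groups: pd.Series, fraction: float = 0.5
) -> dict[str, np.ndarray]:
    """Central convex area per group with >= 3 members, in the score plane."""
    hulls = {}
    for g, idx in groups.groupby(groups).groups.items():
        pts = scores.loc[scores.index.intersection(idx)]
        if len(pts) >= 3:
            hulls[str(g)] = central_convex_area(pts, fraction)
    return hulls
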