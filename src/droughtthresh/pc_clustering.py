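"""PCA feature extraction over covariates and PC-space mesh neighborhoods.

Grid cells with comparable climate and vegetation conditions are pooled not
by geographic adjacency but by proximity in the space of the first three
principal components of the seven covariates.  Each PC axis is cut into bins
of width 4% of its range (25 bins); a cell's pooling neighborhood is every
cell within a 3x3x3 block of bins around its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synthetic import COVARIATE_NAMES

__all__ = [
    "PCEmbedding",
    "NeighborhoodIndex",
    "fit_pca",
    "mesh_assign",
    "neighborhoods",
    "DEFAULT_MIN_SAMPLES",
]

#: Minimum pooled cell-year count for percentile statistics
#: (9 grid cells x 18 years).
DEFAULT_MIN_SAMPLES = 162


@dataclass
class PCEmbedding:
    """Scores on the leading PCs plus full-decomposition diagnostics."""

    scores: np.ndarray  # (cell, n_retained)
    loadings: np.ndarray  # (n_variables, n_retained)
    explained: np.ndarray  # variance fractions for every component
    variables: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


@dataclass
class NeighborhoodIndex:
    """Per-cell mesh triple and pooled member set."""

    mesh: np.ndarray  # (cell, 3) int bin triples
    members: list[np.ndarray]  # member cell indices, includes the cell itself
    sufficient: np.ndarray  # bool, pooled cell-year count meets the gate
    pooled_counts: np.ndarray  # members * years
    min_samples: int


def fit_pca(covariates: pd.DataFrame, n_components: int = 3) -> PCEmbedding:
    """PCA of the standardized covariate table.

    Covariates are centered and scaled to unit variance (they carry
    incommensurate units), so the decomposition acts on their correlation
    structure.  Zero-variance columns are dropped with a warning.  The sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    cols = [c for c in COVARIATE_NAMES if c in covariates.columns]
    if len(cols) != len(COVARIATE_NAMES):
        cols = list(covariates.columns)
    X = covariates[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates entering PCA must have no missing entries")
    if X.shape[0] < 8:
        raise ValueError("PCA needs at least 8 cells")
    if X.shape[0] <= n_components:
        raise ValueError("fewer cells than retained components")

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance covariates: {[c for c, k in zip(cols, keep) if not k]}",
            stacklevel=2,
        )
        X = X[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd

    n_comp_full = min(Z.shape)
    pca = PCA(n_components=n_comp_full, svd_solver="full")
    scores_full = pca.fit_transform(Z)
    comps = pca.components_  # (component, variable)

    # Deterministic sign: largest-magnitude loading positive.
    for j in range(comps.shape[0]):
        k = np.argmax(np.abs(comps[j]))
        if comps[j, k] < 0:
            comps[j] *= -1.0
            scores_full[:, j] *= -1.0

    n_ret = min(n_components, n_comp_full)
    return PCEmbedding(
        scores=scores_full[:, :n_ret],
        loadings=comps[:n_ret].T,
        explained=pca.explained_variance_ratio_,
        variables=tuple(cols),
    )


def mesh_assign(embedding: PCEmbedding, width_frac: float = 0.04) -> np.ndarray:
    """Bin each PC axis into windows of width ``width_frac`` of its range.

    With the default 4% width each axis carries 25 bins; the axis maximum is
    assigned to the top bin (closed upper edge), interior edge ties go to the
    upper bin via floor.  A degenerate axis (max == min) collapses to a
    single bin with a warning.
    """
    s = embedding.scores
    n_bins = int(round(1.0 / width_frac))
    mesh = np.zeros(s.shape, dtype=int)
    for ax in range(s.shape[1]):
        lo, hi = float(s[:, ax].min()), float(s[:, ax].max())
        if hi == lo:
            warnings.warn(f"degenerate PC axis {ax}: single bin", stacklevel=2)
            continue
        width = (hi - lo) * width_frac
        idx = np.floor((s[:, ax] - lo) / width).astype(int)
        mesh[:, ax] = np.clip(idx, 0, n_bins - 1)
    return mesh


def neighborhoods(
    mesh: np.ndarray,
    n_years: int,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> NeighborhoodIndex:
    """Members of each cell's 3x3x3 mesh window (Chebyshev distance <= 1).

    A cell whose pooled cell-year count (members x years) falls below
    ``min_samples`` is flagged insufficient rather than erroring.
    """
    mesh = np.asarray(mesh, dtype=int)
    n_cells = mesh.shape[0]
    buckets: dict[tuple[int, ...], list[int]] = {}
    for i, triple in enumerate(map(tuple, mesh)):
        buckets.setdefault(triple, []).append(i)

    offsets = np.array(np.meshgrid(*([[-1, 0, 1]] * mesh.shape[1]), indexing="ij")).reshape(
        mesh.shape[1], -1
    ).T
    members: list[np.ndarray] = []
    for triple in map(tuple, mesh):
        got: list[int] = []
        for off in offsets:
            got.extend(buckets.get(tuple(np.add(triple, off)), ()))
        members.append(np.array(sorted(got), dtype=int))
    counts = np.array([m.size * n_years for m in members])
    return NeighborhoodIndex(
        mesh=mesh,
        members=members,
        sufficient=counts >= min_samples,
        pooled_counts=counts,
        min_samples=min_samples,
    )
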