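"""Ordination of morphology feature tables and community tables.

Morphology feature tables (samples x textural descriptors) are summarized by
PCA on centered, unit-variance-scaled columns; community tables by principal
coordinates analysis (PCoA) on the quantitative Jaccard (Ruzicka) distance
``D = 2B/(1+B)`` with B the Bray-Curtis dissimilarity of the abundance
vectors.  Because the sign of an ordination axis is arbitrary, an explicit
orientation step fixes the reading of the first axis (e.g. "more complex
morphology = more negative PC1").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .fingerprints import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "quantitative_jaccard",
    "pcoa",
    "pca_scaled",
    "orient_axis",
]


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if v.min() < 0:
            raise ValueError("distances must be nonnegative")
        self.values = v


@dataclass
class OrdinationResult:
    """Sample scores with per-axis variance fractions.

    ``eigenvalues`` are the full spectrum (PCoA may contain negative values;
    their summed magnitude is reported as ``negative_eigenvalue_mass`` and no
    correction is applied).  ``loadings`` are present for PCA only.
    """

    scores: pd.DataFrame  # samples x axes
    variance_fraction: np.ndarray
    method: str
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    loadings: pd.DataFrame | None = None
    negative_eigenvalue_mass: float = 0.0
    orientation_reference: str | None = None

    def axis(self, k: int = 0) -> pd.Series:
        return self.scores.iloc[:, k]


def quantitative_jaccard(table: CommunityTable | pd.DataFrame) -> DistanceMatrix:
    """Quantitative Jaccard (Ruzicka) distances between community rows.

    ``B = sum|x-y| / sum(x+y)`` (Bray-Curtis), ``D = 2B/(1+B)``.  A pair of
    all-zero rows is assigned D = 0 with a warning.
    """
    df = table.abundance if isinstance(table, CommunityTable) else table
    x = df.to_numpy(dtype=float)
    if x.min() < 0:
        raise ValueError("abundances must be nonnegative")
    empty = x.sum(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        b = squareform(pdist(x, metric="braycurtis"))
    d = 2.0 * b / (1.0 + b)
    if empty.any():
        warnings.warn("all-zero community rows present; their distances set to 0")
        d[np.ix_(empty, empty)] = 0.0
    d = np.nan_to_num(d, nan=1.0)
    d[np.ix_(empty, empty)] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, ids=[str(i) for i in df.index])


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis via Gower double-centering.

    ``-1/2 J D^2 J`` with the centering projector ``J = I - 11'/n`` is
    eigendecomposed; coordinates come from positive eigenvalues only and
    variance fractions are relative to the summed positive eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are reported unaltered.
    """
    d = dm.values
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if n_axes > n:
        raise ValueError("more axes requested than samples")
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12 * max(abs(evals[0]), 1.0)
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos) if n_pos else 0
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pos_sum = evals[pos].sum() if n_pos else 1.0
    vf = evals[:k] / pos_sum
    neg_mass = float(-evals[evals < 0].sum())
    scores = pd.DataFrame(coords, index=dm.ids,
                          columns=[f"PCoA{i + 1}" for i in range(k)])
    return OrdinationResult(scores=scores, variance_fraction=vf, method="pcoa",
                            eigenvalues=evals, negative_eigenvalue_mass=neg_mass)


def pca_scaled(features: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """PCA of a samples x variables table after centering and unit-variance scaling.

    Columns that are constant (or entirely missing, e.g. a descriptor
    undefined for every sample) carry no information on the correlation
    structure; they are dropped with a log message.  Variance fractions are
    eigenvalues of the correlation structure over the number of retained
    variables.
    """
    if features.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = features.to_numpy(dtype=float)
    keep = []
    for jcol in range(x.shape[1]):
        col = x[:, jcol]
        if np.isnan(col).any() or np.nanstd(col) == 0:
            continue
        keep.append(jcol)
    dropped = x.shape[1] - len(keep)
    if dropped:
        logger.info("pca_scaled: dropped %d constant/missing columns", dropped)
    if not keep:
        raise ValueError("all columns constant or missing")
    cols = features.columns[keep]
    x = x[:, keep]
    n = x.shape[0]
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    evals = s ** 2 / (n - 1)
    k = min(n_axes, len(evals))
    # deterministic sign: largest-magnitude loading of each axis positive
    for i in range(k):
        jmax = np.argmax(np.abs(vt[i]))
        if vt[i, jmax] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=features.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    loadings = pd.DataFrame(vt[:k].T, index=cols,
                            columns=[f"PC{i + 1}" for i in range(k)])
    vf = evals[:k] / len(keep)
    return OrdinationResult(scores=scores, variance_fraction=vf, method="pca",
                            eigenvalues=evals, loadings=loadings)


def orient_axis(result: OrdinationResult, axis: str,
                reference: str, desired_sign: int) -> OrdinationResult:
    """Fix the arbitrary sign of an ordination axis against a reference.

    For PCA the reference is a variable name whose loading on ``axis`` must
    have ``desired_sign``; for PCoA it is a sample id whose score must.  The
    operation is an involution: flipping twice restores the input.
    """
    if desired_sign not in (-1, 1):
        raise ValueError("desired_sign must be +1 or -1")
    scores = result.scores.copy()
    loadings = result.loadings.copy() if result.loadings is not None else None
    if loadings is not None and reference in loadings.index:
        current = loadings.loc[reference, axis]
    elif reference in scores.index:
        current = scores.loc[reference, axis]
    else:
        raise ValueError(f"orientation reference {reference!r} not found")
    if current != 0 and np.sign(current) != desired_sign:
        scores[axis] = -scores[axis]
        if loadings is not None:
            loadings[axis] = -loadings[axis]
    out = OrdinationResult(scores=scores, variance_fraction=result.variance_fraction,
                           method=result.method, eigenvalues=result.eigenvalues,
                           loadings=loadings,
                           negative_eigenvalue_mass=result.negative_eigenvalue_mass,
                           orientation_reference=f"{reference}:{axis}:{desired_sign:+d}")
    return out
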