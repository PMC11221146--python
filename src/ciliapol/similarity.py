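"""Vector-space comparison of transcriptomic population signatures.

Each population (e.g. a microglial subtype such as PAM, ATM, CD11c+,
DAM1/2, MGnD, LDAM) is represented by an n-dimensional attribute vector
v = (v_1, ..., v_n) whose components are the differential-expression
levels of n genes on a shared gene axis.  Similarity between populations
i and j is quantified two ways:

* Euclidean distance   d_ij = sqrt(sum_k (v_k^i - v_k^j)^2)
  (smaller distance = more similar), and
* absolute-cosine correlation   C_ij = |cos theta| = |v^i . v^j| / (||v^i|| ||v^j||)
  in [0, 1]: 0 means orthogonal attribute vectors (no relationship),
  1 means linearly dependent vectors (equivalent profiles).

The pairwise matrices are ordered by average-linkage hierarchical
clustering on the distance matrix, so related populations sit adjacent
in heat maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InvalidParameterError, UndefinedStatisticError

__all__ = [
    "ExpressionProfileSet",
    "SimilarityResult",
    "align_genes",
    "euclidean_distance",
    "cosine_correlation",
    "similarity_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionProfileSet:
    """Population-labelled gene -> differential-expression vectors.

    ``values`` is a populations x genes DataFrame; NaN marks a gene not
    measured (or not reported) for that population.  ``scale`` documents
    the convention of the attribute values (default log2 fold change
    versus a homeostatic baseline) so mixed conventions are detectable.
    """

    values: pd.DataFrame
    scale: str = "log2fc"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.duplicated().any():
            raise InvalidParameterError("duplicate population labels")
        if self.values.columns.duplicated().any():
            raise InvalidParameterError("duplicate gene identifiers")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise InvalidParameterError("profile set must be non-empty")
        finite_per_pop = np.isfinite(self.values.to_numpy(dtype=float)).any(axis=1)
        if not finite_per_pop.all():
            bad = list(self.values.index[~finite_per_pop])
            raise InvalidParameterError(f"populations with no finite value: {bad}")

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SimilarityResult:
    labels: list[str]
    distance: pd.DataFrame  # symmetric, zero diagonal
    correlation: pd.DataFrame  # symmetric, unit diagonal, values in [0, 1]
    n_genes_used: int
    cluster_order: list[str]
    linkage_record: np.ndarray
    excluded: list[str] = field(default_factory=list)


def align_genes(profiles: ExpressionProfileSet) -> ExpressionProfileSet:
    """Restrict to genes with finite values in every population (intersection).

    Gene symbols are matched case-insensitively; the number of dropped
    genes is logged.  Zero-filling missing genes is deliberately not the
    default because it biases the cosine correlation toward 0.
    """
    if len(profiles.populations) < 2:
        raise InvalidParameterError("gene alignment needs >= 2 populations")
    df = profiles.values.copy()
    df.columns = [str(c).upper() for c in df.columns]
    if df.columns.duplicated().any():
        # same symbol under different cases: average duplicates
        df = df.T.groupby(level=0).mean().T
    keep = np.isfinite(df.to_numpy(dtype=float)).all(axis=0)
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise InvalidParameterError("no gene is finite in all populations")
    if dropped:
        logger.info("align_genes: dropped %d of %d genes", dropped, keep.size)
    return ExpressionProfileSet(df.loc[:, keep], scale=profiles.scale)


def euclidean_distance(v, w) -> float:
    """Euclidean distance d = sqrt(sum_k (v_k - w_k)^2).

    Accumulation is sequential over the gene axis, so the result is
    bit-reproducible and independent of any vectorised summation order.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or v.size < 1:
        raise InvalidParameterError("vectors must be 1-D and of equal length >= 1")
    total = 0.0
    for a, b in zip(v.tolist(), w.tolist()):
        total += (a - b) ** 2
    return math.sqrt(total)


def cosine_correlation(v, w) -> float:
    """Absolute-cosine correlation |v.w| / (||v|| ||w||) in [0, 1].

    Sequential accumulation, as in :func:`euclidean_distance`.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or v.size < 1:
        raise InvalidParameterError("vectors must be 1-D and of equal length >= 1")
    dot = nv = nw = 0.0
    for a, b in zip(v.tolist(), w.tolist()):
        dot += a * b
        nv += a * a
        nw += b * b
    if nv == 0.0 or nw == 0.0:
        raise UndefinedStatisticError("cosine correlation undefined for a zero vector")
    return min(abs(dot) / (math.sqrt(nv) * math.sqrt(nw)), 1.0)


def similarity_matrix(
    profiles: ExpressionProfileSet, linkage: str = "average"
) -> SimilarityResult:
    """All pairwise distances and correlations, plus a clustering order.

    Populations whose aligned vector is all-zero are excluded with a
    warning (their direction, hence correlation, is undefined).  The
    cluster order comes from agglomerative clustering (``linkage``
    method, default average) on the Euclidean distance matrix.
    """
    aligned = align_genes(profiles)
    mat = aligned.values.to_numpy(dtype=float)
    labels = aligned.populations

    norms = np.linalg.norm(mat, axis=1)
    excluded = [lab for lab, nrm in zip(labels, norms) if nrm == 0.0]
    if excluded:
        logger.warning("excluding zero-vector populations: %s", excluded)
        keep = norms > 0.0
        mat = mat[keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise InvalidParameterError("need >= 2 non-zero populations")

    p = len(labels)
    dist = np.zeros((p, p))
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            dist[i, j] = dist[j, i] = euclidean_distance(mat[i], mat[j])
            corr[i, j] = corr[j, i] = cosine_correlation(mat[i], mat[j])

    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(link)]

    return SimilarityResult(
        labels=labels,
        distance=pd.DataFrame(dist, index=labels, columns=labels),
        correlation=pd.DataFrame(corr, index=labels, columns=labels),
        n_genes_used=mat.shape[1],
        cluster_order=order,
        linkage_record=link,
        excluded=excluded,
    )


def plot_correlation_heatmap(result: SimilarityResult, path) -> None:
    """Save a heat map of the correlation matrix in cluster order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.cluster_order
    c = result.correlation.loc[order, order]
    fig, ax = plt.subplots(figsize=(0.6 * len(order) + 2, 0.6 * len(order) + 1.5))
    im = ax.imshow(c.to_numpy(), vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    fig.colorbar(im, ax=ax, label="|cos theta|")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
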