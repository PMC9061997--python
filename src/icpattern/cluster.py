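"""Resampling-based consensus clustering with PAC k-selection and PCA embedding.

Patterns are discovered by repeatedly subsampling patients, clustering each
subsample with k-medoids (PAM) on a 1 - Pearson-correlation distance, and
recording how often each pair of patients co-clusters when co-sampled.  The
number of clusters is chosen by minimizing the proportion of ambiguous
clustering (PAC): the mass of consensus entries falling strictly between the
two ends of an ambiguity interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

__all__ = [
    "ConsensusClustering",
    "ConsensusResult",
    "KSelection",
    "Embedding",
    "consensus_cluster",
    "select_k",
    "pca_embed",
    "canonicalize_pattern_labels",
]


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of X (samples x features)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if (norms == 0).any():
        raise ValueError("sample with zero variance across features")
    C = (Xc @ Xc.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(C, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialization of PAM: deterministic given the matrix."""
    m = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, D[:, c])
    return np.asarray(medoids)


def _pam(D: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """k-medoids (PAM): BUILD init then alternating assignment/medoid update.

    Fully deterministic, so consensus variability comes from item resampling
    alone.
    """
    m = D.shape[0]
    medoids = _pam_build(D, k)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster at the point farthest from its medoid
                far = int(np.argmax(D[np.arange(m), medoids[labels]]))
                new_medoids[c] = far
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if (new_medoids == medoids).all() and (new_labels == labels).all():
            break
        medoids, labels = new_medoids, new_labels
    return labels


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering over item resamples with a PAM base clusterer.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k for the base clusterer and the final cut.
    n_resamples : int
        Number of subsampled clustering runs (default 1000).
    item_fraction : float in (0, 1]
        Fraction of samples drawn (without replacement) per run.
    random_state : int or None
        Seed for the resampling and medoid initialization stream.

    Fitted attributes: ``consensus_matrix_`` (n x n, symmetric, unit diagonal)
    with entries = co-clustered count / co-sampled count; ``labels_`` from
    average-linkage hierarchical clustering of 1 - consensus cut at k.
    """

    def __init__(self, n_clusters: int = 3, n_resamples: int = 1000,
                 item_fraction: float = 0.8, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_resamples = n_resamples
        self.item_fraction = item_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if k >= n:
            raise ValueError(f"n_clusters={k} must be < n_samples={n}")
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not (0.0 < self.item_fraction <= 1.0):
            raise ValueError("item_fraction must be in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        D = _correlation_distance(X)
        m = max(k + 1, int(round(self.item_fraction * n)))

        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(self.n_resamples):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            labels = _pam(D[np.ix_(idx, idx)], k)
            ind = np.zeros(n, dtype=bool)
            ind[idx] = True
            sampled += np.outer(ind, ind)
            for c in range(k):
                member = np.zeros(n, dtype=bool)
                member[idx[labels == c]] = True
                together += np.outer(member, member)

        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        off = ~np.eye(n, dtype=bool)
        if (sampled[off] == 0).any():
            warnings.warn("some sample pairs were never co-sampled; consensus set to 0")
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0

        Z = linkage(squareform(1.0 - M, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < k:
            warnings.warn("hierarchical cut produced fewer than k nonempty clusters")
        self.consensus_matrix_ = M
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame  # samples x samples in [0, 1]
    assignments: pd.Series  # sample -> 1..k
    n_resamples: int
    item_fraction: float


@dataclass
class KSelection:
    k_grid: list[int]
    cdf_grid: np.ndarray  # evaluation points in [0, 1]
    cdf: dict[int, np.ndarray]  # per-k empirical CDF of off-diagonal entries
    pac: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int


@dataclass
class Embedding:
    components: pd.DataFrame  # samples x d
    explained_variance_ratio: np.ndarray


def consensus_cluster(
    expr_subset: ExpressionMatrix,
    k: int,
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    seed: int | None = None,
    standardize_genes: bool = True,
) -> ConsensusResult:
    """Consensus-cluster samples of a genes x samples matrix at a fixed k.

    ``standardize_genes`` z-scores each gene across samples first (constant
    genes dropped), so the sample-sample correlation distance reflects the
    relative expression profile rather than gene-level baselines.
    """
    model = ConsensusClustering(
        n_clusters=k, n_resamples=n_resamples,
        item_fraction=item_fraction, random_state=seed,
    )
    V = expr_subset.values
    if standardize_genes:
        sd = V.std(axis=1, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"dropping {(sd == 0).sum()} constant gene(s) before clustering")
            V = V.loc[sd > 0]
            sd = sd[sd > 0]
        V = V.sub(V.mean(axis=1), axis=0).div(sd, axis=0)
    X = V.to_numpy(dtype=float).T
    labels = model.fit_predict(X)
    samples = expr_subset.samples
    return ConsensusResult(
        k=k,
        consensus_matrix=pd.DataFrame(model.consensus_matrix_, index=samples, columns=samples),
        assignments=pd.Series(labels, index=samples, name="cluster"),
        n_resamples=n_resamples,
        item_fraction=item_fraction,
    )


def _off_diagonal(M: np.ndarray) -> np.ndarray:
    return M[~np.eye(M.shape[0], dtype=bool)]


def select_k(
    results: dict[int, ConsensusResult],
    ambiguity_interval: tuple[float, float] = (0.1, 0.9),
) -> KSelection:
    """Choose k by minimum PAC over the grid; ties break toward smaller k.

    PAC_k = CDF(u2) - CDF(u1), the fraction of off-diagonal consensus entries
    inside the ambiguity interval (u1, u2].  The relative change in area under
    the consensus CDF (delta-area) is reported alongside for k >= 3.
    """
    if not results:
        raise ValueError("empty k grid")
    u1, u2 = ambiguity_interval
    ks = sorted(results)
    grid = np.linspace(0.0, 1.0, 101)
    cdf: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    area: dict[int, float] = {}
    for k in ks:
        entries = _off_diagonal(results[k].consensus_matrix.to_numpy())
        cdf[k] = np.array([(entries <= u).mean() for u in grid])
        pac[k] = float((entries <= u2).mean() - (entries <= u1).mean())
        area[k] = float(np.trapezoid(cdf[k], grid))
    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta_area[k] = (area[k] - prev) / prev if prev > 0 else np.inf
    best = min(pac, key=lambda k: (pac[k], k))
    return KSelection(ks, grid, cdf, pac, delta_area, chosen_k=best)


def pca_embed(expr: ExpressionMatrix, d: int = 2) -> Embedding:
    """Project samples onto the top-d principal components of z-scored genes.

    Constant genes are dropped with a warning before standardization.
    """
    V = expr.values
    sd = V.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} constant gene(s) before PCA")
        V = V.loc[keep]
        sd = sd[keep]
    if d > min(V.shape):
        raise ValueError(f"d={d} exceeds matrix rank bound {min(V.shape)}")
    Z = ((V.sub(V.mean(axis=1), axis=0)).div(sd, axis=0)).to_numpy().T  # samples x genes
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(Z)
    return Embedding(
        components=pd.DataFrame(
            coords, index=expr.samples, columns=[f"PC{i+1}" for i in range(d)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def canonicalize_pattern_labels(
    expr_subset: ExpressionMatrix, assignments: pd.Series
) -> pd.Series:
    """Rename clusters A, B, C, ... in decreasing order of mean expression.

    'A' is the high-expression (immune-hot) pattern, making labels comparable
    across runs regardless of the arbitrary numeric labels.
    """
    means = {
        c: expr_subset.values.loc[:, assignments.index[assignments == c]].to_numpy().mean()
        for c in assignments.unique()
    }
    order = sorted(means, key=lambda c: -means[c])
    letters = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    return assignments.map(letters).rename("pattern")
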