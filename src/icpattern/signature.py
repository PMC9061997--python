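"""Signature-gene derivation and the PCA-based ICscore.

Signature genes are the intersection of differentially expressed genes across
all pairwise pattern contrasts.  The ICscore of a sample is the sum of its
coordinates on the first two principal components of the z-scored signature
matrix; each component is oriented so that the sum of its gene loadings is
non-positive, so higher mean signature expression drives the score DOWN and
the low-ICscore group is the immune-hot one.  Patients are dichotomized at
the cutpoint maximizing the absolute standardized log-rank statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .survival import logrank_z

__all__ = [
    "DEGResult",
    "ICScoreModel",
    "ICscoreResult",
    "cluster_degs",
    "derive_icscore",
    "dichotomize_by_cutpoint",
]


@dataclass
class DEGResult:
    contrasts: dict[tuple[str, str], pd.DataFrame]  # gene -> statistic, p, adj_p
    significant: dict[tuple[str, str], list[str]]
    intersection: list[str]
    fdr_threshold: float


def cluster_degs(
    expr: ExpressionMatrix,
    labels: pd.Series,
    fdr_threshold: float = 0.05,
    method: str = "welch",
) -> DEGResult:
    """Differential expression between every unordered pair of patterns.

    Per gene and contrast: Welch t (default) or Wilcoxon rank-sum on log-scale
    expression, Benjamini-Hochberg adjustment within each contrast, and the
    intersection of significant genes across all contrasts.
    """
    if method not in ("welch", "wilcoxon"):
        raise ValueError(f"unknown test {method!r}")
    labels = labels.reindex(expr.samples).dropna()
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 pattern labels")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"pattern(s) with fewer than 3 samples: {small.index.tolist()}")

    V = expr.values[labels.index]
    contrasts: dict[tuple[str, str], pd.DataFrame] = {}
    significant: dict[tuple[str, str], list[str]] = {}
    for a, b in combinations(levels, 2):
        A = V.loc[:, labels[labels == a].index].to_numpy(dtype=float)
        B = V.loc[:, labels[labels == b].index].to_numpy(dtype=float)
        if method == "welch":
            stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        else:
            stat, p = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
        p = np.where(np.isfinite(p), p, 1.0)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        df = pd.DataFrame({"statistic": stat, "p": p, "adj_p": adj}, index=expr.genes)
        contrasts[(a, b)] = df
        significant[(a, b)] = df.index[df["adj_p"] < fdr_threshold].tolist()

    inter: set[str] | None = None
    for genes in significant.values():
        inter = set(genes) if inter is None else inter & set(genes)
    intersection = [g for g in expr.genes if g in (inter or set())]
    return DEGResult(contrasts, significant, intersection, fdr_threshold)


class ICScoreModel(TransformerMixin, BaseEstimator):
    """PCA signature scorer: score = PC1 + PC2 sample coordinates.

    Fit on a samples x signature-genes frame.  Genes are z-scored with the
    training mean/sd (``z_score=True``, the default), the two leading
    components are extracted, and each is sign-oriented so its loading sum is
    <= 0.  Scoring held-out samples reuses the stored standardization and
    rotation, so joint and held-out scoring agree on the same fitted model.

    Fitted attributes: ``mean_``, ``sd_``, ``loadings_`` (genes x 2),
    ``explained_variance_ratio_``, ``genes_``.
    """

    def __init__(self, z_score: bool = True):
        self.z_score = z_score

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        sd = X.std(axis=0, ddof=1)
        usable = sd[sd > 0].index
        dropped = [g for g in X.columns if g not in set(usable)]
        if dropped:
            warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}")
        if len(usable) < 2:
            raise ValueError("need at least 2 signature genes with nonzero variance")
        X = X[usable]
        self.genes_ = list(usable)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1) if self.z_score else pd.Series(1.0, index=usable)
        Z = (X - self.mean_) / self.sd_
        n_comp = min(2, len(usable), len(X) - 1)
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(Z.to_numpy())
        load = pca.components_.T  # genes x n_comp
        # orient: loading sum <= 0 so high signature expression lowers the score
        for j in range(load.shape[1]):
            if load[:, j].sum() > 0:
                load[:, j] = -load[:, j]
        if load.shape[1] == 1:
            load = np.hstack([load, np.zeros_like(load)])
        self.loadings_ = pd.DataFrame(load, index=self.genes_, columns=["PC1", "PC2"])
        ev = np.zeros(2)
        ev[: n_comp] = pca.explained_variance_ratio_
        self.explained_variance_ratio_ = ev
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)
        missing = [g for g in self.genes_ if g not in X.columns]
        if missing:
            raise ValueError(f"matrix missing signature gene(s): {missing[:5]}")
        Z = (X[self.genes_] - self.mean_) / self.sd_
        coords = Z.to_numpy() @ self.loadings_.to_numpy()
        return pd.Series(coords.sum(axis=1), index=X.index, name="ICscore")


@dataclass
class ICscoreResult:
    scores: pd.Series  # per-sample ICscore
    model: ICScoreModel
    cutpoint: float | None = None
    groups: pd.Series | None = None  # "low" / "high"


def derive_icscore(
    expr: ExpressionMatrix,
    signature_genes: list[str],
    z_score: bool = True,
) -> ICscoreResult:
    """Fit the signature PCA on the given genes and score every sample.

    Genes absent from the matrix are dropped with a warning; fewer than two
    usable genes is an error.
    """
    present = [g for g in signature_genes if g in set(expr.genes)]
    absent = sorted(set(signature_genes) - set(present))
    if absent:
        warnings.warn(f"{len(absent)} signature gene(s) not in matrix: {absent[:5]}")
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    X = expr.values.loc[present].T  # samples x genes
    model = ICScoreModel(z_score=z_score).fit(X)
    return ICscoreResult(scores=model.transform(X), model=model)


def dichotomize_by_cutpoint(
    scores: pd.Series,
    times,
    events,
    minprop: float = 0.1,
) -> tuple[float, pd.Series]:
    """Survival-optimal dichotomization by maximally selected log-rank statistic.

    Candidate cutpoints are midpoints between consecutive sorted unique scores
    whose induced groups each hold at least ``minprop`` of the samples.  The
    chosen cutpoint maximizes |(O - E)/sqrt(V)| of the two-group log-rank
    statistic; exact ties break toward the candidate nearest the median score.
    Samples strictly below the cutpoint are labelled "low".
    """
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must be in (0, 0.5)")
    scores = pd.Series(scores).astype(float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n = len(scores)
    uniq = np.unique(scores.to_numpy())
    if uniq.size < 2:
        raise ValueError("all scores identical: no candidate cutpoints")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    s = scores.to_numpy()
    n_low = np.array([(s < c).sum() for c in mids])
    ok = (n_low >= minprop * n) & ((n - n_low) >= minprop * n)
    candidates = mids[ok]
    if candidates.size == 0:
        raise ValueError("no candidate cutpoint satisfies the minprop constraint")
    z = np.array([abs(logrank_z(times, events, s < c)) for c in candidates])
    best = z.max()
    tied = candidates[z == best]
    median = np.median(s)
    cut = float(tied[np.argmin(np.abs(tied - median))])
    groups = pd.Series(np.where(s < cut, "low", "high"), index=scores.index, name="group")
    return cut, groups
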