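"""Single-sample gene-set enrichment (ssGSEA), ESTIMATE-style stromal/immune
scores, and score-score association statistics.

The ssGSEA statistic for one sample and one gene set ranks all genes by the
sample's expression (average ranks on ties), walks the ranked list from the
top, and accumulates the difference between a rank-weighted in-set cumulative
distribution and the uniform out-of-set cumulative distribution:

    ES = sum_i [ P_in^w(i) - P_out(i) ],
    P_in^w(i) = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha,
    P_out(i)  = #(j<=i, j not in S) / (N - |S|),

where r_j is the within-sample rank of gene j.  The score depends only on
within-sample ranks, so it is invariant to any strictly monotone transform of
a sample's expression values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["SsGSEAScorer", "ssgsea", "estimate_scores", "correlate"]


def _sample_scores(values: np.ndarray, set_masks: np.ndarray, alpha: float) -> np.ndarray:
    """ES for one sample (values: n_genes) against each set mask (n_sets x n_genes)."""
    n = values.size
    ranks = rankdata(values)  # 1..n, average ties; high expression = high rank
    order = np.argsort(-ranks, kind="stable")
    r_ord = ranks[order]
    w = r_ord ** alpha
    scores = np.empty(set_masks.shape[0])
    for s, mask in enumerate(set_masks):
        in_ord = mask[order]
        w_in = np.where(in_ord, w, 0.0)
        denom_in = w_in.sum()
        p_in = np.cumsum(w_in) / denom_in
        n_out = n - int(in_ord.sum())
        if n_out == 0:
            # set covers the whole matrix: out-of-set walk is empty, score
            # comes from the in-set walk alone
            p_out = np.zeros(n)
        else:
            p_out = np.cumsum(~in_ord) / n_out
        scores[s] = float((p_in - p_out).sum())
    return scores


class SsGSEAScorer(TransformerMixin, BaseEstimator):
    """Transform a samples x genes expression frame into samples x set scores.

    Parameters
    ----------
    gene_sets : mapping of set name -> list of gene symbols
    alpha : float
        Rank weight exponent (canonical ssGSEA value 0.25).
    normalize : {"none", "minmax"}
        Optional min-max rescaling of each set's scores across samples.

    Sets sharing no gene with the matrix are dropped with a warning; the
    retained names are in ``set_names_`` and the dropped ones in
    ``dropped_sets_``.
    """

    def __init__(self, gene_sets: dict[str, list[str]], alpha: float = 0.25,
                 normalize: str = "none"):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.normalize not in ("none", "minmax"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        genes = pd.Index(X.columns)
        masks, names, dropped = [], [], []
        for name, members in self.gene_sets.items():
            mask = genes.isin(set(members))
            if mask.any():
                masks.append(mask)
                names.append(name)
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(f"dropping {len(dropped)} set(s) with no gene overlap: {dropped}")
        if not names:
            raise ValueError("no gene set overlaps the expression matrix")
        self.feature_names_in_ = np.asarray(genes)
        self.set_masks_ = np.array(masks)
        self.set_names_ = names
        self.dropped_sets_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "set_masks_")
        if not np.array_equal(np.asarray(X.columns), self.feature_names_in_):
            raise ValueError("gene columns differ from those seen at fit time")
        V = X.to_numpy(dtype=float)
        out = np.stack([
            _sample_scores(V[i], self.set_masks_, self.alpha) for i in range(V.shape[0])
        ])
        scores = pd.DataFrame(out, index=X.index, columns=self.set_names_)
        if self.normalize == "minmax":
            rng = scores.max(axis=0) - scores.min(axis=0)
            rng = rng.replace(0.0, 1.0)
            scores = (scores - scores.min(axis=0)) / rng
        return scores


def ssgsea(
    expr: ExpressionMatrix,
    sets: GeneSetCollection | dict[str, list[str]],
    alpha: float = 0.25,
    normalize: str = "none",
) -> pd.DataFrame:
    """ssGSEA scores as a sets x samples DataFrame."""
    gene_sets = sets.sets if isinstance(sets, GeneSetCollection) else dict(sets)
    scorer = SsGSEAScorer(gene_sets, alpha=alpha, normalize=normalize)
    X = expr.values.T  # samples x genes
    return scorer.fit(X).transform(X).T


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Stromal/immune signature scores and their sum, per sample.

    StromalScore and ImmuneScore are the (unnormalized) ssGSEA scores of the
    two signatures; ESTIMATEScore is exactly their sum.
    """
    genes = set(expr.genes)
    for name, s in (("stromal", stromal_set), ("immune", immune_set)):
        if not genes & set(s):
            raise ValueError(f"{name} signature shares no gene with the matrix")
    scores = ssgsea(expr, {"StromalScore": stromal_set, "ImmuneScore": immune_set},
                    alpha=alpha, normalize="none").T
    scores["ESTIMATEScore"] = scores["StromalScore"] + scores["ImmuneScore"]
    return scores


def correlate(
    x,
    y,
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Association between two per-sample score vectors.

    spearman: Pearson on average-ranked data, p from the t approximation.
    distance: sample distance correlation from double-centered Euclidean
    distance matrices, p from a seeded permutation null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: correlation undefined")
        return (np.nan, np.nan)
    if method == "spearman":
        rho, p = spearmanr(x, y)
        return float(rho), float(p)
    if method == "distance":
        import pingouin as pg

        dcor, p = pg.distance_corr(x, y, alternative="greater",
                                   n_boot=n_permutations, seed=seed)
        return float(dcor), float(p)
    raise ValueError(f"unknown method {method!r}")
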