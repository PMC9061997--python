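"""Empirical-Bayes location/scale batch correction (ComBat model).

The model writes expression of gene g in sample j of batch i as

    x_gij = alpha_g + gamma_ig + delta_ig * eps_gij

with per-(gene,batch) location gamma and scale delta.  Parametric empirical
Bayes shrinks the per-batch estimates toward batch-level priors (normal for
gamma, inverse-gamma for delta^2) with method-of-moments hyperparameters,
iterated to convergence.  With shrinkage disabled the raw per-batch
estimates are used, so location-only correction equalizes per-gene batch
means to machine precision.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

__all__ = ["CombatAdjuster", "combat_adjust"]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


class CombatAdjuster(TransformerMixin, BaseEstimator):
    """Location/scale empirical-Bayes batch corrector.

    Parameters
    ----------
    mode : {"location_scale", "location_only"}
        Whether to correct batch scale as well as batch location.
    parametric : bool
        If True, shrink per-(gene,batch) estimates with parametric EB priors;
        if False, use the raw estimates (no shrinkage).
    tol, max_iter :
        Convergence controls for the EB fixed-point iteration.

    Fitted attributes (samples are rows, genes are columns):
    ``alpha_`` per-gene grand effect; ``sigma_`` per-gene pooled scale;
    ``gamma_`` and ``delta2_`` per-(batch,gene) location and squared scale;
    ``batches_`` batch levels; ``flagged_genes_`` indices of genes with zero
    pooled variance, which pass through unchanged.
    """

    def __init__(self, mode: str = "location_scale", parametric: bool = True,
                 tol: float = 1e-4, max_iter: int = 100):
        self.mode = mode
        self.parametric = parametric
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, batch):
        if self.mode not in ("location_scale", "location_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.shape[0] != batch.shape[0]:
            raise ValueError("batch labels must align with rows of X")
        levels, codes = np.unique(batch, return_inverse=True)
        counts = np.bincount(codes)
        self.single_batch_ = len(levels) < 2
        if self.single_batch_:
            warnings.warn("single batch: correction is the identity transform")
            self.batches_ = levels
            self.flagged_genes_ = np.array([], dtype=int)
            return self
        if (counts < 2).any():
            bad = levels[counts < 2].tolist()
            raise ValueError(f"batch(es) with a single sample: {bad}")

        n_batches, n_genes = len(levels), X.shape[1]
        n_total = X.shape[0]
        # per-batch means, batch-size-weighted grand effect
        batch_means = np.stack([X[codes == i].mean(axis=0) for i in range(n_batches)])
        alpha = counts @ batch_means / n_total
        resid = X - batch_means[codes]
        var_pooled = (resid ** 2).sum(axis=0) / n_total
        flagged = np.flatnonzero(var_pooled <= 0)
        if flagged.size:
            warnings.warn(f"{flagged.size} gene(s) constant within every batch; left unchanged")
            var_pooled = var_pooled.copy()
            var_pooled[flagged] = 1.0  # placeholder; flagged genes bypass correction
        sigma = np.sqrt(var_pooled)

        Z = (X - alpha) / sigma
        gamma_hat = np.stack([Z[codes == i].mean(axis=0) for i in range(n_batches)])
        # ddof=0 keeps the pooled and per-batch variances on the same scale,
        # so shrinkage-off correction is exactly idempotent
        delta2_hat = np.stack([
            Z[codes == i].var(axis=0) for i in range(n_batches)
        ])

        if not self.parametric:
            gamma_star, delta2_star = gamma_hat, delta2_hat
            self.prior_params_ = None
        else:
            gamma_bar = gamma_hat.mean(axis=1)
            t2 = gamma_hat.var(axis=1, ddof=1)
            m = delta2_hat.mean(axis=1)
            s2 = delta2_hat.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a_prior = (2.0 * s2 + m ** 2) / s2
                b_prior = (m * s2 + m ** 3) / s2
            gamma_star = np.empty_like(gamma_hat)
            delta2_star = np.empty_like(delta2_hat)
            for i in range(n_batches):
                n_i = counts[i]
                Zi = Z[codes == i]
                g_new = gamma_hat[i].copy()
                d_new = delta2_hat[i].copy()
                for _ in range(self.max_iter):
                    g_old, d_old = g_new, d_new
                    g_new = _postmean(gamma_hat[i], gamma_bar[i], n_i, d_old, t2[i])
                    sum_sq = ((Zi - g_new) ** 2).sum(axis=0)
                    d_new = _postvar(sum_sq, n_i, a_prior[i], b_prior[i])
                    change = max(
                        np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
                        np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-12),
                    )
                    if change < self.tol:
                        break
                gamma_star[i], delta2_star[i] = g_new, d_new
            self.prior_params_ = {
                "gamma_bar": gamma_bar, "t2": t2, "a_prior": a_prior, "b_prior": b_prior,
            }

        if self.mode == "location_only":
            delta2_star = np.ones_like(delta2_star)

        if flagged.size:  # flagged genes bypass correction entirely
            gamma_star[:, flagged] = 0.0
            delta2_star[:, flagged] = 1.0
        self.alpha_ = alpha
        self.sigma_ = sigma
        self.gamma_ = gamma_star
        self.delta2_ = delta2_star
        self.batches_ = levels
        self.flagged_genes_ = flagged
        return self

    def transform(self, X, batch):
        check_is_fitted(self, "batches_")
        X = np.asarray(X, dtype=float)
        if self.single_batch_:
            return X.copy()
        batch = np.asarray(batch)
        unknown = sorted(set(batch) - set(self.batches_))
        if unknown:
            raise ValueError(f"unknown batch level(s): {unknown}")
        codes = np.searchsorted(self.batches_, batch)
        Z = (X - self.alpha_) / self.sigma_
        adj = (Z - self.gamma_[codes]) / np.sqrt(self.delta2_[codes])
        out = adj * self.sigma_ + self.alpha_
        if self.flagged_genes_.size:
            out[:, self.flagged_genes_] = X[:, self.flagged_genes_]
        return out

    def fit_transform(self, X, batch):
        return self.fit(X, batch).transform(X, batch)


def combat_adjust(
    expr: ExpressionMatrix,
    mode: str = "location_scale",
    parametric: bool = True,
) -> tuple[ExpressionMatrix, CombatAdjuster]:
    """Correct batch effects in a genes x samples expression matrix.

    Returns the corrected matrix (same dimensions, batch labels preserved)
    and the fitted :class:`CombatAdjuster`.
    """
    if expr.batch is None:
        raise ValueError("expression matrix has no batch labels")
    model = CombatAdjuster(mode=mode, parametric=parametric)
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    corrected = model.fit_transform(X, expr.batch.to_numpy())
    out = pd.DataFrame(corrected.T, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.batch), model
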