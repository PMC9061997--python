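"""Mutation-landscape summaries from MAF-style tables and thresholded CNV calls.

Covers per-sample tumor mutation burden (nonsynonymous count, optionally per
megabase), per-gene mutation frequency, pairwise co-occurrence / mutual
exclusivity by Fisher exact tests with BH adjustment, and CNV gain/loss
frequencies.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .survival import _odds_ratio

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "compute_tmb",
    "mutation_frequency",
    "cooccurrence",
    "cnv_frequency",
]

NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Translation_Start_Site", "Nonstop_Mutation",
})


def _nonsyn(maf: pd.DataFrame, nonsyn_classes) -> pd.DataFrame:
    return maf[maf["Variant_Classification"].isin(set(nonsyn_classes))]


def compute_tmb(
    maf: pd.DataFrame,
    sample_ids: list[str],
    nonsyn_classes=NONSYNONYMOUS_CLASSES,
    capture_mb: float | None = None,
) -> pd.Series:
    """Per-sample nonsynonymous mutation count (TMB).

    Samples with no MAF records get TMB 0.  With ``capture_mb`` the count is
    divided by the capture size to give mutations per megabase.
    """
    ns = _nonsyn(maf, nonsyn_classes)
    silent = set(maf["Variant_Classification"].unique()) - set(nonsyn_classes)
    if silent:
        warnings.warn(f"classes not counted toward TMB: {sorted(silent)}")
    counts = ns.groupby("Tumor_Sample_Barcode").size()
    tmb = counts.reindex(sample_ids, fill_value=0).astype(float).rename("TMB")
    if capture_mb is not None:
        if capture_mb <= 0:
            raise ValueError("capture_mb must be positive")
        tmb = tmb / capture_mb
    return tmb


def _mutated_matrix(maf: pd.DataFrame, genes: list[str], sample_ids: list[str],
                    nonsyn_classes=NONSYNONYMOUS_CLASSES) -> pd.DataFrame:
    """Boolean genes x samples matrix: sample has >= 1 nonsynonymous hit in gene."""
    ns = _nonsyn(maf, nonsyn_classes)
    ns = ns[ns["Hugo_Symbol"].isin(set(genes)) & ns["Tumor_Sample_Barcode"].isin(set(sample_ids))]
    mat = pd.DataFrame(False, index=list(genes), columns=list(sample_ids))
    for gene, sample in zip(ns["Hugo_Symbol"], ns["Tumor_Sample_Barcode"]):
        mat.loc[gene, sample] = True
    return mat


def mutation_frequency(
    maf: pd.DataFrame,
    genes: list[str],
    sample_ids: list[str],
    nonsyn_classes=NONSYNONYMOUS_CLASSES,
) -> pd.Series:
    """Fraction of samples with at least one nonsynonymous hit per gene.

    Multiple hits in one sample count once; genes absent from the MAF get 0.
    """
    mat = _mutated_matrix(maf, genes, sample_ids, nonsyn_classes)
    return mat.mean(axis=1).rename("mutation_frequency")


def cooccurrence(
    maf: pd.DataFrame,
    genes: list[str],
    sample_ids: list[str],
    fdr: float = 0.05,
    nonsyn_classes=NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Pairwise mutation co-occurrence / exclusivity over a gene panel.

    Per pair: Fisher exact p on the 2x2 mutated/wild-type cross-tab (exact p
    from the uncorrected table; Haldane-corrected odds ratio when a cell is
    zero), BH adjustment across all pairs, and a co-occurring / exclusive /
    none label.  Pairs involving a gene mutated in zero samples are skipped.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    mat = _mutated_matrix(maf, genes, sample_ids, nonsyn_classes)
    mutated_counts = mat.sum(axis=1)
    rows = []
    for g1, g2 in combinations(genes, 2):
        if mutated_counts[g1] == 0 or mutated_counts[g2] == 0:
            warnings.warn(f"pair ({g1}, {g2}) skipped: gene with zero mutated samples")
            continue
        m1 = mat.loc[g1].to_numpy()
        m2 = mat.loc[g2].to_numpy()
        a = int((m1 & m2).sum())
        b = int((m1 & ~m2).sum())
        c = int((~m1 & m2).sum())
        d = int((~m1 & ~m2).sum())
        table = np.array([[a, b], [c, d]])
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append({"gene1": g1, "gene2": g2, "n11": a, "n10": b, "n01": c, "n00": d,
                     "odds_ratio": _odds_ratio(table), "p": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    _, adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["adj_p"] = adj
    out["label"] = "none"
    out.loc[(out["odds_ratio"] > 1) & (out["adj_p"] < fdr), "label"] = "co-occurring"
    out.loc[(out["odds_ratio"] < 1) & (out["adj_p"] < fdr), "label"] = "exclusive"
    return out


def cnv_frequency(cnv: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Per-gene CNV gain and loss frequencies from a {-1, 0, +1} call matrix."""
    missing = [g for g in genes if g not in cnv.index]
    if missing:
        raise ValueError(f"gene(s) absent from CNV table: {missing}")
    sub = cnv.loc[genes]
    return pd.DataFrame({
        "gain_freq": (sub == 1).mean(axis=1),
        "loss_freq": (sub == -1).mean(axis=1),
    })
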