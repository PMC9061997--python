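"""End-to-end orchestration: simulate/load -> batch-correct -> discover
patterns -> enrich -> derive signature and ICscore -> survival -> genomics.

All stage outputs are plain TSV plus a JSON manifest; a fixed config and seed
reproduce the bundle bit-identically.  One global seed fans out to per-stage
substreams, so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .batch import combat_adjust
from .cluster import ConsensusResult, canonicalize_pattern_labels, consensus_cluster, \
    pca_embed, select_k
from .enrich import correlate, estimate_scores, ssgsea
from .genomics import compute_tmb, cooccurrence, mutation_frequency
from .io import ExpressionMatrix, read_clinical, read_cnv, read_expression_matrix, \
    read_gmt, read_maf
from .registry import load_icg_registry
from .signature import cluster_degs, derive_icscore, dichotomize_by_cutpoint
from .simulate import SimulationConfig, simulate_cohort
from .survival import cox_fit, km_estimate, logrank_test

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config object for the whole pipeline.

    Exactly one of ``simulate`` (overrides for :class:`SimulationConfig`) or
    ``inputs`` (paths for expression/clinical/maf/cnv/sets) must be given;
    ``seed`` is mandatory.
    """

    seed: int
    simulate: dict | None = None
    inputs: dict | None = None
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6)
    force_k_icg: int | None = None
    force_k_gene: int | None = 2
    n_resamples: int = 1000
    item_fraction: float = 0.8
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: str = "none"
    fdr: float = 0.05
    minprop: float = 0.1
    ties: str = "efron"
    batch_mode: str = "location_scale"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "k_grid" in raw:
            raw["k_grid"] = tuple(raw["k_grid"])
        return cls(**raw)


@dataclass
class ReportBundle:
    patterns: pd.Series  # sample -> ICGcluster letter
    k_selection: pd.DataFrame
    consensus: dict[int, ConsensusResult]
    enrichment: pd.DataFrame  # sets x samples
    estimate: pd.DataFrame | None
    degs: list[str]
    gene_clusters: pd.Series
    icscore: pd.DataFrame  # sample, ICscore, group
    cutpoint: float
    survival_tables: dict[str, pd.DataFrame]
    genomics_tables: dict[str, pd.DataFrame]
    crosswalk: pd.DataFrame
    summary: dict
    manifest: dict


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    clinical = read_clinical(paths["clinical"])
    batch = clinical["batch"] if "batch" in clinical.columns else None
    expr = read_expression_matrix(paths["expression"], batch=batch)
    maf = read_maf(paths["maf"]) if "maf" in paths else None
    cnv = read_cnv(paths["cnv"]) if "cnv" in paths else None
    sets = read_gmt(paths["sets"]) if "sets" in paths else None
    return expr, clinical, maf, cnv, sets, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ReportBundle:
    """Run every stage and write the tabular report bundle to ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_icg_registry()

    # ----- stage: data -----------------------------------------------------
    if config.simulate is not None:
        sim_args = dict(config.simulate)
        sim_args.setdefault(
            "seed", int(substream(config.seed, "simulate").integers(2 ** 31)))
        for key in ("n_per_pattern", "tmb_mean_by_pattern"):
            if key in sim_args:
                sim_args[key] = tuple(sim_args[key])
        cohort = simulate_cohort(SimulationConfig(**sim_args))
        expr, clinical = cohort.expression, cohort.clinical
        maf, cnv, sets = cohort.maf, cohort.cnv, cohort.gene_sets
        truth = cohort.truth
    else:
        expr, clinical, maf, cnv, sets, truth = _load_inputs(config)

    # ----- stage: batch correction -----------------------------------------
    if expr.batch is not None and expr.batch.nunique() > 1:
        expr, _ = combat_adjust(expr, mode=config.batch_mode)

    # ----- stage: pattern discovery over the ICG panel ----------------------
    icg_expr = expr.subset_genes(registry.genes)
    seed_icg = int(substream(config.seed, "cluster_icg").integers(2 ** 31))
    results = {
        k: consensus_cluster(icg_expr, k, n_resamples=config.n_resamples,
                             item_fraction=config.item_fraction, seed=seed_icg + k)
        for k in config.k_grid
    }
    ksel = select_k(results)
    k_icg = config.force_k_icg or ksel.chosen_k
    patterns = canonicalize_pattern_labels(icg_expr, results[k_icg].assignments)
    k_table = pd.DataFrame({
        "k": list(ksel.pac), "PAC": list(ksel.pac.values()),
        "delta_area": [ksel.delta_area[k] for k in ksel.pac],
        "chosen": [k == ksel.chosen_k for k in ksel.pac],
    })
    embedding = pca_embed(icg_expr, d=2)

    # ----- stage: immune enrichment -----------------------------------------
    scores = ssgsea(expr, sets, alpha=config.ssgsea_alpha,
                    normalize=config.ssgsea_normalize) if sets is not None else pd.DataFrame()
    est = None
    if sets is not None and {"StromalSignature", "ImmuneSignature"} <= set(sets.names()):
        est = estimate_scores(expr, sets["StromalSignature"], sets["ImmuneSignature"],
                              alpha=config.ssgsea_alpha)

    # ----- stage: signature derivation --------------------------------------
    degs = cluster_degs(expr, patterns, fdr_threshold=config.fdr)
    sig_genes = degs.intersection
    if len(sig_genes) < 2:
        raise RuntimeError("signature stage: fewer than 2 intersection DEGs")
    seed_gene = int(substream(config.seed, "cluster_gene").integers(2 ** 31))
    gene_res = consensus_cluster(expr.subset_genes(sig_genes), config.force_k_gene or 2,
                                 n_resamples=config.n_resamples,
                                 item_fraction=config.item_fraction, seed=seed_gene)
    gene_clusters = canonicalize_pattern_labels(
        expr.subset_genes(sig_genes), gene_res.assignments)
    ic = derive_icscore(expr, sig_genes)
    aligned = clinical.loc[ic.scores.index]
    cutpoint, groups = dichotomize_by_cutpoint(
        ic.scores, aligned["os_time"], aligned["os_event"], minprop=config.minprop)
    icscore_table = pd.DataFrame({"ICscore": ic.scores, "group": groups})

    # ----- stage: survival ---------------------------------------------------
    surv_tables: dict[str, pd.DataFrame] = {}
    km_rows = []
    for name, curve_groups in (("icscore_group", groups), ("pattern", patterns)):
        for level in sorted(curve_groups.unique()):
            idx = curve_groups.index[curve_groups == level]
            km = km_estimate(aligned.loc[idx, "os_time"], aligned.loc[idx, "os_event"])
            for t, n_j, d_j, s, v in zip(km.times, km.at_risk, km.events,
                                         km.survival, km.greenwood_var):
                km_rows.append({"stratum": name, "level": level, "time": t,
                                "at_risk": n_j, "events": d_j, "survival": s,
                                "greenwood_var": v})
    surv_tables["km"] = pd.DataFrame(km_rows)
    lr_group = logrank_test(aligned["os_time"], aligned["os_event"], groups)
    lr_pattern = logrank_test(aligned["os_time"], aligned["os_event"], patterns)
    surv_tables["logrank"] = pd.DataFrame([
        {"contrast": "icscore_group", "statistic": lr_group.statistic,
         "df": lr_group.df, "p": lr_group.p_value},
        {"contrast": "pattern", "statistic": lr_pattern.statistic,
         "df": lr_pattern.df, "p": lr_pattern.p_value},
    ])
    cox_df = pd.DataFrame({
        "os_time": aligned["os_time"], "os_event": aligned["os_event"],
        "high_icscore": (groups == "high").astype(float),
    })
    cox = cox_fit(cox_df, ["high_icscore"], ties=config.ties)
    surv_tables["cox"] = pd.DataFrame({
        "beta": cox.beta, "HR": cox.hazard_ratio, "se": cox.se,
        "ci_lower": cox.ci_lower, "ci_upper": cox.ci_upper, "p": cox.p_value,
    })

    # ----- stage: genomics ---------------------------------------------------
    gen_tables: dict[str, pd.DataFrame] = {}
    spearman_tmb = np.nan
    if maf is not None:
        samples = list(ic.scores.index)
        tmb = compute_tmb(maf, samples)
        gen_tables["tmb"] = tmb.to_frame()
        spearman_tmb, _ = correlate(tmb.to_numpy(), ic.scores.to_numpy(), "spearman")
        panel = maf.loc[maf["Variant_Classification"] != "Silent", "Hugo_Symbol"]
        top = panel.value_counts().head(20).index.tolist()
        freq_rows = {}
        for level in ("low", "high"):
            idx = groups.index[groups == level].tolist()
            freq_rows[f"freq_{level}"] = mutation_frequency(maf, top, idx)
        gen_tables["mutfreq"] = pd.DataFrame(
            {"freq_all": mutation_frequency(maf, top, samples), **freq_rows})
        gen_tables["cooccur"] = cooccurrence(maf, top[:10], samples, fdr=config.fdr)
    if cnv is not None:
        from .genomics import cnv_frequency

        present = [g for g in registry.genes if g in cnv.index]
        gen_tables["cnvfreq"] = cnv_frequency(cnv, present)

    # ----- crosswalk and summary --------------------------------------------
    status = np.where(aligned["os_event"] == 1, "dead", "alive")
    crosswalk = pd.DataFrame({
        "ICGcluster": patterns, "geneCluster": gene_clusters,
        "ICscore": ic.scores, "group": groups, "survival_status": status,
    })
    crosswalk.index.name = "sample_id"

    mean_by_pattern = ic.scores.groupby(patterns).mean().to_dict()
    summary = {
        "n_samples": len(ic.scores),
        "chosen_k": int(ksel.chosen_k),
        "k_used": int(k_icg),
        "n_signature_genes": len(sig_genes),
        "cutpoint": float(cutpoint),
        "mean_icscore_by_pattern": {k: float(v) for k, v in mean_by_pattern.items()},
        "logrank_p_icscore_group": float(lr_group.p_value),
        "cox_hr_high_vs_low": float(cox.hazard_ratio.iloc[0]),
        "spearman_icscore_tmb": float(spearman_tmb),
        "pc1_variance_fraction": float(embedding.explained_variance_ratio[0]),
    }
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        true_pat = pd.Series(truth["pattern"]).reindex(patterns.index)
        summary["pattern_recovery_ari"] = float(
            adjusted_rand_score(true_pat, patterns))

    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
            .encode()).hexdigest(),
    }

    # ----- write bundle ------------------------------------------------------
    patterns.rename("ICGcluster").to_frame().to_csv(out / "assignments.tsv", sep="\t")
    k_table.to_csv(out / "kselect.tsv", sep="\t", index=False)
    if len(scores):
        scores.to_csv(out / "enrichment_scores.tsv", sep="\t")
    if est is not None:
        est.to_csv(out / "estimate.tsv", sep="\t")
    pd.Series(sig_genes, name="gene").to_csv(out / "signature_genes.tsv",
                                             sep="\t", index=False)
    icscore_table.to_csv(out / "icscore.tsv", sep="\t")
    for name, table in {**surv_tables, **gen_tables}.items():
        table.to_csv(out / f"{name}.tsv", sep="\t")
    crosswalk.to_csv(out / "crosswalk.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ReportBundle(
        patterns=patterns, k_selection=k_table, consensus=results,
        enrichment=scores, estimate=est, degs=sig_genes,
        gene_clusters=gene_clusters, icscore=icscore_table, cutpoint=cutpoint,
        survival_tables=surv_tables, genomics_tables=gen_tables,
        crosswalk=crosswalk, summary=summary, manifest=manifest,
    )
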