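"""Synthetic multi-batch gastric-cancer-like cohorts with planted structure.

The generator emits linked expression / clinical / mutation / CNV / gene-set
data with the statistical structure the downstream analysis assumes:

* three planted expression patterns over the 31-gene immune-checkpoint panel
  (pattern A immune-hot/high expression, C cold/low, B intermediate with its
  own per-gene profile so the three patterns are separable in correlation
  space), with a configurable minority of panel genes reversed;
* a block of pattern-associated background genes (the planted signature)
  among null background genes;
* immune-cell gene sets whose true abundance tracks a per-sample latent
  immune axis (hot = high), plus stromal/immune summary signatures;
* exponential survival with a protective hot axis and independent uniform
  censoring calibrated to a marginal censor fraction;
* MAF-like mutations whose burden is higher in hot patterns (so TMB is
  anti-correlated with the ICscore downstream), with a few driver genes given
  pattern-dependent mutation probabilities;
* additive-location / multiplicative-scale batch effects, exactly the model
  the ComBat-style corrector fits;
* categorical clinical subtypes (MSI, stage, N stage) with pattern-dependent
  proportions.

Everything is a pure function of (config, seed): identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .io import ExpressionMatrix, GeneSetCollection, write_clinical, write_cnv, \
    write_expression_matrix, write_gmt, write_maf
from .registry import load_icg_registry

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort",
           "simulate_survival", "write_cohort"]

PATTERNS = ("A", "B", "C")


@dataclass
class SimulationConfig:
    """Parameters of the planted cohort; defaults are the study conditions."""

    n_per_pattern: tuple[int, int, int] = (80, 80, 80)
    n_batches: int = 3
    batch_shift_sd: float = 0.4  # per-(gene,batch) additive location sd, log2 units
    batch_scale_sd: float = 0.15  # per-(gene,batch) log scale factor sd
    n_background_genes: int = 2000  # includes the signature block
    n_signature_genes: int = 300  # truly pattern-associated background genes
    icg_effect: float = 1.5  # per-pattern mean shift on the ICG panel, log2 units
    n_reversed_icgs: int = 2  # panel genes with reversed direction (CD276/VTCN1-like)
    signature_effect: float = 1.0
    signature_frac_positive: float = 0.8  # fraction of signature genes up in hot samples
    residual_sd: float = 1.0
    axis_sd: float = 0.3  # within-pattern sd of the latent immune axis
    n_immune_sets: int = 28
    immune_set_size: int = 30
    immune_set_effect: float = 0.8
    stromal_effect: float = 0.4
    baseline_rate: float = 0.02  # exponential hazard per month
    hazard_log_hr: float = float(np.log(2.0))  # protective log-HR per unit hot axis
    censor_rate: float = 0.3
    tmb_mean_by_pattern: tuple[float, float, float] = (12.0, 8.0, 5.0)  # hot > cold
    n_mutation_genes: int = 100
    driver_mutation_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ARID1A": (0.57, 0.35, 0.17),
            "PIK3CA": (0.41, 0.25, 0.10),
            "TP53": (0.36, 0.40, 0.42),
        }
    )
    msi_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {  # per pattern: (MSI-H, MSI-L, MSS)
            "A": (0.50, 0.30, 0.20),
            "B": (0.25, 0.35, 0.40),
            "C": (0.08, 0.27, 0.65),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_pattern):
            raise ValueError("n_per_pattern entries must be positive")
        if self.n_batches <= 0 or self.n_background_genes <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.n_signature_genes <= self.n_background_genes):
            raise ValueError("n_signature_genes must fit inside the background block")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        for probs in self.msi_probs.values():
            if not np.isclose(sum(probs), 1.0):
                raise ValueError("MSI probabilities must sum to 1")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame  # indexed by sample_id; includes true_* columns
    maf: pd.DataFrame
    cnv: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: dict


def simulate_survival(linear_predictor, baseline_rate: float, censor_rate: float,
                      seed: int | np.random.Generator = 0):
    """Exponential event times with independent uniform censoring.

    Event times are exponential with rate ``baseline_rate * exp(lp)``; censor
    times are Uniform(0, tau) with tau calibrated (by bisection on the exact
    marginal censoring probability) so the expected censored fraction equals
    ``censor_rate``.  Returns (os_time, os_event).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictor must be finite")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate == 0.0:
        return t_event, np.ones(lp.size, dtype=int)

    def marginal_censor(tau: float) -> float:
        x = rates * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0 / rates.min()
    while marginal_censor(hi) > censor_rate:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if marginal_censor(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    t_cens = rng.uniform(0.0, tau, size=lp.size)
    os_event = (t_event <= t_cens).astype(int)
    os_time = np.minimum(t_event, t_cens)
    return os_time, os_event


def _multinomial_draw(rng, probs, n):
    return rng.choice(len(probs), size=n, p=np.asarray(probs, dtype=float))


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full linked synthetic cohort from ``config`` (pure in seed)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    registry = load_icg_registry()
    icg_genes = registry.genes
    n_icg = len(icg_genes)
    n_pat = np.asarray(cfg.n_per_pattern)
    n = int(n_pat.sum())
    samples = [f"S{i+1:04d}" for i in range(n)]
    pattern = np.repeat(np.array(PATTERNS), n_pat)
    pat_code = np.repeat(np.arange(3), n_pat)  # A=0, B=1, C=2

    # latent immune axis: hot (A) high, cold (C) low
    rng_axis = substream(cfg.seed, "axis")
    axis_mean = np.array([1.0, 0.0, -1.0])[pat_code]
    z = axis_mean + rng_axis.normal(0.0, cfg.axis_sd, size=n)

    # --- gene panel layout -------------------------------------------------
    rng_genes = substream(cfg.seed, "genes")
    n_sig = cfg.n_signature_genes
    n_null = cfg.n_background_genes - n_sig
    sig_genes = [f"SIG{i+1:04d}" for i in range(n_sig)]
    null_genes = [f"BG{i+1:04d}" for i in range(n_null)]
    imm_genes = [f"IMM{s+1:02d}G{j+1:02d}"
                 for s in range(cfg.n_immune_sets) for j in range(cfg.immune_set_size)]
    strm_genes = [f"STRMG{j+1:02d}" for j in range(cfg.immune_set_size)]
    est_imm_genes = [f"ESTIMMG{j+1:02d}" for j in range(cfg.immune_set_size)]
    genes = icg_genes + sig_genes + null_genes + imm_genes + strm_genes + est_imm_genes
    n_genes = len(genes)

    # --- mean structure ----------------------------------------------------
    base = rng_genes.normal(5.0, 1.0, size=n_genes)
    mean = np.tile(base[:, None], (1, n))

    # ICG panel: direction +1 except a reversed minority; pattern A shifted up,
    # C down, B at an intermediate per-gene level with its own profile shape
    icg_dir = np.ones(n_icg)
    coinhib = [i for i, g in enumerate(icg_genes) if g in ("CD276", "VTCN1")]
    reversed_idx = (coinhib[: cfg.n_reversed_icgs]
                    if cfg.n_reversed_icgs <= len(coinhib)
                    else rng_genes.choice(n_icg, cfg.n_reversed_icgs, replace=False))
    icg_dir[np.asarray(reversed_idx, dtype=int)] = -1.0
    # B's per-gene relative level: intermediate between A (+1) and C (-1) on
    # every gene, but with a distinctive profile shape so the three patterns
    # are separable under a scale-invariant correlation distance
    w_b = (rng_genes.choice([-1.0, 1.0], size=n_icg)
           * rng_genes.uniform(0.5, 0.9, size=n_icg))
    pat_shift = np.stack([np.ones(n_icg), w_b, -np.ones(n_icg)])  # pattern x gene
    mean[:n_icg, :] += (cfg.icg_effect * icg_dir * pat_shift[pat_code]).T

    # signature block: tracks the latent axis, mostly up in hot samples
    sig_sign = np.where(
        rng_genes.uniform(size=n_sig) < cfg.signature_frac_positive, 1.0, -1.0)
    lo = n_icg
    mean[lo:lo + n_sig, :] += np.outer(sig_sign * cfg.signature_effect, z)

    # immune-cell sets: per-set abundance multiplier, all up on the hot axis
    set_mult = rng_genes.uniform(0.4, 1.2, size=cfg.n_immune_sets)
    lo = n_icg + n_sig + n_null
    for s in range(cfg.n_immune_sets):
        rows = slice(lo + s * cfg.immune_set_size, lo + (s + 1) * cfg.immune_set_size)
        mean[rows, :] += cfg.immune_set_effect * set_mult[s] * z

    lo = n_icg + n_sig + n_null + cfg.n_immune_sets * cfg.immune_set_size
    mean[lo:lo + cfg.immune_set_size, :] += cfg.stromal_effect * z  # stromal
    lo += cfg.immune_set_size
    mean[lo:lo + cfg.immune_set_size, :] += cfg.immune_set_effect * z  # immune summary

    # --- batches and noise -------------------------------------------------
    rng_batch = substream(cfg.seed, "batch")
    batch = rng_batch.permutation(np.arange(n) % cfg.n_batches)
    gamma = rng_batch.normal(0.0, cfg.batch_shift_sd, size=(n_genes, cfg.n_batches))
    delta = np.exp(rng_batch.normal(0.0, cfg.batch_scale_sd, size=(n_genes, cfg.n_batches)))
    rng_noise = substream(cfg.seed, "noise")
    eps = rng_noise.normal(0.0, cfg.residual_sd, size=(n_genes, n))
    values = mean + gamma[:, batch] + delta[:, batch] * eps
    batch_labels = pd.Series([f"batch{b+1}" for b in batch], index=samples, name="batch")
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), batch=batch_labels)

    # --- survival ----------------------------------------------------------
    rng_surv = substream(cfg.seed, "survival")
    lp = -cfg.hazard_log_hr * z  # hot axis protective
    os_time, os_event = simulate_survival(lp, cfg.baseline_rate, cfg.censor_rate, rng_surv)

    # --- clinical categoricals ---------------------------------------------
    rng_clin = substream(cfg.seed, "clinical")
    msi_levels = np.array(["MSI-H", "MSI-L", "MSS"])
    msi = np.empty(n, dtype=object)
    stage_levels = np.array(["I", "II", "III", "IV"])
    stage_probs = {"A": (0.30, 0.35, 0.25, 0.10), "B": (0.20, 0.35, 0.30, 0.15),
                   "C": (0.10, 0.30, 0.35, 0.25)}
    n_levels = np.array(["N0", "N1", "N2", "N3"])
    n_probs = {"A": (0.45, 0.30, 0.15, 0.10), "B": (0.35, 0.30, 0.20, 0.15),
               "C": (0.20, 0.30, 0.25, 0.25)}
    stage_col = np.empty(n, dtype=object)
    nstage_col = np.empty(n, dtype=object)
    for p in PATTERNS:
        m = pattern == p
        msi[m] = msi_levels[_multinomial_draw(rng_clin, cfg.msi_probs[p], m.sum())]
        stage_col[m] = stage_levels[_multinomial_draw(rng_clin, stage_probs[p], m.sum())]
        nstage_col[m] = n_levels[_multinomial_draw(rng_clin, n_probs[p], m.sum())]
    clinical = pd.DataFrame({
        "os_time": os_time, "os_event": os_event, "stage": stage_col,
        "n_stage": nstage_col, "msi_subtype": msi, "batch": batch_labels.to_numpy(),
        "true_pattern": pattern, "true_immune_axis": z,
    }, index=pd.Index(samples, name="sample_id"))

    # --- mutations (MAF) ---------------------------------------------------
    rng_mut = substream(cfg.seed, "mutations")
    panel = [f"MUT{i+1:03d}" for i in range(cfg.n_mutation_genes)]
    nonsyn = np.array(["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                       "Splice_Site", "In_Frame_Del"])
    nonsyn_p = np.array([0.70, 0.10, 0.08, 0.07, 0.05])
    records = []
    tmb_mean = np.array(cfg.tmb_mean_by_pattern)[pat_code]
    for i, sid in enumerate(samples):
        k = rng_mut.poisson(tmb_mean[i])
        if k > 0:
            hit_genes = rng_mut.choice(panel, size=k, replace=True)
            classes = nonsyn[_multinomial_draw(rng_mut, nonsyn_p, k)]
            for g, c in zip(hit_genes, classes):
                records.append((g, sid, c))
        for drv, probs in cfg.driver_mutation_probs.items():
            if rng_mut.uniform() < probs[pat_code[i]]:
                records.append((drv, sid, "Missense_Mutation"))
        for _ in range(rng_mut.poisson(1.0)):  # silent passengers, not TMB
            records.append((rng_mut.choice(panel), sid, "Silent"))
    maf = pd.DataFrame(records, columns=[
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"])

    # --- CNV over the ICG panel --------------------------------------------
    rng_cnv = substream(cfg.seed, "cnv")
    gain_prone = {"LGALS9", "CD160", "KIR3DL1", "VSIR", "TNFSF4", "TNFSF18",
                  "CD40", "CD40LG"}
    loss_prone = {"PDCD1", "VTCN1", "TNFSF9", "CD70", "TNFSF14"}
    calls = np.zeros((n_icg, n), dtype=int)
    for gi, g in enumerate(icg_genes):
        p_gain, p_loss = (0.30, 0.05) if g in gain_prone else \
                         (0.05, 0.30) if g in loss_prone else (0.10, 0.10)
        u = rng_cnv.uniform(size=n)
        calls[gi] = np.where(u < p_gain, 1, np.where(u < p_gain + p_loss, -1, 0))
    cnv = pd.DataFrame(calls, index=icg_genes, columns=samples)

    # --- gene sets ----------------------------------------------------------
    sets = {f"ImmuneCell{s+1:02d}":
            imm_genes[s * cfg.immune_set_size:(s + 1) * cfg.immune_set_size]
            for s in range(cfg.n_immune_sets)}
    sets["StromalSignature"] = strm_genes
    sets["ImmuneSignature"] = est_imm_genes
    descriptions = {name: "synthetic" for name in sets}
    gene_sets = GeneSetCollection(sets, descriptions)

    truth = {
        "pattern": dict(zip(samples, pattern)),
        "immune_axis": dict(zip(samples, z.tolist())),
        "signature_genes": sig_genes,
        "signature_sign": dict(zip(sig_genes, sig_sign.tolist())),
        "icg_direction": dict(zip(icg_genes, icg_dir.tolist())),
        "immune_set_multiplier": dict(
            zip(sorted(s for s in sets if s.startswith("ImmuneCell")), set_mult.tolist())),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
    }
    return SyntheticCohort(expression, clinical, maf, cnv, gene_sets, truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write expression.tsv, clinical.tsv, mutations.maf, cnv.tsv, sets.gmt, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(cohort.expression, outdir / "expression.tsv")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    write_maf(cohort.maf, outdir / "mutations.maf")
    write_cnv(cohort.cnv, outdir / "cnv.tsv")
    write_gmt(cohort.gene_sets, outdir / "sets.gmt")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
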