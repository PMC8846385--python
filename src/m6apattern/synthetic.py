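"""Synthetic breast-cancer cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
three regulator-driven sample clusters, cluster-dependent DEGs and
immune-set activity, exponential survival with hazard tied to cluster and a
latent per-sample score, mutation burden anti-correlated with that score,
and planted regulator copy-number gains/losses.  A single master seed is
fanned out to named substreams (expression / survival / mutation / cnv /
clinical) so adding one output type never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data_model import (
    CNVMatrix,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MAFTable,
    default_regulator_catalog,
    write_clinical,
    write_cnv,
    write_expression,
    write_gene_sets,
    write_maf,
)

__all__ = ["SimulationConfig", "GroundTruth", "generate_cohort", "truth_report", "write_bundle"]

_SUBSTREAMS = ("expression", "survival", "mutation", "cnv", "clinical")

_NONSYN_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                   "Frame_Shift_Ins", "Splice_Site", "In_Frame_Del")
_NONSYN_PROBS = (0.70, 0.10, 0.07, 0.05, 0.05, 0.03)


@dataclass
class SimulationConfig:
    """Planted-structure cohort parameters.

    Defaults are desk-scale (n=300, 2000 genes, seconds to generate) with
    three clusters separated by +/-2 z on the regulators, 100 DEGs per
    cluster at 2 log2 units, survival driven by the latent score
    (coefficient -0.8: high score = lower hazard, mirroring the survival
    benefit of the high-score group), 30% censoring, and a mutation burden
    negatively coupled to the score (target Spearman about -0.4).
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_clusters: int = 3
    regulator_shift: float = 2.0
    n_deg_per_contrast: int = 100
    deg_effect: float = 2.0
    n_prognostic: int = 100
    prognostic_effect: float = 1.5
    cluster_score_means: tuple[float, ...] | None = None  # default evenly spread
    score_noise_sd: float = 0.75
    baseline_hazard: float = 1.0 / 1500.0   # events per day
    cluster_log_hazard: tuple[float, ...] | None = None   # default all zero
    score_hazard_coef: float = -0.8
    censoring_rate: float = 0.3
    tmb_score_correlation: float = -0.4
    tmb_mean: float = 20.0
    n_immune_sets: int = 6
    immune_set_size: int = 15
    immune_shift: float = 1.5
    immune_set_activation: dict[int, list[str]] | None = None
    n_pathway_sets: int = 4
    pathway_set_size: int = 20
    amplified_regulators: tuple[str, ...] = ("VIRMA", "METTL3", "IGF2BP1")
    amplification_rate: float = 0.30
    deleted_regulators: tuple[str, ...] = ("WTAP", "RBM15", "ZC3H13")
    deletion_rate: float = 0.25
    cnv_background_rate: float = 0.02
    regulator_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for name in ("regulator_shift", "deg_effect", "immune_shift", "prognostic_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.cluster_score_means is None:
            # evenly spread, first cluster highest (best prognosis with coef < 0)
            self.cluster_score_means = tuple(
                np.linspace(1.0, -1.0, self.n_clusters).tolist()
            )
        if len(self.cluster_score_means) != self.n_clusters:
            raise ValueError("cluster_score_means length must equal n_clusters")
        if self.cluster_log_hazard is None:
            self.cluster_log_hazard = tuple(0.0 for _ in range(self.n_clusters))
        if len(self.cluster_log_hazard) != self.n_clusters:
            raise ValueError("cluster_log_hazard length must equal n_clusters")


@dataclass
class GroundTruth:
    """Planted quantities the pipeline should recover."""

    cluster: pd.Series                      # 1..K per sample
    deg_membership: dict[str, list[str]]    # contrast id -> planted DEG genes
    prognostic_genes: list[str]
    latent_score: pd.Series                 # standardized driver of hazard/TMB
    expected_tmb: pd.Series                 # Poisson mean per sample
    immune_activation: dict[int, list[str]]


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def generate_cohort(config: SimulationConfig) -> tuple[
        ExpressionMatrix, ClinicalTable, GeneSetCollection, MAFTable, CNVMatrix, GroundTruth]:
    """Generate a full synthetic cohort; byte-reproducible from config.seed."""
    cfg = config
    catalog = default_regulator_catalog()
    regulators = catalog.symbols
    n_special = (cfg.n_deg_per_contrast * cfg.n_clusters + len(regulators)
                 + cfg.n_immune_sets * cfg.immune_set_size
                 + cfg.n_pathway_sets * cfg.pathway_set_size)
    if n_special > cfg.n_genes:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for {n_special} planted genes "
            "(regulators + DEGs + gene-set members)")
    rngs = _spawn_rngs(cfg.seed)

    # --- sample frame -----------------------------------------------------
    n, K = cfg.n_samples, cfg.n_clusters
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    cluster = np.repeat(np.arange(1, K + 1), int(np.ceil(n / K)))[:n]
    width = len(str(cfg.n_genes))
    other = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes - len(regulators))]
    gene_ids = regulators + other

    # carve non-regulator genes into DEG / immune / pathway / background blocks
    cursor = 0
    deg_genes = other[cursor:cursor + cfg.n_deg_per_contrast * K]
    cursor += len(deg_genes)
    immune_members = {}
    for s in range(cfg.n_immune_sets):
        immune_members[f"IMMUNE_SET_{s + 1}"] = other[cursor:cursor + cfg.immune_set_size]
        cursor += cfg.immune_set_size
    pathway_members = {}
    for s in range(cfg.n_pathway_sets):
        pathway_members[f"PATHWAY_{s + 1}"] = other[cursor:cursor + cfg.pathway_set_size]
        cursor += cfg.pathway_set_size

    # --- latent score (drives hazard and TMB) -----------------------------
    rng_surv = rngs["survival"]
    raw = np.array([cfg.cluster_score_means[k - 1] for k in cluster]) \
        + rng_surv.normal(0.0, cfg.score_noise_sd, n)
    score = (raw - raw.mean()) / raw.std(ddof=0)

    # --- expression -------------------------------------------------------
    rng_expr = rngs["expression"]
    expr = rng_expr.normal(0.0, 1.0, (cfg.n_genes, n))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    # regulator shifts: per-cluster random +/- pattern
    directions = rng_expr.choice((-1.0, 1.0), size=(K, len(regulators)))
    for k in range(1, K + 1):
        cols = cluster == k
        for j, g in enumerate(regulators):
            expr[gene_pos[g], cols] += cfg.regulator_shift * directions[k - 1, j]
    # DEGs: driver cluster up by effect, the others down by effect/2, so every
    # one-vs-rest contrast separates each planted gene
    deg_membership: dict[str, list[str]] = {}
    for k in range(1, K + 1):
        block = deg_genes[(k - 1) * cfg.n_deg_per_contrast: k * cfg.n_deg_per_contrast]
        deg_membership[f"{k}_vs_rest"] = list(block)
        for g in block:
            row = gene_pos[g]
            expr[row, cluster == k] += cfg.deg_effect
            expr[row, cluster != k] -= cfg.deg_effect / 2.0
    # prognostic genes additionally load on the latent score
    prognostic = deg_genes[:: max(1, len(deg_genes) // max(cfg.n_prognostic, 1))][: cfg.n_prognostic]
    for g in prognostic:
        expr[gene_pos[g]] += cfg.prognostic_effect * score
    # immune-set activation per cluster
    if cfg.immune_set_activation is None:
        names = list(immune_members)
        activation = {k: [names[i] for i in range(len(names)) if i % K == (k - 1)]
                      for k in range(1, K + 1)}
    else:
        activation = {int(k): list(v) for k, v in cfg.immune_set_activation.items()}
    for k, set_names in activation.items():
        cols = cluster == k
        for sname in set_names:
            for g in immune_members.get(sname, ()):
                expr[gene_pos[g], cols] += cfg.immune_shift
    # shift to a log2-like positive scale
    expr = expr + 8.0
    X = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))

    # --- survival ---------------------------------------------------------
    log_h = (np.log(cfg.baseline_hazard)
             + np.array([cfg.cluster_log_hazard[k - 1] for k in cluster])
             + cfg.score_hazard_coef * score)
    hazard = np.exp(log_h)
    event_time = rng_surv.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        cens_rate = hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        cens_time = rng_surv.exponential(1.0 / cens_rate)
    else:
        cens_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)

    # --- clinical ---------------------------------------------------------
    rng_clin = rngs["clinical"]
    subtype = rng_clin.choice(("basal", "her2", "lumA", "lumB", "normal"),
                              size=n, p=(0.18, 0.12, 0.40, 0.22, 0.08))
    clin = pd.DataFrame({
        "os_time": np.round(os_time, 3),
        "os_event": os_event,
        "age": rng_clin.integers(28, 88, n),
        "t_stage": rng_clin.choice(("T1", "T2", "T3", "T4"), n, p=(0.3, 0.45, 0.15, 0.1)),
        "n_stage": rng_clin.choice(("N0", "N1", "N2", "N3"), n, p=(0.5, 0.3, 0.12, 0.08)),
        "tumor_stage": rng_clin.choice(("I", "II", "III", "IV"), n, p=(0.25, 0.45, 0.25, 0.05)),
        "subtype": subtype,
        "ips_pd1": np.round(5.0 + 0.4 * score + rng_clin.normal(0, 1, n), 4),
        "ips_ctla4": np.round(5.0 + 0.4 * score + rng_clin.normal(0, 1, n), 4),
        "ips_pd1_ctla4": np.round(5.0 + 0.4 * score + rng_clin.normal(0, 1, n), 4),
    }, index=pd.Index(sample_ids, name="sample_id"))
    clinical = ClinicalTable(clin)

    # --- gene sets --------------------------------------------------------
    sets: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    for name, members in immune_members.items():
        sets[name] = list(members)
        cats[name] = "immune-cell"
    for name, members in pathway_members.items():
        sets[name] = list(members)
        cats[name] = "pathway"
    gene_sets = GeneSetCollection(sets, cats)

    # --- mutations (MAF) --------------------------------------------------
    rng_mut = rngs["mutation"]
    # log-mean linear in -score; slope calibrated for the default burden so
    # the empirical Spearman lands near the configured target
    slope = 0.25 * abs(cfg.tmb_score_correlation)
    mu = cfg.tmb_mean * np.exp(np.sign(cfg.tmb_score_correlation) * slope * score)
    counts = rng_mut.poisson(mu)
    records = []
    mut_pool = other  # nonsynonymous passenger mutations land outside the regulators
    for i, sid in enumerate(sample_ids):
        gs = rng_mut.choice(len(mut_pool), size=counts[i], replace=True)
        classes = rng_mut.choice(len(_NONSYN_CLASSES), size=counts[i], p=_NONSYN_PROBS)
        for g, c in zip(gs, classes):
            records.append((mut_pool[g], sid, _NONSYN_CLASSES[c], "SNP",
                            int(rng_mut.integers(1, 23)), int(rng_mut.integers(1, 10**8))))
        # occasional regulator mutation (the rare-event headline of the cohort)
        if rng_mut.random() < cfg.regulator_mutation_rate:
            g = regulators[int(rng_mut.integers(len(regulators)))]
            records.append((g, sid, "Missense_Mutation", "SNP",
                            int(rng_mut.integers(1, 23)), int(rng_mut.integers(1, 10**8))))
        # a sprinkle of silent records that must never count toward TMB
        for _ in range(int(rng_mut.poisson(2.0))):
            g = mut_pool[int(rng_mut.integers(len(mut_pool)))]
            records.append((g, sid, "Silent", "SNP",
                            int(rng_mut.integers(1, 23)), int(rng_mut.integers(1, 10**8))))
    maf = MAFTable(pd.DataFrame(records, columns=[
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
        "Variant_Type", "Chromosome", "Start_Position"]))

    # --- CNV --------------------------------------------------------------
    rng_cnv = rngs["cnv"]
    calls = np.zeros((len(regulators), n), dtype=int)
    for j, g in enumerate(regulators):
        if g in cfg.amplified_regulators:
            hit = rng_cnv.random(n) < cfg.amplification_rate
            calls[j, hit] = rng_cnv.choice((1, 2), size=int(hit.sum()), p=(0.7, 0.3))
        elif g in cfg.deleted_regulators:
            hit = rng_cnv.random(n) < cfg.deletion_rate
            calls[j, hit] = -rng_cnv.choice((1, 2), size=int(hit.sum()), p=(0.7, 0.3))
        else:
            hit = rng_cnv.random(n) < cfg.cnv_background_rate
            calls[j, hit] = rng_cnv.choice((-1, 1), size=int(hit.sum()))
    cnv = CNVMatrix(pd.DataFrame(calls, index=regulators, columns=sample_ids))

    truth = GroundTruth(
        cluster=pd.Series(cluster, index=sample_ids, name="cluster"),
        deg_membership=deg_membership,
        prognostic_genes=list(prognostic),
        latent_score=pd.Series(score, index=sample_ids, name="latent_score"),
        expected_tmb=pd.Series(mu, index=sample_ids, name="expected_tmb"),
        immune_activation=activation,
    )
    return X, clinical, gene_sets, maf, cnv, truth


def truth_report(truth: GroundTruth, predicted_labels) -> dict:
    """Concordance of predicted cluster labels with the planted partition.

    Reports the adjusted Rand index (permutation-invariant in label names)
    and, per true cluster, the recall of its best-matching predicted label.
    """
    pred = pd.Series(list(predicted_labels), index=truth.cluster.index) \
        if not isinstance(predicted_labels, pd.Series) else predicted_labels
    if len(pred) != len(truth.cluster):
        raise ValueError("predicted labels do not match the sample universe")
    pred = pred.reindex(truth.cluster.index)
    if pred.isna().any():
        raise ValueError("predicted labels missing for some samples")
    ari = float(adjusted_rand_score(truth.cluster.to_numpy(), pred.to_numpy()))
    recall = {}
    for c in sorted(truth.cluster.unique()):
        members = truth.cluster.index[truth.cluster == c]
        counts = pred.loc[members].value_counts()
        recall[int(c)] = float(counts.iloc[0] / len(members)) if len(counts) else 0.0
    return {"ari": ari, "per_cluster_recall": recall}


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate a cohort and write the full file bundle plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X, clinical, sets, maf, cnv, truth = generate_cohort(config)
    params = dataclasses.asdict(config)
    files = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "maf": outdir / "mutations.maf",
        "cnv": outdir / "cnv.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(X, files["expression"], seed=config.seed, config=params)
    write_clinical(clinical, files["clinical"], seed=config.seed)
    write_gene_sets(sets, files["gene_sets"], seed=config.seed)
    write_maf(maf, files["maf"], seed=config.seed)
    write_cnv(cnv, files["cnv"], seed=config.seed)
    truth_json = {
        "cluster": truth.cluster.to_dict(),
        "deg_membership": truth.deg_membership,
        "prognostic_genes": truth.prognostic_genes,
        "latent_score": {k: float(v) for k, v in truth.latent_score.items()},
        "expected_tmb": {k: float(v) for k, v in truth.expected_tmb.items()},
        "immune_activation": {str(k): v for k, v in truth.immune_activation.items()},
    }
    files["truth"].write_text(json.dumps(truth_json, indent=1))
    return {k: str(v) for k, v in files.items()}
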