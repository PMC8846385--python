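"""End-to-end orchestration: simulate/load -> cluster -> enrich -> DEG ->
gene clusters -> signature/m6Ascore -> stratify -> genomic associations.

Every stage writes its tables under the output directory and the run ends
with a machine-readable ``run_summary.json`` carrying the headline numbers
(chosen k, cluster sizes, overlap-DEG count, signature size, cutpoint,
log-rank p, score-TMB rho) so reruns on real cohorts can be compared
against published results.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import cluster_labels, consensus_cluster
from .data_model import (
    cohort_manifest,
    default_regulator_catalog,
    load_clinical,
    load_cnv,
    load_expression,
    load_gene_sets,
    load_maf,
)
from .diffexp import moderated_t_fit, overlap_degs, select_degs
from .enrichment import gsva_like_scores, ssgsea_scores
from .genomics import cnv_frequency, compute_tmb, mutation_frequency
from .scoring import associate_score, build_signature, m6a_score, regulator_network, stratify
from .synthetic import SimulationConfig, generate_cohort, truth_report

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    outdir: str = "m6apattern_run"
    seed: int = 0
    # either a simulate block ...
    simulate: dict | None = None
    # ... or explicit input paths
    expression: str | None = None
    clinical: str | None = None
    gene_sets: str | None = None
    maf: str | None = None
    cnv: str | None = None
    # stage parameters
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    reps: int = 1000
    subsample_fraction: float = 0.8
    forced_k: int | None = None
    enrichment_method: str = "ssgsea"
    ssgsea_alpha: float = 0.25
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    cox_p_threshold: float = 0.05
    minprop: float = 0.1
    exome_size_mb: float = 38.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        if cfg.simulate is None and cfg.expression is None:
            raise ValueError("config needs either a 'simulate' block or an 'expression' path")
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out, time.perf_counter() - t0
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; any failure aborts naming the stage.

    Returns the run summary (also written to ``run_summary.json``); partial
    stage outputs are preserved on failure.
    """
    t_start = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "cohorts": cohort_manifest(),
        "stages": {},
    }

    def emit(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", **kw)
        files[name] = str(path)

    # ---- stage: inputs ---------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            return generate_cohort(sim)
        X = load_expression(config.expression)
        clinical = load_clinical(config.clinical) if config.clinical else None
        sets = load_gene_sets(config.gene_sets) if config.gene_sets else None
        maf = load_maf(config.maf) if config.maf else None
        cnv = load_cnv(config.cnv) if config.cnv else None
        return X, clinical, sets, maf, cnv, None

    (X, clinical, gene_sets, maf, cnv, truth), dt = load_inputs()
    summary["stages"]["inputs"] = {"seconds": dt, "n_samples": X.n_samples, "n_genes": X.n_genes}
    catalog = default_regulator_catalog()
    outcome = clinical.outcome(X.sample_ids) if clinical is not None else None

    # ---- stage: m6A clusters (consensus on regulators) --------------------
    @_stage("m6a_clusters")
    def cluster_regulators():
        res = consensus_cluster(X, features=catalog.symbols, k_range=config.k_range,
                                reps=config.reps, subsample_fraction=config.subsample_fraction,
                                seed=config.seed)
        k = config.forced_k or res.chosen_k
        return res, cluster_labels(res, k)

    (cons, m6a_labels), dt = cluster_regulators()
    emit("m6a_cluster_labels", m6a_labels.to_frame(), index_label="sample_id")
    diag = pd.DataFrame({"k": cons.k_range,
                         "pac": [cons.pac[k] for k in cons.k_range],
                         "cdf_area": [cons.cdf_area[k] for k in cons.k_range],
                         "delta_area": [cons.delta_area[k] for k in cons.k_range]})
    emit("m6a_cluster_diagnostics", diag, index=False)
    sizes = m6a_labels.value_counts().sort_index()
    summary["stages"]["m6a_clusters"] = {
        "seconds": dt, "chosen_k": cons.chosen_k,
        "used_k": int(m6a_labels.nunique()),
        "cluster_sizes": {int(k): int(v) for k, v in sizes.items()},
    }
    if truth is not None:
        summary["stages"]["m6a_clusters"]["truth"] = truth_report(truth, m6a_labels)

    # ---- stage: enrichment -------------------------------------------------
    if gene_sets is not None:
        @_stage("enrichment")
        def enrich():
            if config.enrichment_method == "ssgsea":
                E = ssgsea_scores(X, gene_sets, alpha=config.ssgsea_alpha)
            else:
                E = gsva_like_scores(X, gene_sets)
            per_cluster = E.scores.T.groupby(m6a_labels).mean().T
            tests = []
            for sname in E.set_names:
                stat, p = associate_score(E.scores.loc[sname], m6a_labels, kind="kruskal")
                tests.append((sname, stat, p))
            return E, per_cluster, pd.DataFrame(tests, columns=["set", "kruskal_h", "p"])

        (E, per_cluster, ktab), dt = enrich()
        emit("enrichment_scores", E.scores, index_label="set")
        emit("enrichment_by_cluster", per_cluster, index_label="set")
        emit("enrichment_cluster_tests", ktab, index=False)
        summary["stages"]["enrichment"] = {
            "seconds": dt, "method": E.method, "n_sets": len(E.set_names),
            "min_cluster_test_p": float(ktab["p"].min()),
        }

    # ---- stage: differential expression ------------------------------------
    @_stage("diffexp")
    def run_deg():
        deg = moderated_t_fit(X, m6a_labels, contrast="one_vs_rest")
        lists = {c: select_degs(deg, config.lfc_threshold, config.p_threshold, contrast=c)
                 for c in deg.contrasts}
        core, regions = overlap_degs(lists)
        return deg, lists, core, regions

    (deg, deg_lists, overlap, regions), dt = run_deg()
    emit("deg_table", deg.table, index=False)
    (outdir / "overlap_degs.txt").write_text("\n".join(overlap) + "\n")
    files["overlap_degs"] = str(outdir / "overlap_degs.txt")
    summary["stages"]["diffexp"] = {
        "seconds": dt,
        "per_contrast_deg_counts": {c: len(v) for c, v in deg_lists.items()},
        "n_overlap_degs": len(overlap),
        "venn_regions": regions,
    }
    if not overlap:
        raise PipelineError("stage 'diffexp' failed: no signature genes (empty DEG overlap)")

    # ---- stage: gene clusters (consensus on overlap DEGs) ------------------
    @_stage("gene_clusters")
    def cluster_genespace():
        res = consensus_cluster(X, features=overlap, k_range=config.k_range,
                                reps=config.reps, subsample_fraction=config.subsample_fraction,
                                seed=config.seed + 1)
        k = config.forced_k or res.chosen_k
        return res, cluster_labels(res, k)

    (gcons, gene_cluster), dt = cluster_genespace()
    emit("gene_cluster_labels", gene_cluster.to_frame(), index_label="sample_id")
    summary["stages"]["gene_clusters"] = {
        "seconds": dt, "chosen_k": gcons.chosen_k,
        "cluster_sizes": {int(k): int(v) for k, v in gene_cluster.value_counts().sort_index().items()},
    }

    # ---- stage: signature + m6Ascore ---------------------------------------
    score_table = None
    if outcome is not None:
        @_stage("signature")
        def signature():
            model = build_signature(X, overlap, outcome, cox_p_threshold=config.cox_p_threshold)
            scores = m6a_score(model, X)
            grouped, strat = stratify(scores, outcome, minprop=config.minprop)
            return model, scores, grouped, strat

        (model, scores, grouped, strat), dt = signature()
        score_table = grouped
        sig_json = {
            "genes": model.genes,
            "means": model.means.tolist(),
            "sds": model.sds.tolist(),
            "pc1": model.pc1.tolist(),
            "pc2": model.pc2.tolist(),
            "variance_explained": list(model.variance_explained),
            "degenerate_pc2": bool(model.degenerate_pc2),
        }
        (outdir / "signature_model.json").write_text(json.dumps(sig_json, indent=1))
        files["signature_model"] = str(outdir / "signature_model.json")
        out_scores = pd.DataFrame({"m6ascore": grouped.scores, "group": grouped.groups})
        emit("m6ascore", out_scores, index_label="sample_id")
        summary["stages"]["signature"] = {
            "seconds": dt,
            "n_signature_genes": len(model.genes),
            "variance_explained": list(model.variance_explained),
            "cutpoint": strat["cutpoint"],
            "logrank_p": strat["logrank_p"],
            "n_high": strat["n_high"], "n_low": strat["n_low"],
            "median_survival_high": strat["median_survival_high"],
            "median_survival_low": strat["median_survival_low"],
        }
        if truth is not None:
            rho, p = associate_score(grouped.scores, truth.latent_score, kind="spearman")
            summary["stages"]["signature"]["latent_score_spearman"] = {"rho": rho, "p": p}

        # ---- regulator network --------------------------------------------
        @_stage("regulator_network")
        def network():
            return regulator_network(X, outcome, catalog)

        (pairs, per_reg), dt = network()
        emit("regulator_correlations", pairs, index=False)
        emit("regulator_prognosis", per_reg, index_label="gene")
        summary["stages"]["regulator_network"] = {
            "seconds": dt,
            "n_favorable": int((per_reg["prognostic_class"] == "favorable").sum()),
            "n_risk": int((per_reg["prognostic_class"] == "risk").sum()),
        }

    # ---- stage: genomic associations ---------------------------------------
    if maf is not None:
        @_stage("genomics")
        def genomics_stage():
            tmb = compute_tmb(maf, X.sample_ids, exome_size_mb=config.exome_size_mb)
            res: dict = {}
            if score_table is not None:
                rho, p = associate_score(score_table.scores, tmb["tmb_count"], kind="spearman")
                res["tmb_spearman"] = {"rho": rho, "p": p}
                mfreq = mutation_frequency(maf, catalog.symbols, score_table.groups)
            else:
                mfreq = mutation_frequency(
                    maf, catalog.symbols,
                    pd.Series("all", index=X.sample_ids))
            cfreq = cnv_frequency(cnv, catalog.symbols) if cnv is not None else None
            return tmb, mfreq, cfreq, res

        (tmb, mfreq, cfreq, res), dt = genomics_stage()
        emit("tmb", tmb, index_label="sample_id")
        emit("regulator_mutation_frequency", mfreq, index_label="gene")
        if cfreq is not None:
            emit("regulator_cnv_frequency", cfreq, index_label="gene")
        summary["stages"]["genomics"] = {
            "seconds": dt,
            "median_tmb": float(tmb["tmb_count"].median()),
            "regulator_altered_samples": mfreq.attrs["any_gene_altered_samples"],
            "regulator_altered_fraction": mfreq.attrs["any_gene_altered_fraction"],
            **res,
        }

    # ---- IPS association ---------------------------------------------------
    if clinical is not None and score_table is not None:
        ips_cols = [c for c in clinical.table.columns if c.startswith("ips")]
        if ips_cols and score_table.groups is not None:
            ips_res = {}
            for col in ips_cols:
                stat, p = associate_score(
                    clinical.table.loc[list(score_table.scores.index), col],
                    score_table.groups, kind="wilcoxon")
                ips_res[col] = {"statistic": stat, "p": p}
            summary["stages"]["ips"] = ips_res

    summary["files"] = files
    summary["wall_seconds"] = time.perf_counter() - t_start
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
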