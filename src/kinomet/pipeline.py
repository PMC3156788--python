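"""End-to-end orchestration: simulate -> preprocess -> subtype -> discover
-> cutpoint -> validate -> report.

A :class:`RunConfig` collects every stage's parameters (QT cluster size and
correlation floors, DE thresholds, cutpoint group floor, resampling size and
iterations, signature coverage floor) plus the simulation design.  One
top-level seed is fanned out to per-stage child seeds so stages can be rerun
in isolation; identical configs reproduce identical artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import classification, discovery, io, simulate, subtyping, survstats

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    qt_min_size: int = 15
    qt_min_corr: float = 0.6
    de_alpha: float = 0.05
    de_fdr: float = 0.05
    min_group_fraction: float = 0.10
    resampling_k: int = 28
    resampling_B: int = 100_000
    # signature coverage floor as a fraction of the signature size
    # (25-of-28 expressed as a ratio, rounded up per series)
    coverage_floor_fraction: float = 25 / 28
    subtype_min_margin: float = 0.0
    screen_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            sim = dict(self.simulation)
            if "planted_clusters" in sim:
                sim["planted_clusters"] = [
                    simulate.PlantedCluster(*c) if not isinstance(
                        c, simulate.PlantedCluster) else c
                    for c in sim["planted_clusters"]]
            self.simulation = simulate.SimulationConfig(**sim)
        if self.qt_min_size < 2 or self.resampling_B < 1:
            raise ValueError("invalid QT/resampling parameters")
        # fan the top-level seed out to the stages
        self.simulation.seed = self.seed

    @property
    def resampling_seed(self) -> int:
        return (self.seed * 2654435761 + 7) % (2**31)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Objects produced by one run (artifacts are also written to disk)."""

    config: RunConfig
    de: discovery.DEResult
    clusters: list[discovery.GeneCluster]
    screening: pd.DataFrame
    classifier: classification.CutpointClassifier | None
    null: discovery.ResamplingNull | None
    validation: classification.ValidationResult | None
    training_metagene: discovery.Metagene | None
    out_dir: Path


def _log(lines: list[str], **kv) -> None:
    lines.append(" ".join(f"{k}={v}" for k, v in kv.items()))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full discovery/validation pipeline on synthetic cohorts.

    The first simulated series is the training set; the remaining series
    form the validation panel.  Artifacts (TSV tables, classifier JSON, run
    log) are written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    _log(log, stage="start", config_hash=config.digest(), seed=config.seed)

    # --- simulate -----------------------------------------------------------
    cohorts = simulate.simulate_multiseries(config.simulation)
    training, validation = cohorts[0], cohorts[1:]
    _log(log, stage="simulate", n_series=len(cohorts),
         n_samples=training.expression.n_samples,
         n_genes=training.expression.n_genes)

    # --- preprocess + subtype ----------------------------------------------
    train_centered = io.median_center_genes(training.expression)
    centroids = subtyping.make_centroids(training.expression,
                                         training.subtypes)
    assignment = subtyping.assign_subtypes(
        training.expression, centroids, min_margin=config.subtype_min_margin)
    basal_matrix, basal_clinical = subtyping.select_basal(
        assignment, train_centered, training.clinical)
    _log(log, stage="subtype",
         n_basal=basal_matrix.n_samples,
         n_unclassified=int((assignment.labels == "unclassified").sum()))

    # --- discovery ----------------------------------------------------------
    de = discovery.basal_upregulated_genes(
        train_centered, assignment.labels,
        alpha=config.de_alpha, fdr=config.de_fdr)
    _log(log, stage="de", n_selected=len(de.selected))
    candidate = io.ExpressionMatrix(
        basal_matrix.values.loc[de.selected], series_id=basal_matrix.series_id,
        is_centered=True) if de.selected else None
    clusters = discovery.qt_cluster(
        candidate, min_size=config.qt_min_size, min_corr=config.qt_min_corr
    ) if candidate is not None and len(de.selected) >= config.qt_min_size \
        else []
    _log(log, stage="qt", n_clusters=len(clusters),
         sizes=",".join(str(c.size) for c in clusters) or "-")

    metagenes = {
        f"metagene_{i + 1}": discovery.build_metagene(
            basal_matrix, c.genes, name=f"metagene_{i + 1}")
        for i, c in enumerate(clusters)
    }
    screening = discovery.screen_metagenes_cox(
        metagenes, basal_clinical, alpha=config.screen_alpha
    ) if metagenes else pd.DataFrame(
        columns=["hr", "ci_low", "ci_high", "p", "n", "flagged"])
    _log(log, stage="screen", n_flagged=int(screening["flagged"].sum())
         if len(screening) else 0)

    classifier = null = validation_result = best_mg = None
    if len(screening) and screening["flagged"].any():
        best_name = screening.loc[screening["flagged"], "p"].idxmin()
        best_mg = metagenes[best_name]
        best_cluster = clusters[list(metagenes).index(best_name)]

        # --- cutpoint -------------------------------------------------------
        classifier = classification.optimize_cutpoint(
            best_mg.score, basal_clinical,
            min_group_fraction=config.min_group_fraction)
        classifier.gene_set = list(best_cluster.genes)
        classifier.coverage_floor = math.ceil(
            config.coverage_floor_fraction * len(best_cluster.genes))
        _log(log, stage="cutpoint", threshold=f"{classifier.threshold:.6g}",
             chi2=f"{classifier.train_statistic:.4g}")

        # --- resampling null ------------------------------------------------
        sub_clin = basal_clinical.subset(basal_matrix.sample_ids)
        solver = survstats.UnivariateCox(sub_clin.times, sub_clin.events)
        observed_p = solver.fit(
            best_mg.score.loc[basal_matrix.sample_ids].to_numpy()).p
        null = discovery.resampling_null(
            basal_matrix, basal_clinical, k=config.resampling_k,
            B=config.resampling_B, observed_stat=observed_p,
            seed=config.resampling_seed)
        _log(log, stage="resampling", B=null.iterations,
             observed_p=f"{observed_p:.3g}",
             tail=f"{null.tail_probability:.4g}")

        # --- validation -----------------------------------------------------
        if validation:
            pairs = []
            for cohort in validation:
                va = subtyping.assign_subtypes(
                    cohort.expression, centroids,
                    min_margin=config.subtype_min_margin)
                v_matrix, v_clin = subtyping.select_basal(
                    va, io.median_center_genes(cohort.expression),
                    cohort.clinical)
                pairs.append((v_matrix, v_clin))
            validation_result = classification.apply_across_series(
                pairs, classifier)
            pooled = validation_result.pooled_labels
            chi2, p = survstats.logrank_test(
                pooled, validation_result.pooled_clinical)
            _log(log, stage="validate",
                 n_pooled=len(pooled),
                 n_high=int((pooled == "High").sum()),
                 n_low=int((pooled == "Low").sum()),
                 logrank_chi2=f"{chi2:.4g}", logrank_p=f"{p:.3g}")

    _write_artifacts(out, config, de, clusters, metagenes, screening,
                     classifier, null, validation_result, log)
    return PipelineResult(config, de, clusters, screening, classifier, null,
                          validation_result, best_mg, out)


def _write_artifacts(out, config, de, clusters, metagenes, screening,
                     classifier, null, validation_result, log) -> None:
    de.table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"cluster": i + 1, "gene": g, "size": c.size,
          "quality": round(c.quality, 6)}
         for i, c in enumerate(clusters) for g in c.genes]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if metagenes:
        pd.DataFrame({n: m.score for n, m in metagenes.items()}).to_csv(
            out / "metagene_scores.tsv", sep="\t", index_label="sample_id")
    screening.to_csv(out / "screening.tsv", sep="\t", index_label="metagene")
    if classifier is not None:
        classification.save_classifier(classifier, out / "classifier.json")
    if null is not None:
        (out / "resampling.json").write_text(json.dumps({
            "k": null.k, "B": null.iterations,
            "observed_stat": null.observed_stat,
            "tail_probability": null.tail_probability,
        }, indent=2) + "\n")
    if validation_result is not None:
        validation_result.pooled_labels.to_frame("label").to_csv(
            out / "validation_labels.tsv", sep="\t", index_label="sample_id")
        validation_result.per_series.to_csv(
            out / "per_series_summary.tsv", sep="\t", index_label="series_id")
    (out / "config.json").write_text(json.dumps(
        asdict(config), indent=2, sort_keys=True, default=str) + "\n")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
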