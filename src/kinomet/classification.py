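"""Survival-optimized dichotomization of a metagene and its transfer.

The classifier is a single threshold tau on the metagene score: samples
scoring above tau are "High", at or below are "Low".  Training scans every
admissible midpoint between consecutive distinct scores (both induced groups
must hold at least ``min_group_fraction`` of samples) and keeps the one
maximizing the log-rank chi-square between the two survival curves.  The
learned threshold is then applied unchanged to each validation series after
the same preprocessing (per-series gene median centering), the labeled
subgroups are pooled, and per-series 5-year DFS differences are summarized
with a t-based confidence interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import MetageneCoverageError, build_metagene
from .io import ClinicalTable, ExpressionMatrix, median_center_genes
from .survstats import km_estimate, logrank_test

__all__ = [
    "CutpointClassifier",
    "ValidationResult",
    "optimize_cutpoint",
    "classify",
    "apply_across_series",
    "save_classifier",
    "load_classifier",
]


@dataclass
class CutpointClassifier:
    """Learned threshold tau: score > tau -> "High", else "Low"."""

    threshold: float
    train_statistic: float           # log-rank chi-square at tau
    n_candidates: int
    min_group_fraction: float
    n_train: int
    gene_set: list[str] = field(default_factory=list)
    coverage_floor: int | None = None
    preprocessing: dict = field(default_factory=lambda: {"median_center_genes": True})


@dataclass
class ValidationResult:
    """Pooled High/Low labels across series plus per-series summaries."""

    pooled_labels: pd.Series
    pooled_clinical: ClinicalTable
    per_series: pd.DataFrame     # n, n_high, n_low, coverage, dfs5_high/low/diff
    mean_dfs5_diff: float | None
    ci_dfs5_diff: tuple[float, float] | None
    excluded_series: list[str] = field(default_factory=list)


def optimize_cutpoint(
    scores: pd.Series | Sequence[float],
    clinical: ClinicalTable,
    min_group_fraction: float = 0.10,
) -> CutpointClassifier:
    """Threshold maximizing the log-rank separation of the induced groups.

    Candidates are midpoints between consecutive distinct sorted scores whose
    two groups each contain at least ``min_group_fraction`` of the samples.
    Ties on the statistic go to the smaller "High" group.
    """
    scores = pd.Series(scores, dtype=float)
    if isinstance(scores.index, pd.RangeIndex):
        scores.index = clinical.sample_ids
    s = scores.to_numpy()
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if clinical.events.sum() < 2:
        raise ValueError("no events: need at least two events to optimize")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("constant scores: no admissible threshold")
    n = len(s)
    floor = min_group_fraction * n
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best_tau = None
    best_stat = -np.inf
    best_n_high = n + 1
    n_admissible = 0
    for tau in candidates:
        n_high = int((s > tau).sum())
        n_low = n - n_high
        if n_high < floor or n_low < floor:
            continue
        n_admissible += 1
        labels = np.where(s > tau, "High", "Low")
        stat, _ = logrank_test(pd.Series(labels, index=scores.index),
                               clinical.subset(list(scores.index)))
        tol = 1e-9 * max(1.0, abs(best_stat))
        if stat > best_stat + tol or (
            abs(stat - best_stat) <= tol and n_high < best_n_high
        ):
            best_tau, best_stat, best_n_high = float(tau), float(stat), n_high
    if best_tau is None:
        raise ValueError(
            f"no candidate threshold leaves both groups >= "
            f"{min_group_fraction:.0%} of {n} samples")
    return CutpointClassifier(
        threshold=best_tau, train_statistic=best_stat,
        n_candidates=n_admissible, min_group_fraction=min_group_fraction,
        n_train=n,
    )


def classify(scores: pd.Series | Sequence[float],
             classifier: CutpointClassifier) -> pd.Series:
    """Label samples High/Low by the threshold; missing scores -> unclassified."""
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(
        np.where(scores > classifier.threshold, "High", "Low"),
        index=scores.index, name="label")
    labels[scores.isna()] = "unclassified"
    return labels


def _five_year_dfs(clinical: ClinicalTable, ids: list[str]) -> float | None:
    if not ids:
        return None
    km = km_estimate(clinical.subset(ids))
    return km.five_year_dfs


def apply_across_series(
    series: Sequence[tuple[ExpressionMatrix, ClinicalTable]],
    classifier: CutpointClassifier,
) -> ValidationResult:
    """Classify each validation series with the trained threshold and pool.

    Each series is preprocessed with the classifier's profile (per-series
    gene median centering by default), scored on the classifier's gene set
    with the coverage floor enforced (failing series are excluded with a
    warning), labeled, and the subgroups pooled.  Per-series 5-year DFS
    differences (High minus Low) are averaged with a t-based 95% CI.
    """
    if not classifier.gene_set:
        raise ValueError("classifier carries no gene set")
    rows = {}
    label_parts, clin_parts, excluded = [], [], []
    for matrix, clinical in series:
        if classifier.preprocessing.get("median_center_genes", False) \
                and not matrix.is_centered:
            matrix = median_center_genes(matrix)
        try:
            mg = build_metagene(matrix, classifier.gene_set,
                                coverage_floor=classifier.coverage_floor)
        except MetageneCoverageError as exc:
            warnings.warn(f"series {matrix.series_id!r} excluded: {exc}",
                          stacklevel=2)
            excluded.append(matrix.series_id)
            continue
        labels = classify(mg.score, classifier)
        label_parts.append(labels)
        clin_parts.append(clinical.subset(list(labels.index)).data)
        high = [i for i in labels.index if labels[i] == "High"]
        low = [i for i in labels.index if labels[i] == "Low"]
        dfs_h = _five_year_dfs(clinical, high)
        dfs_l = _five_year_dfs(clinical, low)
        rows[matrix.series_id] = {
            "n": len(labels), "n_high": len(high), "n_low": len(low),
            "coverage": mg.coverage[0],
            "dfs5_high": np.nan if dfs_h is None else dfs_h,
            "dfs5_low": np.nan if dfs_l is None else dfs_l,
            "dfs5_diff": np.nan if dfs_h is None or dfs_l is None
            else dfs_h - dfs_l,
        }
    if not rows:
        raise ValueError("every series failed the coverage floor")
    per_series = pd.DataFrame.from_dict(rows, orient="index")
    pooled_labels = pd.concat(label_parts)
    pooled_clinical = ClinicalTable(pd.concat(clin_parts))

    diffs = per_series["dfs5_diff"].dropna().to_numpy()
    if len(diffs) >= 2:
        from scipy import stats as sps

        mean = float(diffs.mean())
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        tq = sps.t.ppf(0.975, len(diffs) - 1)
        ci = (mean - tq * sem, mean + tq * sem)
    elif len(diffs) == 1:
        mean, ci = float(diffs[0]), None
    else:
        mean, ci = None, None
    return ValidationResult(pooled_labels, pooled_clinical, per_series,
                            mean, ci, excluded)


def save_classifier(classifier: CutpointClassifier, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(classifier), indent=2,
                                     sort_keys=True) + "\n")


def load_classifier(path: str | Path) -> CutpointClassifier:
    return CutpointClassifier(**json.loads(Path(path).read_text()))
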