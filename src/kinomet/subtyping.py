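"""Nearest-centroid molecular subtype assignment (single-sample predictor).

Each sample is correlated (Pearson, over genes shared with the centroid set,
after per-gene median centering) with one centroid per molecular subtype and
labeled with the best-correlated subtype.  Samples whose best correlation is
negative, or whose margin over the runner-up falls below ``min_margin``, are
flagged unclassified.  Centroids are an input — typically published subtype
centroids, or per-subtype gene means on simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, median_center_genes

__all__ = [
    "SUBTYPE_LABELS",
    "SubtypeCentroidSet",
    "SubtypeAssignment",
    "read_centroids",
    "write_centroids",
    "make_centroids",
    "assign_subtypes",
    "select_basal",
]

SUBTYPE_LABELS = ("basal", "luminalA", "luminalB", "ERBB2", "normal-like")


@dataclass
class SubtypeCentroidSet:
    """Centroid expression vectors, genes x five subtype columns."""

    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in SUBTYPE_LABELS if s not in self.centroids.columns]
        if missing:
            raise ValueError(f"centroid set missing subtypes: {missing}")
        if self.centroids.shape[0] == 0:
            raise ValueError("centroid gene set is empty")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class SubtypeAssignment:
    """Per-sample centroid correlations, argmax label and margin."""

    correlations: pd.DataFrame    # samples x subtypes
    labels: pd.Series             # argmax subtype, "unclassified" where flagged
    margin: pd.Series             # best minus second-best correlation
    n_shared_genes: int

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def read_centroids(path: str | Path) -> SubtypeCentroidSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SubtypeCentroidSet(df)


def write_centroids(centroids: SubtypeCentroidSet, path: str | Path) -> None:
    centroids.centroids.to_csv(path, sep="\t", index_label="gene_id")


def make_centroids(matrix: ExpressionMatrix,
                   labels: pd.Series) -> SubtypeCentroidSet:
    """Per-subtype gene-mean centroids (the simulation-mode centroid builder)."""
    cols = {}
    for s in SUBTYPE_LABELS:
        members = labels.index[labels == s]
        if len(members) == 0:
            raise ValueError(f"no samples labeled {s!r}")
        cols[s] = matrix.values[list(members)].mean(axis=1)
    return SubtypeCentroidSet(pd.DataFrame(cols))


def assign_subtypes(
    matrix: ExpressionMatrix,
    centroids: SubtypeCentroidSet,
    min_margin: float = 0.0,
    min_shared_genes: int = 20,
) -> SubtypeAssignment:
    """Label every sample with its best-correlated subtype centroid."""
    shared = [g for g in matrix.gene_ids
              if g.upper() in {c.upper() for c in centroids.gene_ids}]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids "
            f"(need >= {min_shared_genes})")
    upper = {c.upper(): c for c in centroids.gene_ids}
    cgenes = [upper[g.upper()] for g in shared]

    centered = median_center_genes(matrix) if not matrix.is_centered else matrix
    X = centered.values.loc[shared].to_numpy(dtype=float)      # genes x samples
    C = centroids.centroids.loc[cgenes].to_numpy(dtype=float)  # genes x 5

    Xz = X - X.mean(axis=0)
    Cz = C - C.mean(axis=0)
    xn = np.linalg.norm(Xz, axis=0)
    cn = np.linalg.norm(Cz, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xz.T @ Cz) / np.outer(xn, cn)                  # samples x 5
    corr = np.nan_to_num(corr, nan=-1.0)

    cols = list(centroids.centroids.columns)
    cdf = pd.DataFrame(corr, index=matrix.sample_ids, columns=cols)
    ordered = np.sort(corr, axis=1)
    best = ordered[:, -1]
    margin = best - ordered[:, -2]
    labels = pd.Series(
        [cols[i] for i in np.argmax(corr, axis=1)],
        index=matrix.sample_ids, name="subtype")
    flagged = (best < 0) | (margin < min_margin)
    labels[flagged] = "unclassified"
    return SubtypeAssignment(cdf, labels,
                             pd.Series(margin, index=matrix.sample_ids),
                             len(shared))


def select_basal(
    assignment: SubtypeAssignment | pd.Series,
    matrix: ExpressionMatrix,
    clinical: ClinicalTable | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable | None]:
    """Restrict a cohort to its basal-labeled samples."""
    labels = assignment.labels if isinstance(assignment, SubtypeAssignment) \
        else assignment
    missing = [s for s in matrix.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"assignment missing samples: {missing[:5]}")
    basal = [s for s in matrix.sample_ids if labels[s] == "basal"]
    if not basal:
        raise ValueError("no basal samples in cohort")
    sub_clin = clinical.subset(basal) if clinical is not None else None
    return matrix.subset_samples(basal), sub_clin
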