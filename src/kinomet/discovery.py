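"""Supervised gene selection, QT clustering, metagenes and resampling nulls.

The discovery chain mirrors a metagene-based signature search on a basal
cohort: per-gene Welch t-tests of basal versus each other molecular subtype
(Benjamini-Hochberg FDR within each comparison, direction-aware selection),
quality-threshold clustering of the selected genes into coherent blocks,
per-cluster metagene scores (mean of member-gene expression), univariate Cox
screening of each metagene against disease-free survival, and an empirical
null built from random gene sets of matched size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix
from .survstats import UnivariateCox, cox_fit

__all__ = [
    "DEResult",
    "GeneCluster",
    "Metagene",
    "MetageneCoverageError",
    "ResamplingNull",
    "ClusteringLayout",
    "basal_upregulated_genes",
    "hierarchical_cluster",
    "qt_cluster",
    "build_metagene",
    "screen_metagenes_cox",
    "resampling_null",
]


# ---------------------------------------------------------------------------
# supervised selection


@dataclass
class DEResult:
    """Per-gene, per-comparison differential-expression statistics.

    ``table`` is tidy with columns gene / comparison / t / p / q / up /
    selected_in_comparison; ``selected`` is the union of genes passing the
    direction, alpha and FDR filters in at least one comparison, in matrix
    gene order.
    """

    table: pd.DataFrame
    selected: list[str]
    alpha: float
    fdr: float
    direction: str
    comparisons: list[str]
    skipped: list[str] = field(default_factory=list)


def basal_upregulated_genes(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    fdr: float = 0.05,
    target_label: str = "basal",
    direction: str = "up",
) -> DEResult:
    """Genes up (or down) in basal versus at least one other subtype.

    One Welch t-test per gene per pairwise comparison; Benjamini-Hochberg
    applied within each comparison.  A gene is selected if, in >= 1
    comparison, its effect has the requested direction, raw p < ``alpha``
    and adjusted p < ``fdr``.
    """
    from statsmodels.stats.multitest import multipletests

    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    labels = labels.reindex(matrix.sample_ids)
    target = labels.index[labels == target_label]
    if len(target) < 2:
        raise ValueError(f"need >= 2 {target_label!r} samples")
    others = [g for g in labels.dropna().unique()
              if g not in (target_label, "unclassified")]
    Xt = matrix.values[list(target)].to_numpy(dtype=float)

    rows, comparisons, skipped = [], [], []
    hit = pd.Series(False, index=matrix.gene_ids)
    for other in others:
        members = labels.index[labels == other]
        if len(members) < 2:
            skipped.append(other)
            warnings.warn(f"comparison vs {other!r} skipped: "
                          f"{len(members)} sample(s)", stacklevel=2)
            continue
        comparisons.append(other)
        Xo = matrix.values[list(members)].to_numpy(dtype=float)
        t, p = stats.ttest_ind(Xt, Xo, axis=1, equal_var=False)
        t = np.nan_to_num(t, nan=0.0)
        p = np.nan_to_num(p, nan=1.0)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        up = t > 0 if direction == "up" else t < 0
        sel = up & (p < alpha) & (q < fdr)
        hit |= pd.Series(sel, index=matrix.gene_ids)
        rows.append(pd.DataFrame({
            "gene": matrix.gene_ids, "comparison": other,
            "t": t, "p": p, "q": q, "up": t > 0,
            "selected_in_comparison": sel,
        }))
    if not comparisons:
        raise ValueError("no comparison subtype has >= 2 samples")
    table = pd.concat(rows, ignore_index=True)
    selected = [g for g in matrix.gene_ids if hit[g]]
    return DEResult(table, selected, alpha, fdr, direction,
                    comparisons, skipped)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusteringLayout:
    """Hierarchical gene/sample dendrograms for heatmap-style layouts."""

    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_order: list[str]
    sample_order: list[str]
    dropped_genes: list[str] = field(default_factory=list)


def hierarchical_cluster(matrix: ExpressionMatrix) -> ClusteringLayout:
    """Centroid-linkage clustering of genes and samples under 1 - Pearson."""
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    values = matrix.values
    const = values.std(axis=1) == 0
    dropped = list(values.index[const])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant gene(s) with "
                      "undefined correlation", stacklevel=2)
        values = values.loc[~const]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")

    def _link(X: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X)
        D = 1.0 - np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2, 0.0, None)
        return linkage(squareform(D, checks=False), method="centroid")

    gl = _link(values.to_numpy(dtype=float))
    sl = _link(values.to_numpy(dtype=float).T)
    genes = list(values.index)
    samples = list(values.columns)
    return ClusteringLayout(
        gene_linkage=gl, sample_linkage=sl,
        gene_order=[genes[i] for i in leaves_list(gl)],
        sample_order=[samples[i] for i in leaves_list(sl)],
        dropped_genes=dropped,
    )


@dataclass
class GeneCluster:
    """A coherent gene set: quality = minimum pairwise Pearson correlation."""

    genes: list[str]
    quality: float

    @property
    def size(self) -> int:
        return len(self.genes)


def _grow_candidate(C: np.ndarray, seed: int, available: np.ndarray,
                    min_corr: float, mode: str) -> list[int]:
    """Greedy quality-threshold growth from one seed gene.

    At each step the gene whose inclusion keeps the cluster quality highest
    is added, while quality stays >= min_corr.  ``mode='diameter'`` defines
    quality as the minimum pairwise correlation among members;
    ``mode='seed'`` as the minimum correlation to the seed.
    """
    members = [seed]
    active = available.copy()
    active[seed] = False
    if mode == "seed":
        ref = C[seed].copy()
        while True:
            ref_masked = np.where(active, ref, -np.inf)
            best = int(np.argmax(ref_masked))
            if ref_masked[best] < min_corr:
                break
            members.append(best)
            active[best] = False
        return members
    # diameter mode: track min correlation to current members
    mincorr = C[seed].copy()
    while True:
        cand = np.where(active, mincorr, -np.inf)
        best = int(np.argmax(cand))
        if cand[best] < min_corr:
            break
        members.append(best)
        active[best] = False
        mincorr = np.minimum(mincorr, C[best])
    return members


def qt_cluster(
    matrix: ExpressionMatrix,
    min_size: int = 15,
    min_corr: float = 0.6,
    mode: str = "diameter",
) -> list[GeneCluster]:
    """Quality-threshold clustering of genes.

    Every remaining gene seeds a greedily grown candidate cluster; the
    largest candidate (ties: higher quality, then lower seed index) is
    emitted if it reaches ``min_size``, its genes are removed, and the search
    repeats.  Genes never reaching ``min_size`` stay unclustered.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if mode not in ("diameter", "seed"):
        raise ValueError("mode must be 'diameter' or 'seed'")
    genes = matrix.gene_ids
    if len(genes) < min_size:
        return []
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=-1.0)
    C[sd == 0, :] = -1.0
    C[:, sd == 0] = -1.0
    np.fill_diagonal(C, 1.0)

    available = np.ones(len(genes), dtype=bool)
    clusters: list[GeneCluster] = []
    while available.sum() >= min_size:
        best_members: list[int] | None = None
        best_quality = -np.inf
        for seed in np.flatnonzero(available):
            members = _grow_candidate(C, int(seed), available, min_corr, mode)
            if best_members is None or len(members) > len(best_members):
                best_members = members
                best_quality = _min_pairwise(C, members)
            elif len(members) == len(best_members):
                q = _min_pairwise(C, members)
                if q > best_quality + 1e-12:
                    best_members, best_quality = members, q
        assert best_members is not None
        if len(best_members) < min_size:
            break
        clusters.append(GeneCluster(
            genes=[genes[i] for i in sorted(best_members)],
            quality=float(best_quality)))
        available[best_members] = False
    return clusters


def _min_pairwise(C: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 1.0
    sub = C[np.ix_(members, members)]
    return float(sub[np.triu_indices(len(members), 1)].min())


# ---------------------------------------------------------------------------
# metagenes


class MetageneCoverageError(ValueError):
    """Raised when too few signature genes are present in a matrix."""

    def __init__(self, missing: list[str], present: int, total: int,
                 floor: int):
        self.missing = missing
        super().__init__(
            f"insufficient signature coverage: {present}/{total} genes "
            f"present (floor {floor}); missing: {', '.join(missing)}")


@dataclass
class Metagene:
    """Mean expression of a gene set per sample, with coverage bookkeeping."""

    name: str
    genes: list[str]               # requested signature
    present_genes: list[str]       # members found in the matrix
    score: pd.Series               # per-sample mean over present members

    @property
    def coverage(self) -> tuple[int, int]:
        return len(self.present_genes), len(self.genes)


def build_metagene(
    matrix: ExpressionMatrix,
    gene_set: list[str],
    coverage_floor: int | None = None,
    name: str = "metagene",
) -> Metagene:
    """Per-sample mean of the member genes present in the matrix."""
    if not gene_set:
        raise ValueError("gene set is empty")
    lookup = {g.upper(): g for g in matrix.gene_ids}
    present = [g for g in gene_set if g.upper() in lookup]
    missing = [g for g in gene_set if g.upper() not in lookup]
    floor = coverage_floor if coverage_floor is not None else 1
    if len(present) < floor:
        raise MetageneCoverageError(missing, len(present), len(gene_set),
                                    floor)
    rows = [lookup[g.upper()] for g in present]
    score = matrix.values.loc[rows].mean(axis=0)
    score.name = name
    return Metagene(name, list(gene_set), present, score)


def screen_metagenes_cox(
    metagenes: dict[str, Metagene],
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox of each continuous metagene score against DFS.

    Returns one row per metagene (hr per 1-unit score, 95% CI, Wald p, n,
    flagged = p < alpha).
    """
    if clinical.events.sum() < 2:
        raise ValueError("need at least two events to screen metagenes")
    rows = {}
    for name, mg in metagenes.items():
        cov = pd.DataFrame({name: mg.score}).reindex(clinical.sample_ids)
        fit = cox_fit(cov, clinical, multivariate=False)
        rows[name] = fit.table.loc[name]
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["flagged"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# resampling null


@dataclass
class ResamplingNull:
    """Empirical null of Cox Wald p-values for random size-k gene sets."""

    k: int
    pool: list[str]
    iterations: int
    null_pvalues: np.ndarray
    observed_stat: float
    seed: int

    @property
    def tail_probability(self) -> float:
        """P(random metagene at least as prognostic), add-one corrected."""
        hits = int((self.null_pvalues <= self.observed_stat).sum())
        return (hits + 1) / (self.iterations + 1)


def resampling_null(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    k: int,
    B: int,
    observed_stat: float,
    pool: list[str] | None = None,
    seed: int = 0,
) -> ResamplingNull:
    """How often does a random k-gene metagene beat the observed Wald p?

    Draws ``B`` k-subsets without replacement from ``pool`` (default: every
    gene in the matrix), scores each as a metagene and fits a univariate Cox
    model; the tail probability is ``(#{p_i <= observed} + 1) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pool = list(pool) if pool is not None else matrix.gene_ids
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} genes smaller than k={k}")
    sub = clinical.subset(matrix.sample_ids)
    X = matrix.values.loc[pool].to_numpy(dtype=float)
    solver = UnivariateCox(sub.times, sub.events)
    rng = np.random.default_rng(seed)
    pvals = np.empty(B)
    for b in range(B):
        idx = rng.choice(len(pool), size=k, replace=False)
        pvals[b] = solver.fit(X[idx].mean(axis=0)).p
    return ResamplingNull(k, pool, B, pvals, float(observed_stat), seed)
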