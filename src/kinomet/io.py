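"""Reading, writing and preprocessing of expression and clinical tables.

Expression matrices are genes x samples on the log2 scale, held in a pandas
DataFrame wrapped by :class:`ExpressionMatrix`.  Clinical annotation travels
with the matrix as a :class:`ClinicalTable` keyed by sample id, carrying a
censored disease-free-survival outcome plus tri-state (1/0/missing) binary
covariates.

Preprocessing mirrors the conventional microarray post-processing contract:
quantile normalization across samples, per-gene median centering, restriction
to a curated gene list (e.g. a kinome list) and reconciliation of signature
genes across heterogeneous series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneList",
    "ClinicalTable",
    "CoverageReport",
    "ExpressionParseError",
    "read_expression",
    "write_expression",
    "read_genelist",
    "read_clinical",
    "write_clinical",
    "quantile_normalize",
    "median_center_genes",
    "restrict_to_genelist",
    "harmonize_series",
    "CLINICAL_COVARIATES",
]

#: binary covariates carried by the clinical TSV schema (0/1, empty = missing)
CLINICAL_COVARIATES = (
    "age_gt50",
    "pT_gt20mm",
    "pN_pos",
    "grade_high",
    "er_pos",
    "pr_pos",
    "erbb2_pos",
    "vascular_invasion",
    "lymphocyte_infiltrate",
    "chemo",
    "hormone_tx",
    "pcr",
)


class ExpressionParseError(ValueError):
    """Raised when an expression file is malformed."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes in rows and samples in columns."""

    values: pd.DataFrame
    series_id: str = "series"
    is_centered: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ExpressionParseError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ExpressionParseError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ExpressionParseError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])


@dataclass
class GeneList:
    """A named, ordered list of unique gene symbols."""

    name: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene list {self.name!r} is empty")
        seen: set[str] = set()
        for g in self.gene_ids:
            key = g.upper()
            if key in seen:
                raise ValueError(f"duplicate symbol {g!r} in gene list {self.name!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome and binary covariates.

    ``data`` is indexed by sample id with at least ``dfs_months`` (follow-up in
    months) and ``event`` (1 = relapse/death, 0 = censored); covariate columns
    hold 1/0/NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("dfs_months", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        t = self.data["dfs_months"]
        if (t.dropna() < 0).any():
            raise ValueError("negative dfs_months")
        ev = self.data["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    @property
    def times(self) -> np.ndarray:
        return self.data["dfs_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=float)


@dataclass
class CoverageReport:
    """Which genes of a target list were found in a matrix."""

    requested: int
    present: list[str]
    absent: list[str]

    @property
    def n_present(self) -> int:
        return len(self.present)

    @property
    def fraction(self) -> float:
        return self.n_present / self.requested if self.requested else 0.0


# ---------------------------------------------------------------------------
# parsing


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the row with the largest IQR."""
    if not df.index.duplicated().any():
        return df
    iqr = df.quantile(0.75, axis=1) - df.quantile(0.25, axis=1)
    order = np.argsort(-iqr.to_numpy(), kind="stable")
    picked = df.iloc[order]
    picked = picked[~picked.index.duplicated(keep="first")]
    # restore first-appearance gene order
    return picked.loc[[g for g in df.index.unique()]]


def _validate_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    try:
        out = df.astype(float)
    except (TypeError, ValueError):
        for gene, row in df.iterrows():
            for sample, v in row.items():
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ExpressionParseError(
                        f"{path}: non-numeric value {v!r} at gene {gene!r}, "
                        f"sample {sample!r}"
                    ) from None
        raise
    return out


def read_expression(path: str | Path, format: str = "tsv",
                    series_id: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT 1.2.

    Duplicate sample columns raise; duplicate gene rows are collapsed to the
    row with the largest inter-quartile range.
    """
    path = Path(path)
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown format {format!r}")
    if format == "tsv":
        header = path.read_text().split("\n", 1)[0].split("\t")[1:]
        if len(header) != len(set(header)):
            dups = sorted({c for c in header if header.count(c) > 1})
            raise ExpressionParseError(
                f"{path}: duplicate sample ids {dups[:5]}")
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        with open(path) as fh:
            version = fh.readline().strip()
            if version not in ("#1.2", "#1.3"):
                raise ExpressionParseError(f"{path}: not a GCT file ({version!r})")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ExpressionParseError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", index_col=0)
        body = body.drop(columns=[c for c in ("Description",) if c in body.columns])
        if body.shape != (n_genes, n_samples):
            raise ExpressionParseError(
                f"{path}: GCT header declares {n_genes}x{n_samples} "
                f"but body is {body.shape[0]}x{body.shape[1]}"
            )
        df = body
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ExpressionParseError(f"{path}: duplicate sample ids {dups[:5]}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ExpressionParseError(f"{path}: missing/ragged value at gene {gene!r}")
    df = _validate_numeric(df, str(path))
    df.index = df.index.astype(str)
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, series_id=series_id or path.stem)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     format: str = "tsv") -> None:
    """Write a matrix as TSV (default) or GCT 1.2."""
    path = Path(path)
    if format == "tsv":
        matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = matrix.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_genelist(path: str | Path, name: str | None = None) -> GeneList:
    """Read a gene list, one symbol per line; '#' starts a comment."""
    path = Path(path)
    genes: list[str] = []
    for line in path.read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            genes.append(sym)
    return GeneList(name or path.stem, genes)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    out = clinical.data.copy()
    for col in out.columns:
        if col in CLINICAL_COVARIATES or col == "event":
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to a common distribution.

    After normalization every sample's sorted values equal the per-rank mean
    of the sorted columns; tied input values receive the mean of the reference
    values spanned by their rank range.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one sample")
    if not np.isfinite(X).all():
        raise ValueError("missing values: impute or drop before normalizing")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    from scipy.stats import rankdata

    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    values = pd.DataFrame(out, index=matrix.values.index,
                          columns=matrix.values.columns)
    return replace(matrix, values=values)


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (even n: mean of middle two)."""
    med = matrix.values.median(axis=1)
    values = matrix.values.sub(med, axis=0)
    return replace(matrix, values=values, is_centered=True)


# ---------------------------------------------------------------------------
# gene-list reconciliation


def _match_index(gene_ids: Iterable[str]) -> dict[str, str]:
    """Case-insensitive symbol -> actual row id (first occurrence wins)."""
    out: dict[str, str] = {}
    for g in gene_ids:
        out.setdefault(str(g).upper(), str(g))
    return out


def restrict_to_genelist(
    matrix: ExpressionMatrix, genelist: GeneList
) -> tuple[ExpressionMatrix, CoverageReport]:
    """Keep only genes of ``genelist`` (its order), case-insensitive match."""
    lookup = _match_index(matrix.gene_ids)
    present, absent, rows = [], [], []
    for g in genelist.gene_ids:
        hit = lookup.get(g.upper())
        if hit is None:
            absent.append(g)
        else:
            present.append(g)
            rows.append(hit)
    if not present:
        raise ValueError(
            f"no overlap between matrix and gene list {genelist.name!r}")
    report = CoverageReport(len(genelist), present, absent)
    return replace(matrix, values=matrix.values.loc[rows]), report


def harmonize_series(
    matrices: Sequence[ExpressionMatrix],
    signature: GeneList | Sequence[str],
    floor: int = 0,
) -> pd.DataFrame:
    """Count signature genes present per series; flag series below ``floor``.

    Returns a DataFrame indexed by series id with columns ``n_present``,
    ``n_total``, ``flagged``; the mean count is stored in ``.attrs['mean']``.
    """
    if not matrices:
        raise ValueError("need at least one series")
    genes = signature.gene_ids if isinstance(signature, GeneList) else list(signature)
    rows = {}
    for m in matrices:
        lookup = _match_index(m.gene_ids)
        n = sum(1 for g in genes if g.upper() in lookup)
        rows[m.series_id] = {"n_present": n, "n_total": len(genes),
                             "flagged": n < floor}
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.attrs["mean"] = float(report["n_present"].mean())
    for sid, row in report.iterrows():
        if row["flagged"]:
            warnings.warn(
                f"series {sid!r} covers only {row['n_present']}/{len(genes)} "
                f"signature genes (floor {floor})", stacklevel=2)
    return report
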