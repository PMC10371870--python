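"""Shared domain types, file I/O, QC filtering and normalization.

Count matrices are oriented observations x genes: rows are cells, nuclei or
Visium spots, columns are gene symbols. Genomic intervals follow the BED
convention (0-based, half-open).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

ROW_KINDS = ("cell", "nucleus", "spot")

#: Default mitochondrial/ribosomal gene-symbol prefixes (human nomenclature).
MITO_RIBO_PREFIXES = ("MT-", "RPS", "RPL")

#: Default mito+ribo read-fraction ceiling per row kind.
DEFAULT_MAX_FRAC = {"cell": 0.20, "nucleus": 0.05}


class FormatError(ValueError):
    """A file does not match its declared on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)
        raise ValidationError(
            f"duplicate {what}: {sorted(dup[dup.duplicated()].unique())[:5]}"
        )


@dataclass
class CountMatrix:
    """Sparse nonnegative integer counts over (cell|nucleus|spot) x gene."""

    values: sp.csr_matrix
    row_ids: list[str]
    col_ids: list[str]
    row_kind: str = "cell"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if self.row_kind not in ROW_KINDS:
            raise ValidationError(f"row_kind must be one of {ROW_KINDS}")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        _check_unique(self.row_ids, "row_ids")
        _check_unique(self.col_ids, "col_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per row."""
        return np.asarray((self.values > 0).sum(axis=1)).ravel()

    def subset_rows(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[keep],
            [self.row_ids[i] for i in keep],
            self.col_ids,
            self.row_kind,
        )


@dataclass
class NormMatrix:
    """Log-normalized expression with the same labels as its source counts."""

    values: sp.csr_matrix
    row_ids: list[str]
    col_ids: list[str]
    row_kind: str = "cell"
    norm_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("shape does not match label lengths")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self, gene: str) -> int:
        try:
            return self.col_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def column(self, gene: str) -> np.ndarray:
        return np.asarray(self.values[:, self.gene_index(gene)].todense()).ravel()


@dataclass
class Annotation:
    """Per-row categorical labels (cell state, structure, donor, ...)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        _check_unique(list(self.labels.index), "annotation row_ids")

    @property
    def row_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def categories(self) -> list[str]:
        return sorted(self.labels.unique())

    def for_rows(self, row_ids) -> np.ndarray:
        """Label vector aligned to ``row_ids``; missing ids are an error."""
        missing = [r for r in row_ids if r not in self.labels.index]
        if missing:
            raise ValidationError(f"rows without annotation: {missing[:5]}")
        return self.labels.loc[list(row_ids)].to_numpy()

    def mask(self, row_ids, category) -> np.ndarray:
        return self.for_rows(row_ids) == category


@dataclass
class IntervalSet:
    """0-based half-open genomic intervals with optional names."""

    records: pd.DataFrame  # columns chrom, start, end, name

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).reset_index(drop=True)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"IntervalSet requires a {col!r} column")
        if "name" not in df.columns:
            df["name"] = [f"iv{i}" for i in range(len(df))]
        if df[["start", "end"]].isna().any().any():
            raise ValidationError("NaN interval coordinates")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValidationError("negative interval start")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].head()
            raise ValidationError(f"intervals with start >= end:\n{bad}")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def widths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def subset(self, names) -> "IntervalSet":
        names = set(names)
        return IntervalSet(self.records[self.records["name"].isin(names)])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_single_column(path) -> list[str]:
    ser = pd.read_csv(path, sep="\t", header=None, dtype=str)[0]
    return ser.tolist()


def disambiguate(symbols: list[str]) -> list[str]:
    """Suffix repeated symbols with .1, .2, ... (first occurrence untouched)."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        k = seen.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        seen[s] = k + 1
    return out


def read_count_matrix(matrix_path, genes_path, barcodes_path,
                      row_kind: str = "cell") -> CountMatrix:
    """Read a MatrixMarket matrix (rows = barcodes, cols = genes) plus labels.

    Duplicate gene symbols are disambiguated with numeric suffixes.
    """
    try:
        mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    genes = _read_single_column(genes_path)
    barcodes = _read_single_column(barcodes_path)
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix is {mat.shape} but barcodes/genes files have "
            f"{len(barcodes)}/{len(genes)} lines"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("negative entries in count matrix")
    return CountMatrix(mat, barcodes, disambiguate(genes), row_kind)


def write_count_matrix(cm: CountMatrix, matrix_path, genes_path,
                       barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.values))
    pd.Series(cm.col_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(cm.row_ids).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_bed(path) -> IntervalSet:
    """Read a 3+ column BED file into 0-based half-open intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "name"})
        df = df[["chrom", "start", "end", "name"]]
    else:
        df = df[["chrom", "start", "end"]]
    return IntervalSet(df)


def write_bed(iv: IntervalSet, path) -> None:
    iv.records[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_tsv(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_annotation(path, id_col=0, label_col=1) -> Annotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    ids = df.iloc[:, id_col] if isinstance(id_col, int) else df[id_col]
    lab = df.iloc[:, label_col] if isinstance(label_col, int) else df[label_col]
    return Annotation(pd.Series(lab.to_numpy(), index=ids.to_numpy()))


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def mito_ribo_mask(col_ids: list[str], gene_list=None) -> np.ndarray:
    """Boolean mask of mitochondrial/ribosomal genes.

    With an explicit ``gene_list``, symbols absent from the matrix are
    ignored with a log message; otherwise symbols matching the standard
    MT-/RPS/RPL prefixes are used.
    """
    if gene_list is not None:
        wanted = set(gene_list)
        unknown = wanted - set(col_ids)
        if unknown:
            logger.info("ignoring %d mito/ribo genes absent from matrix",
                        len(unknown))
        return np.array([g in wanted for g in col_ids])
    return np.array([g.upper().startswith(MITO_RIBO_PREFIXES) for g in col_ids])


def qc_filter_cells(counts: CountMatrix, mito_ribo_genes=None,
                    min_genes: int = 200, max_frac: float | None = None,
                    doublet_scores=None, doublet_cutoff: float = 0.3,
                    ) -> CountMatrix:
    """Keep cells/nuclei with > ``min_genes`` detected genes and a
    mito+ribo read fraction strictly below ``max_frac``.

    ``max_frac`` defaults to 0.20 for cells and 0.05 for nuclei. Optional
    externally computed ``doublet_scores`` (aligned to rows) are thresholded
    at ``doublet_cutoff`` (rows with score >= cutoff are removed).
    """
    if counts.row_kind not in ("cell", "nucleus"):
        raise ValidationError("qc_filter_cells expects cell or nucleus rows")
    if max_frac is None:
        max_frac = DEFAULT_MAX_FRAC[counts.row_kind]
    mask = mito_ribo_mask(counts.col_ids, mito_ribo_genes)
    totals = counts.row_sums()
    mito = np.asarray(counts.values[:, np.flatnonzero(mask)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (counts.genes_detected() > min_genes) & (frac < max_frac)
    if doublet_scores is not None:
        keep &= np.asarray(doublet_scores) < doublet_cutoff
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    return counts.subset_rows(keep)


def qc_filter_spots(counts: CountMatrix, min_umi: int = 500,
                    min_genes: int = 300) -> CountMatrix:
    """Keep spots with total UMI > ``min_umi`` and >= ``min_genes`` genes."""
    if counts.row_kind != "spot":
        raise ValidationError("qc_filter_spots expects spot rows")
    keep = (counts.row_sums() > min_umi) & (counts.genes_detected() >= min_genes)
    return counts.subset_rows(keep)


def normalize_log(counts: CountMatrix, target_sum: float | None = None
                  ) -> NormMatrix:
    """Scale each row to ``target_sum`` total counts, then apply log1p.

    ``target_sum`` defaults to the median of the nonzero row sums. All-zero
    rows stay all-zero.
    """
    totals = counts.row_sums().astype(float)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValidationError("cannot normalize an all-zero matrix")
    if target_sum is None:
        target_sum = float(np.median(totals[nonzero]))
    scale = np.zeros_like(totals)
    scale[nonzero] = target_sum / totals[nonzero]
    mat = sp.csr_matrix(counts.values, dtype=np.float64)
    mat = sp.diags(scale) @ mat
    mat.data = np.log1p(mat.data)
    return NormMatrix(mat, counts.row_ids, counts.col_ids, counts.row_kind,
                      {"target_sum": target_sum, "pseudocount": 1.0})
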