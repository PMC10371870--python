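"""GWAS SNP enrichment in cell-state open chromatin.

Per-barcode peak counts are binarized (>0), aggregated to cell states, and
a peak is called open for a state when at least 5% of its barcodes show
signal. For each trait, the fraction of its SNPs falling inside a state's
open peaks (the SNP proportion) is compared against a null built by
shuffling the open/closed labels of that state's peaks, preserving the
number of open peaks in every draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .io_core import Annotation, IntervalSet, ValidationError, read_bed
from .cell_scoring import bh_adjust

#: Exhaustive enumeration of open-peak subsets kicks in below this count.
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class PeakMatrix:
    """Binary barcode x peak accessibility matrix tied to peak intervals."""

    values: sp.csr_matrix
    barcode_ids: list[str]
    peak_ids: list[str]
    peaks: IntervalSet

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.nnz and not np.isin(self.values.data, (0, 1)).all():
            raise ValidationError("peak matrix must be binary")
        if self.values.shape != (len(self.barcode_ids), len(self.peak_ids)):
            raise ValidationError("peak matrix shape mismatch")
        names = set(self.peaks.records["name"])
        missing = [p for p in self.peak_ids if p not in names]
        if missing:
            raise ValidationError(f"peaks without intervals: {missing[:5]}")


@dataclass
class OpenPeakCalls:
    """State x peak open calls plus per-state barcode counts."""

    open_: pd.DataFrame           # bool, states x peaks
    state_sizes: pd.Series
    peaks: IntervalSet

    @property
    def states(self) -> list[str]:
        return list(self.open_.index)

    def open_peak_names(self, state: str) -> list[str]:
        row = self.open_.loc[state]
        return list(row.index[row])

    def n_open(self, state: str) -> int:
        return int(self.open_.loc[state].sum())


def binarize_counts(counts, barcode_ids, peak_ids, peaks: IntervalSet
                    ) -> PeakMatrix:
    """Binarize raw peak counts: 1 iff read count > 0. Idempotent."""
    mat = sp.csr_matrix(counts)
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("peak counts must be nonnegative")
    mat = (mat > 0).astype(np.int8)
    return PeakMatrix(mat, list(barcode_ids), list(peak_ids), peaks)


def call_open_peaks(pm: PeakMatrix, labels: Annotation, frac: float = 0.05
                    ) -> OpenPeakCalls:
    """A peak is open for a state iff >= ``frac`` of its barcodes show it."""
    lab = labels.for_rows(pm.barcode_ids)
    states = [s for s in pd.unique(lab)]
    rows, sizes = [], {}
    for s in states:
        idx = np.flatnonzero(lab == s)
        if len(idx) == 0:
            warnings.warn(f"state {s!r} has no barcodes; excluded", stacklevel=2)
            continue
        pos = np.asarray(pm.values[idx].sum(axis=0)).ravel()
        rows.append(pos / len(idx) >= frac)
        sizes[s] = len(idx)
    open_ = pd.DataFrame(rows, index=list(sizes), columns=pm.peak_ids)
    return OpenPeakCalls(open_, pd.Series(sizes), pm.peaks)


def read_snp_bed(path, one_based: bool = False) -> IntervalSet:
    """Read SNP positions as 1-bp intervals.

    BED input is 0-based already; ``one_based`` shifts variant-table style
    1-based positions down by one.
    """
    iv = read_bed(path)
    recs = iv.records.copy()
    if one_based:
        recs["start"] -= 1
    recs["end"] = recs["start"] + 1
    return IntervalSet(recs)


def _peak_tree(peaks: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in peaks.records.itertuples(index=False):
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            rec.start, rec.end, rec.name
        )
    return trees


def snp_hit_matrix(peaks: IntervalSet, snps: IntervalSet) -> sp.csr_matrix:
    """Sparse SNP x peak indicator: SNP start position inside the half-open
    peak interval (chromosome-aware, interval-tree lookup)."""
    trees = _peak_tree(peaks)
    name_idx = {n: i for i, n in enumerate(peaks.records["name"])}
    rows, cols = [], []
    for i, rec in enumerate(snps.records.itertuples(index=False)):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for hit in tree.at(rec.start):
            rows.append(i)
            cols.append(name_idx[hit.data])
    data = np.ones(len(rows), dtype=bool)
    return sp.csr_matrix((data, (rows, cols)), shape=(len(snps), len(peaks)))


def snp_proportion(open_peaks: IntervalSet, snps: IntervalSet) -> float:
    """Fraction of SNPs lying in at least one open peak (multi-peak hits
    counted once)."""
    if len(snps) == 0:
        raise ValidationError("no SNPs supplied")
    if len(open_peaks) == 0:
        return 0.0
    hits = snp_hit_matrix(open_peaks, snps)
    return float((np.asarray(hits.sum(axis=1)).ravel() > 0).mean())


def snp_permutation_test(calls: OpenPeakCalls, state: str, snps: IntervalSet,
                         n_perm: int = 1000, seed: int = 0,
                         exhaustive: bool | None = None
                         ) -> tuple[float, float]:
    """Permutation test of a trait's SNP proportion in a state's open peaks.

    Each permutation re-opens a uniformly random subset of the state's
    peaks of the same size as the observed open set; p is the inclusive
    fraction of permutations whose SNP proportion >= the observed one.
    Exhaustive enumeration of all subsets replaces sampling when their
    number is at most ``EXHAUSTIVE_LIMIT`` (or when forced).
    Returns ``(observed_proportion, p)``.
    """
    if len(snps) == 0:
        raise ValidationError("no SNPs supplied")
    open_row = calls.open_.loc[state].to_numpy()
    n_peaks, n_open = len(open_row), int(open_row.sum())
    if n_open == 0:
        raise ValidationError(f"state {state!r} has no open peaks")
    # align interval records to the peak-id column order of the calls
    recs = calls.peaks.records.set_index("name").loc[
        list(calls.open_.columns)
    ].reset_index()
    aligned = IntervalSet(recs[["chrom", "start", "end", "name"]])
    hits = snp_hit_matrix(aligned, snps)              # SNP x all-peak
    observed = float((hits[:, np.flatnonzero(open_row)].sum(axis=1) > 0).mean())
    if n_open == n_peaks:
        return observed, 1.0
    hits_dense = np.asarray(hits.todense(), dtype=bool)
    if exhaustive is None:
        exhaustive = comb(n_peaks, n_open) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        from itertools import combinations

        total = hit_count = 0
        for subset in combinations(range(n_peaks), n_open):
            prop = float(hits_dense[:, list(subset)].any(axis=1).mean())
            total += 1
            if prop >= observed:
                hit_count += 1
        return observed, hit_count / total
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        subset = rng.choice(n_peaks, size=n_open, replace=False)
        prop = float(hits_dense[:, subset].any(axis=1).mean())
        if prop >= observed:
            ge += 1
    return observed, ge / n_perm


def trait_state_scan(calls: OpenPeakCalls, traits: dict[str, IntervalSet],
                     n_perm: int = 1000, seed: int = 0,
                     bh_scope: str = "grid") -> pd.DataFrame:
    """Full trait x state grid of SNP proportions and permutation p-values.

    BH correction spans the whole grid by default (``bh_scope='grid'``);
    ``'trait'`` corrects within each trait instead.
    """
    if not traits or not calls.states:
        raise ValidationError("need at least one trait and one state")
    rows = []
    for t_idx, (trait, snps) in enumerate(sorted(traits.items())):
        for s_idx, state in enumerate(calls.states):
            prop, p = snp_permutation_test(
                calls, state, snps, n_perm=n_perm,
                seed=seed + 10_000 * t_idx + s_idx,
            )
            rows.append((trait, state, prop, p, calls.n_open(state)))
    out = pd.DataFrame(
        rows, columns=["trait", "state", "snp_proportion", "p", "n_open_peaks"]
    )
    if bh_scope == "grid":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    elif bh_scope == "trait":
        out["p_adj"] = out.groupby("trait")["p"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    else:
        raise ValidationError(f"unknown bh_scope {bh_scope!r}")
    return out
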