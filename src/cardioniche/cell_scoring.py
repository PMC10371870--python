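"""Gene-set scoring of cells/spots and the statistics built on the scores.

Two scoring flavours are provided: the plain mean of a gene set's
log-normalized expression, and a binned-reference score that subtracts the
mean of expression-matched control genes (controls drawn per set gene from
its global-mean-expression bin). Downstream: rank-sum ranking of set scores
per cell state, Welch-t differential expression, Benjamini-Hochberg
correction, and per-gene Pearson correlation against an arbitrary score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import Annotation, NormMatrix, ValidationError

#: Generic pan-neuronal cytoskeletal markers used to score neuronal content.
PAN_NEURONAL_MARKERS = ("PRPH", "NEFL", "NEFM", "NEFH")

_LFC_EPS = 1e-9


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _present_indices(norm: NormMatrix, genes, set_name: str = "gene set"
                     ) -> np.ndarray:
    index = {g: i for i, g in enumerate(norm.col_ids)}
    idx = sorted({index[g] for g in genes if g in index})
    if not idx:
        raise ValidationError(f"no gene of {set_name!r} is present in the matrix")
    return np.array(idx)


def score_gene_set_mean(norm: NormMatrix, genes, set_name: str = "gene set"
                        ) -> np.ndarray:
    """Per-row arithmetic mean of normalized expression over present genes.

    Invariant to gene order and to duplicate listing within the set.
    """
    idx = _present_indices(norm, genes, set_name)
    return np.asarray(norm.values[:, idx].mean(axis=1)).ravel()


def score_gene_set_binned_ref(norm: NormMatrix, genes, n_bins: int = 25,
                              ctrl_per_gene: int = 50, seed: int = 0,
                              control_genes=None,
                              set_name: str = "gene set") -> np.ndarray:
    """Binned-reference score: set mean minus matched-control mean.

    Genes are ranked by global mean expression and cut into ``n_bins``
    equal-size bins; for each set gene, ``ctrl_per_gene`` controls are drawn
    uniformly without replacement from its bin (set genes excluded). When a
    bin holds fewer eligible genes than requested, the draw falls back to
    sampling with replacement and a warning is logged. ``control_genes``
    overrides the sampled reference entirely (test hook / custom reference).
    """
    if len(norm.col_ids) < n_bins:
        raise ValidationError(
            f"matrix has {len(norm.col_ids)} genes < n_bins={n_bins}"
        )
    set_idx = _present_indices(norm, genes, set_name)
    if control_genes is not None:
        ctrl_idx = _present_indices(norm, control_genes, "control set")
    else:
        rng = np.random.default_rng(seed)
        gene_means = np.asarray(norm.values.mean(axis=0)).ravel()
        order = np.argsort(gene_means, kind="stable")
        bin_of = np.empty(len(order), dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            bin_of[chunk] = b
        in_set = np.zeros(len(order), dtype=bool)
        in_set[set_idx] = True
        ctrl: list[np.ndarray] = []
        for gi in set_idx:
            pool = np.flatnonzero((bin_of == bin_of[gi]) & ~in_set)
            if len(pool) >= ctrl_per_gene:
                ctrl.append(rng.choice(pool, size=ctrl_per_gene, replace=False))
            else:
                warnings.warn(
                    f"expression bin exhausted for a gene of {set_name!r}; "
                    "sampling controls with replacement",
                    stacklevel=2,
                )
                ctrl.append(rng.choice(pool, size=ctrl_per_gene, replace=True))
        ctrl_idx = np.concatenate(ctrl)
    set_mean = np.asarray(norm.values[:, set_idx].mean(axis=1)).ravel()
    # pooled control mean keeps duplicate draws (weights by sampling)
    ctrl_mean = np.asarray(norm.values[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def score_gene_sets(norm: NormMatrix, gene_sets: dict, method: str = "mean",
                    seed: int = 0, **kwargs) -> pd.DataFrame:
    """Score every set; returns rows x set-name DataFrame (a score matrix)."""
    if method not in ("mean", "binned"):
        raise ValidationError(f"unknown scoring method {method!r}")
    cols = {}
    for name, genes in gene_sets.items():
        if method == "mean":
            cols[name] = score_gene_set_mean(norm, genes, set_name=name)
        else:
            cols[name] = score_gene_set_binned_ref(
                norm, genes, seed=seed, set_name=name, **kwargs
            )
    return pd.DataFrame(cols, index=pd.Index(norm.row_ids, name="row_id"))


# ---------------------------------------------------------------------------
# Rank-sum ranking of sets per group
# ---------------------------------------------------------------------------

def rank_sum_p(in_group: np.ndarray, out_group: np.ndarray,
               exact_max: int = 8) -> tuple[float, float]:
    """Two-sided rank-sum (statistic, p).

    Exact null enumeration when both sides have <= ``exact_max`` members and
    the data are tie-free; otherwise the normal approximation with mid-rank
    tie correction.
    """
    x = np.asarray(in_group, dtype=float)
    y = np.asarray(out_group, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(x) <= exact_max and len(y) <= exact_max and tie_free:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic",
                                       use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _score_lfc(mean_in: float, mean_out: float) -> float:
    """log2 fold change on scores; means clipped at 0 (binned scores can be
    negative) with a small epsilon so the ratio is always defined."""
    return float(np.log2((max(mean_in, 0.0) + _LFC_EPS)
                         / (max(mean_out, 0.0) + _LFC_EPS)))


def rank_sets_for_group(scores: pd.DataFrame, labels: Annotation, group,
                        lfc_min: float = 2.0, p_adj_max: float = 0.05
                        ) -> pd.DataFrame:
    """Rank score columns by enrichment in ``group`` versus all other rows.

    Returns one row per set with log2 fold change, rank-sum statistic,
    two-sided p, BH-adjusted p, and a flag for sets passing
    lfc > ``lfc_min`` and adjusted p < ``p_adj_max``.
    """
    mask = labels.mask(scores.index, group)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValidationError("need >= 2 rows inside and outside the group")
    rows = []
    for name in scores.columns:
        v = scores[name].to_numpy(dtype=float)
        stat, p = rank_sum_p(v[mask], v[~mask])
        if np.all(v == v[0]):
            lfc = 0.0
        else:
            lfc = _score_lfc(v[mask].mean(), v[~mask].mean())
        rows.append((name, lfc, stat, p))
    out = pd.DataFrame(rows, columns=["set", "log2fc", "statistic", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["flagged"] = (out["log2fc"] > lfc_min) & (out["p_adj"] < p_adj_max)
    return out.sort_values(["flagged", "log2fc"], ascending=False,
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def deg_t_test(norm: NormMatrix, labels: Annotation, group,
               reference=None, p_adj_max: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per gene: ``group`` vs reference group(s).

    ``reference`` may be a label, a list of labels, or None (all other
    rows). Fold changes follow the log-normalized-expression convention
    log2((expm1(mean_in)+eps)/(expm1(mean_out)+eps)). Genes constant on
    both sides get statistic 0 and p = 1.
    """
    lab = labels.for_rows(norm.row_ids)
    mask_in = lab == group
    if reference is None:
        mask_out = ~mask_in
    else:
        ref = [reference] if isinstance(reference, str) else list(reference)
        mask_out = np.isin(lab, ref)
    if mask_in.sum() < 2 or mask_out.sum() < 2:
        raise ValidationError("need >= 2 members per side for the t-test")
    dense = norm.dense()
    a, b = dense[mask_in], dense[mask_out]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    m_in, m_out = a.mean(axis=0), b.mean(axis=0)
    lfc = np.log2((np.expm1(m_in) + _LFC_EPS) / (np.expm1(m_out) + _LFC_EPS))
    out = pd.DataFrame(
        {"gene": norm.col_ids, "log2fc": lfc, "statistic": t, "p": p}
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < p_adj_max
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Score-gene correlation
# ---------------------------------------------------------------------------

def correlate_genes_with_score(norm: NormMatrix, score) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with a per-row score.

    Constant genes get r = NaN and are excluded from BH correction; a
    constant score is an error. Two-sided p-values come from the exact
    t-distribution of r under the bivariate-normal null.
    """
    s = np.asarray(score, dtype=float)
    n = len(s)
    if n < 3:
        raise ValidationError("need >= 3 rows to correlate")
    if n != norm.shape[0]:
        raise ValidationError("score length does not match matrix rows")
    if not np.isfinite(s).all():
        raise ValidationError("score contains non-finite values")
    if np.allclose(s, s[0]):
        raise ValidationError("score vector is constant")
    dense = norm.dense()
    sc = s - s.mean()
    gc = dense - dense.mean(axis=0)
    denom = np.sqrt((gc ** 2).sum(axis=0) * (sc ** 2).sum())
    constant = (gc ** 2).sum(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (gc * sc[:, None]).sum(axis=0) / denom
    r = np.where(constant, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame(
        {
            "gene": norm.col_ids,
            "pearson_r": r,
            "p": np.where(constant, np.nan, p),
            "mean_expression": dense.mean(axis=0),
        }
    )
    adj = np.full(len(out), np.nan)
    valid = ~constant
    if valid.any():
        adj[valid] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["p_adj"] = adj
    return out
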