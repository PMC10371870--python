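"""Unsupervised microenvironment discovery by NMF over spot abundances.

A scan fits non-negative matrix factorizations of the spot x cell-state
abundance matrix for a range of factor counts (n_fact). Each factor's
spot loadings are compared against an annotated structure with a Cohen's d
effect size and a label-permutation p-value; the significant factor with
the largest effect size is the best-factor, and the smallest n_fact whose
run holds at least two factors above half the best effect size supplies
the fine-factors — the refined microenvironments.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .io_core import ValidationError
from .spatial_enrichment import AbundanceMatrix

#: Sentinel magnitude for zero-pooled-SD degenerate effect sizes.
EFFECT_CAP = 1e6


@dataclass
class NMFResult:
    n_fact: int
    W: np.ndarray                  # spots x factors, nonnegative
    H: np.ndarray                  # factors x states, nonnegative
    reconstruction_error: float
    seed: int
    spot_ids: list[str] = field(default_factory=list)
    states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.n_fact or self.H.shape[0] != self.n_fact:
            raise ValidationError("factor dimension mismatch")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValidationError("NMF loadings must be nonnegative")

    def normalized_loadings(self) -> np.ndarray:
        """W columns rescaled to unit mean so factors are comparable."""
        means = self.W.mean(axis=0)
        means[means == 0] = 1.0
        return self.W / means

    def top_states(self, factor: int, threshold: float = 0.4) -> list[str]:
        """States whose max-normalized weight in a factor exceeds threshold."""
        h = self.H[factor]
        if h.max() == 0:
            return []
        h = h / h.max()
        return [s for s, w in zip(self.states, h) if w > threshold]


@dataclass
class FactorSelection:
    table: pd.DataFrame            # n_fact, factor, effect_size, p, p_smoothed
    best: tuple[int, int] | None   # (n_fact, factor) of the best-factor
    best_effect: float
    chosen_n_fact: int | None
    fine_factors: list[tuple[int, int]]
    note: str = ""

    @property
    def empty(self) -> bool:
        return self.best is None


def nmf_scan(ab: AbundanceMatrix, n_fact_range=range(5, 15), seed: int = 0,
             max_iter: int = 2000) -> list[NMFResult]:
    """Fit one Frobenius NMF per factor count in ``n_fact_range``.

    Uses coordinate descent with non-negative double SVD ('nndsvda')
    initialization, so results are deterministic for a given seed.
    """
    X = ab.values.to_numpy(float)
    ranks = sorted(n_fact_range)
    if ranks[-1] > min(X.shape):
        raise ValidationError(
            f"max n_fact {ranks[-1]} exceeds min matrix dimension {min(X.shape)}"
        )
    out = []
    for k in ranks:
        model = NMF(n_components=k, init="nndsvda", solver="cd",
                    max_iter=max_iter, random_state=seed, tol=1e-6)
        W = model.fit_transform(X)
        out.append(
            NMFResult(k, W, model.components_,
                      float(model.reconstruction_err_), seed,
                      ab.spot_ids, ab.states)
        )
    return out


def factor_effect_size(loadings, mask) -> float:
    """Cohen's d of factor loadings inside vs outside a structure mask.

    Pooled-SD formulation; zero pooled SD yields 0 for equal means and the
    capped sentinel otherwise. Single-member groups fall back to the
    unpooled SD of the larger group with a warning.
    """
    x = np.asarray(loadings, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not m.any() or m.all():
        raise ValidationError("mask must split the spots into two groups")
    a, b = x[m], x[~m]
    diff = a.mean() - b.mean()
    if len(a) < 2 or len(b) < 2:
        warnings.warn("single-spot group: unpooled SD fallback", stacklevel=2)
        sd = np.concatenate([a, b]).std(ddof=1)
    else:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sd = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                       / (len(a) + len(b) - 2))
    if sd == 0:
        return 0.0 if diff == 0 else math.copysign(EFFECT_CAP, diff)
    return float(np.clip(diff / sd, -EFFECT_CAP, EFFECT_CAP))


def permutation_effect_p(loadings, mask, n_perm: int = 1000, seed: int = 0,
                         exhaustive: bool = False) -> tuple[float, float]:
    """Label-permutation p-value for a factor's structure effect size.

    Returns ``(p, p_smoothed)`` where p is the literal inclusive fraction
    #{d* >= d_obs}/n_perm (0 is possible) and p_smoothed the add-one
    estimate (#{d* >= d_obs}+1)/(n_perm+1). ``exhaustive`` enumerates every
    mask of the observed size instead of sampling.
    """
    x = np.asarray(loadings, dtype=float)
    m = np.asarray(mask, dtype=bool)
    d_obs = factor_effect_size(x, m)
    n, k = len(x), int(m.sum())
    if exhaustive:
        hits = total = 0
        for combo in itertools.combinations(range(n), k):
            mm = np.zeros(n, dtype=bool)
            mm[list(combo)] = True
            total += 1
            if factor_effect_size(x, mm) >= d_obs:
                hits += 1
        return hits / total, (hits + 1) / (total + 1)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = m.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if factor_effect_size(x, perm) >= d_obs:
            hits += 1
    return hits / n_perm, (hits + 1) / (n_perm + 1)


def select_factors(results: list[NMFResult], mask, alpha: float = 0.05,
                   proportion: float = 0.5, n_perm: int = 1000,
                   seed: int = 0, joint: bool = True) -> FactorSelection:
    """Best-/fine-factor selection against a structure mask.

    Effect sizes and permutation p-values are computed on unit-mean
    normalized loadings for every factor of every run. The best-factor is
    the significant (p < alpha) factor with maximal effect size, searched
    jointly across all runs by default; the chosen n_fact is the smallest
    run containing >= 2 factors with effect size above
    ``proportion`` x best, and those factors are the fine-factors.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for ridx, res in enumerate(results):
        Wn = res.normalized_loadings()
        for j in range(res.n_fact):
            d = factor_effect_size(Wn[:, j], mask)
            p, ps = permutation_effect_p(
                Wn[:, j], mask, n_perm=n_perm,
                seed=seed + 1000 * ridx + j,
            )
            rows.append((res.n_fact, j, d, p, ps))
    table = pd.DataFrame(
        rows, columns=["n_fact", "factor", "effect_size", "p", "p_smoothed"]
    )
    sig = table[table["p"] < alpha]
    if sig.empty:
        return FactorSelection(table, None, float("nan"), None, [],
                               note="no factor reached significance")
    if not joint:
        # per-run mode: best within each run, overall best still reported
        pass
    best_row = sig.loc[sig["effect_size"].idxmax()]
    best = (int(best_row["n_fact"]), int(best_row["factor"]))
    d_best = float(best_row["effect_size"])
    chosen, fine = None, []
    for res in sorted(results, key=lambda r: r.n_fact):
        sub = table[(table["n_fact"] == res.n_fact)
                    & (table["effect_size"] > proportion * d_best)]
        if len(sub) >= 2:
            chosen = res.n_fact
            fine = [(int(r.n_fact), int(r.factor)) for r in sub.itertuples()]
            break
    note = "" if chosen is not None else (
        "no run held >= 2 factors above the proportion of the best effect"
    )
    return FactorSelection(table, best, d_best, chosen, fine, note)
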