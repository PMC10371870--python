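"""Ligand-receptor screening over a custom interaction database.

The database format mirrors a CellPhoneDB-style user module: an
interactions table of (partner_a, partner_b) where a partner is either a
protein id or a named complex, a complexes table expanding complex names to
member proteins, and an optional protein-to-gene map. Ligand proxies
(biosynthetic enzymes or transporters standing in for non-gene-encoded
ligands) are ordinary partners carrying a proxy flag for reporting.

The screen statistic is the LR mean: the average of the ligand partner's
mean expression in the sender state and the receptor partner's in the
receiver state, a complex partner contributing the minimum over its
members (limiting subunit). Significance comes from shuffling cell-state
labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import Annotation, NormMatrix, ValidationError
from .cell_scoring import deg_t_test

#: States with fewer cells than this get p = 1 (means too unstable to test).
MIN_CELLS_PER_STATE = 10


@dataclass
class LRDatabase:
    interactions: pd.DataFrame        # partner_a, partner_b, proxy_a, proxy_b
    complexes: dict[str, list[str]]   # complex name -> member protein ids
    gene_map: dict[str, str] = field(default_factory=dict)  # protein -> gene

    def __post_init__(self) -> None:
        for col in ("partner_a", "partner_b"):
            if col not in self.interactions.columns:
                raise ValidationError(f"interactions table needs {col!r}")
        for name, members in self.complexes.items():
            if not members:
                raise ValidationError(f"complex {name!r} has no members")

    def __len__(self) -> int:
        return len(self.interactions)

    def partner_genes(self, partner: str) -> list[str]:
        """Gene symbols for a partner (complex expanded to its members)."""
        members = self.complexes.get(partner, [partner])
        return [self.gene_map.get(m, m) for m in members]

    def is_complex(self, partner: str) -> bool:
        return partner in self.complexes


def load_lr_database(interactions_csv, complexes_csv,
                     gene_map_csv=None) -> LRDatabase:
    """Load and validate interaction + complex tables.

    The complexes CSV has a ``complex_name`` column followed by
    ``member_1..member_k`` columns (trailing members may be blank). With a
    protein-to-gene map, every simple partner and every complex member must
    resolve; partners that are neither complexes nor mapped proteins are
    rejected by name.
    """
    inter = pd.read_csv(interactions_csv)
    comp_df = pd.read_csv(complexes_csv)
    if "complex_name" not in comp_df.columns:
        raise ValidationError("complexes table needs a complex_name column")
    member_cols = [c for c in comp_df.columns if c.startswith("member_")]
    complexes: dict[str, list[str]] = {}
    for row in comp_df.itertuples(index=False):
        members = [
            getattr(row, c) for c in member_cols
            if isinstance(getattr(row, c), str) and getattr(row, c)
        ]
        complexes[row.complex_name] = members
    gene_map: dict[str, str] = {}
    if gene_map_csv is not None:
        gm = pd.read_csv(gene_map_csv)
        gene_map = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))
        unresolved = sorted(
            {
                p
                for p in pd.concat([inter["partner_a"], inter["partner_b"]])
                if p not in complexes and p not in gene_map
            }
            | {
                m
                for members in complexes.values()
                for m in members
                if m not in gene_map
            }
        )
        if unresolved:
            raise ValidationError(
                f"partners neither complexes nor mapped proteins: {unresolved}"
            )
    for col in ("proxy_a", "proxy_b"):
        if col not in inter.columns:
            inter[col] = False
    return LRDatabase(inter, complexes, gene_map)


# ---------------------------------------------------------------------------
# Expression statistics
# ---------------------------------------------------------------------------

def expressed_fraction(norm: NormMatrix, labels: Annotation, gene: str,
                       state: str) -> float:
    """Fraction of a state's cells with nonzero expression of a gene.

    Depends only on the zero pattern, so it is invariant to the
    normalization choice. An absent gene yields 0.
    """
    mask = labels.mask(norm.row_ids, state)
    if not mask.any():
        raise ValidationError(f"state {state!r} has no cells")
    try:
        col = norm.column(gene)
    except KeyError:
        import warnings

        warnings.warn(f"gene {gene!r} absent from matrix", stacklevel=2)
        return 0.0
    return float((col[mask] > 0).mean())


def _partner_value(dense: np.ndarray, col_index: dict[str, int],
                   mask: np.ndarray, genes: list[str],
                   complex_rule: str) -> float:
    means = []
    for g in genes:
        if g not in col_index:
            raise ValidationError(f"interaction member {g!r} not in matrix")
        means.append(float(dense[mask, col_index[g]].mean()))
    if len(means) == 1:
        return means[0]
    return min(means) if complex_rule == "min" else float(np.mean(means))


def lr_mean(norm: NormMatrix, labels: Annotation, db: LRDatabase,
            interaction_index: int, sender: str, receiver: str,
            complex_rule: str = "min") -> float:
    """LR mean of one interaction for a (sender, receiver) state pair."""
    row = db.interactions.iloc[interaction_index]
    dense = norm.dense()
    col_index = {g: i for i, g in enumerate(norm.col_ids)}
    lab = labels.for_rows(norm.row_ids)
    m_s, m_r = lab == sender, lab == receiver
    if not m_s.any() or not m_r.any():
        raise ValidationError("sender or receiver state has no cells")
    a = _partner_value(dense, col_index, m_s, db.partner_genes(row.partner_a),
                       complex_rule)
    b = _partner_value(dense, col_index, m_r, db.partner_genes(row.partner_b),
                       complex_rule)
    return (a + b) / 2.0


def lr_permutation_p(norm: NormMatrix, labels: Annotation, db: LRDatabase,
                     interaction_index: int, sender: str, receiver: str,
                     n_perm: int = 1000, seed: int = 0,
                     complex_rule: str = "min",
                     min_cells: int = MIN_CELLS_PER_STATE,
                     exhaustive: bool = False) -> float:
    """Cell-state label-permutation p-value for one interaction.

    The null shuffles state labels over cells and recomputes the LR mean;
    p is the inclusive fraction of permuted values >= the observed one.
    Degenerate inputs (a single state, undersized states, or an observed LR
    mean of 0) return p = 1.
    """
    lab = labels.for_rows(norm.row_ids)
    states = pd.unique(lab)
    if len(states) < 2:
        return 1.0
    m_s, m_r = lab == sender, lab == receiver
    if m_s.sum() < min_cells or m_r.sum() < min_cells:
        return 1.0
    row = db.interactions.iloc[interaction_index]
    genes_a = db.partner_genes(row.partner_a)
    genes_b = db.partner_genes(row.partner_b)
    dense = norm.dense()
    col_index = {g: i for i, g in enumerate(norm.col_ids)}

    def stat(mask_s, mask_r):
        a = _partner_value(dense, col_index, mask_s, genes_a, complex_rule)
        b = _partner_value(dense, col_index, mask_r, genes_b, complex_rule)
        return (a + b) / 2.0

    observed = stat(m_s, m_r)
    if observed == 0:
        return 1.0
    n = len(lab)
    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            pl = lab[list(perm)]
            total += 1
            if stat(pl == sender, pl == receiver) >= observed:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    perm = lab.copy()
    ge = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if stat(perm == sender, perm == receiver) >= observed:
            ge += 1
    return ge / n_perm


def niche_interaction_screen(norm: NormMatrix, labels: Annotation,
                             db: LRDatabase, niche_states,
                             mode: str = "statistical",
                             frac_min: float = 0.1, p_max: float = 0.05,
                             lfc_min: float = 0.1, n_perm: int = 1000,
                             seed: int = 0,
                             complex_rule: str = "min") -> pd.DataFrame:
    """Screen all interactions over ordered pairs of niche cell states.

    mode 'statistical': every member gene expressed in >= ``frac_min`` of
    its state's cells and label-permutation p < ``p_max``.
    mode 'deg': the fraction filter plus at least one member differentially
    expressed (adjusted p < ``p_max``, log2 fold change > ``lfc_min``) in
    its state versus the rest.
    """
    niche_states = list(niche_states)
    if not niche_states:
        raise ValidationError("empty niche state set")
    vocab = set(labels.labels.unique())
    unknown = [s for s in niche_states if s not in vocab]
    if unknown:
        raise ValidationError(f"states not in annotation: {unknown}")
    if mode not in ("statistical", "deg"):
        raise ValidationError(f"unknown screen mode {mode!r}")
    deg_tables: dict[str, pd.DataFrame] = {}
    if mode == "deg":
        for s in niche_states:
            tab = deg_t_test(norm, labels, s)
            deg_tables[s] = tab.set_index("gene")
    rows = []
    for idx in range(len(db.interactions)):
        rec = db.interactions.iloc[idx]
        genes_a = db.partner_genes(rec.partner_a)
        genes_b = db.partner_genes(rec.partner_b)
        for sender, receiver in itertools.product(niche_states, repeat=2):
            if sender == receiver:
                continue
            frac_ok = all(
                expressed_fraction(norm, labels, g, sender) >= frac_min
                for g in genes_a
            ) and all(
                expressed_fraction(norm, labels, g, receiver) >= frac_min
                for g in genes_b
            )
            if not frac_ok:
                rows.append((idx, rec.partner_a, rec.partner_b, sender,
                             receiver, math.nan, math.nan, False, False))
                continue
            mean = lr_mean(norm, labels, db, idx, sender, receiver,
                           complex_rule)
            if mode == "statistical":
                p = lr_permutation_p(
                    norm, labels, db, idx, sender, receiver,
                    n_perm=n_perm, seed=seed + idx, complex_rule=complex_rule,
                )
                passed = p < p_max
            else:
                hits_a = any(
                    g in deg_tables[sender].index
                    and deg_tables[sender].loc[g, "p_adj"] < p_max
                    and deg_tables[sender].loc[g, "log2fc"] > lfc_min
                    for g in genes_a
                )
                hits_b = any(
                    g in deg_tables[receiver].index
                    and deg_tables[receiver].loc[g, "p_adj"] < p_max
                    and deg_tables[receiver].loc[g, "log2fc"] > lfc_min
                    for g in genes_b
                )
                p = math.nan
                passed = hits_a or hits_b
            rows.append((idx, rec.partner_a, rec.partner_b, sender, receiver,
                         mean, p, True, passed))
    return pd.DataFrame(
        rows,
        columns=["interaction", "partner_a", "partner_b", "sender",
                 "receiver", "lr_mean", "p", "passed_fraction", "passed"],
    )
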