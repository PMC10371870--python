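"""Knowledge-based spatial enrichment and the product-abundance niche caller.

Works on a spot x cell-state abundance matrix (the output format of a
spatial deconvolution model such as cell2location) with array coordinates
and optional manually annotated structure labels (epicardium, node, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.spatial
import scipy.stats
from scipy.sparse.csgraph import connected_components

from .io_core import ValidationError
from .cell_scoring import bh_adjust


@dataclass
class AbundanceMatrix:
    """Dense nonnegative spot x cell-state abundances with coordinates."""

    values: pd.DataFrame                 # spots x states
    coords: pd.DataFrame                 # columns array_row, array_col
    structure: pd.Series | None = None   # per-spot structure label

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("abundances must be nonnegative")
        self.coords = pd.DataFrame(self.coords).loc[self.values.index]
        for c in ("array_row", "array_col"):
            if c not in self.coords.columns:
                raise ValidationError(f"coords needs an {c!r} column")
        if self.coords[["array_row", "array_col"]].duplicated().any():
            raise ValidationError("duplicate spot coordinates")
        if self.structure is not None:
            self.structure = pd.Series(self.structure).loc[self.values.index]

    @property
    def spot_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def states(self) -> list[str]:
        return list(self.values.columns)

    def xy(self) -> np.ndarray:
        return self.coords[["array_col", "array_row"]].to_numpy(float)

    def structure_mask(self, structure) -> np.ndarray:
        """Boolean spot mask for one structure label or a collection."""
        if self.structure is None:
            raise ValidationError("abundance matrix carries no structure labels")
        if isinstance(structure, str):
            structure = [structure]
        return self.structure.isin(list(structure)).to_numpy()


@dataclass
class NicheCallResult:
    """Connected spot clusters called by the product-abundance rule."""

    clusters: list[set]
    sizes: list[int] = field(default_factory=list)
    mean_products: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def all_spots(self) -> set:
        out: set = set()
        for c in self.clusters:
            out |= c
        return out


def read_abundance_tsv(path, structure_col: str = "structure") -> AbundanceMatrix:
    """Read a TSV with columns spot, array_row, array_col, [structure],
    then one column per cell state."""
    df = pd.read_csv(path, sep="\t").set_index("spot")
    coords = df[["array_row", "array_col"]]
    structure = df[structure_col] if structure_col in df.columns else None
    drop = ["array_row", "array_col"] + ([structure_col] if structure is not None else [])
    return AbundanceMatrix(df.drop(columns=drop), coords, structure)


def write_abundance_tsv(ab: AbundanceMatrix, path) -> None:
    df = pd.concat([ab.coords[["array_row", "array_col"]], ab.values], axis=1)
    if ab.structure is not None:
        df.insert(2, "structure", ab.structure)
    df.index.name = "spot"
    df.to_csv(path, sep="\t")


def state_proportions(ab: AbundanceMatrix) -> pd.DataFrame:
    """Per-spot cell-state proportions (rows sum to 1).

    Spots with zero total abundance are excluded with a warning.
    """
    totals = ab.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-abundance spots",
                      stacklevel=2)
    vals = ab.values.loc[~zero]
    return vals.div(totals[~zero], axis=0)


def structure_enrichment(ab: AbundanceMatrix, structure: str,
                         pooled: bool = True,
                         yates: bool = True) -> pd.DataFrame:
    """Odds-ratio enrichment of each cell state in an annotated structure.

    For each state the proportion of total abundance it contributes is
    computed inside and outside the structure (``pooled=True`` sums
    abundances across spots before forming proportions; ``pooled=False``
    averages per-spot proportions). The odds ratio is
    [p_in/(1-p_in)] / [p_out/(1-p_out)]; significance comes from a
    chi-square test on the rounded 2x2 table of summed abundances
    (state vs rest) x (in vs out), Yates-corrected, with BH correction
    across states.
    """
    mask = ab.structure_mask(structure)
    if mask.all() or not mask.any():
        raise ValidationError(
            f"structure {structure!r} must be present on some spots and "
            "absent on others"
        )
    vals = ab.values.to_numpy(float)
    if pooled:
        in_state = vals[mask].sum(axis=0)
        out_state = vals[~mask].sum(axis=0)
        p_in = in_state / in_state.sum()
        p_out = out_state / out_state.sum()
    else:
        props = ab.values.div(ab.values.sum(axis=1), axis=0).to_numpy()
        p_in = props[mask].mean(axis=0)
        p_out = props[~mask].mean(axis=0)
        in_state = vals[mask].sum(axis=0)
        out_state = vals[~mask].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_in = p_in / (1.0 - p_in)
        odds_out = p_out / (1.0 - p_out)
        oratio = odds_in / odds_out
    oratio = np.where((p_in == 0), 0.0, oratio)
    oratio = np.where((p_out == 0) & (p_in > 0), np.inf, oratio)
    total_in, total_out = vals[mask].sum(), vals[~mask].sum()
    pvals = np.empty(len(ab.states))
    for j in range(len(ab.states)):
        table = np.rint(
            [
                [in_state[j], total_in - in_state[j]],
                [out_state[j], total_out - out_state[j]],
            ]
        ).astype(np.int64)
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (
                table.sum(axis=1) == 0).any():
            pvals[j] = 1.0
        else:
            pvals[j] = scipy.stats.chi2_contingency(table, correction=yates)[1]
    return pd.DataFrame(
        {
            "state": ab.states,
            "structure": structure,
            "odds_ratio": oratio,
            "chi2_p": pvals,
            "p_adj": bh_adjust(pvals),
            "n_spots_in": int(mask.sum()),
            "n_spots_out": int((~mask).sum()),
        }
    )


def spot_adjacency(ab: AbundanceMatrix, scale: float = 1.5) -> sp.csr_matrix:
    """Symmetric boolean adjacency: spots within ``scale`` x the minimum
    pairwise distance (Euclidean, array coordinates) are neighbours.

    On the hex-offset lattice of a Visium slide the default captures each
    interior spot's 6 neighbours.
    """
    xy = ab.xy()
    n = len(xy)
    if n < 2:
        raise ValidationError("need >= 2 spots for adjacency")
    tree = scipy.spatial.cKDTree(xy)
    d_nn, _ = tree.query(xy, k=2)
    d_min = float(d_nn[:, 1].min())
    pairs = tree.query_pairs(r=scale * d_min * (1 + 1e-9), output_type="ndarray")
    data = np.ones(len(pairs), dtype=bool)
    adj = sp.coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    adj = adj + adj.T
    return adj.tocsr()


def call_product_niche(ab: AbundanceMatrix, state_a: str, state_b: str,
                       threshold: float = 0.03, min_cluster: int = 5,
                       scale: float = 1.5) -> NicheCallResult:
    """Call niche spot clusters from the product of two state abundances.

    Spots whose per-spot product ab[state_a] * ab[state_b] exceeds
    ``threshold`` are candidates; connected components of candidates (under
    spot adjacency) of size strictly greater than ``min_cluster`` are
    returned.
    """
    for s in (state_a, state_b):
        if s not in ab.values.columns:
            raise ValidationError(f"state {s!r} not in abundance matrix")
    product = (ab.values[state_a] * ab.values[state_b]).to_numpy(float)
    cand = np.flatnonzero(product > threshold)
    if len(cand) == 0:
        return NicheCallResult([], [], [])
    if len(cand) == 1:
        comp_labels = np.array([0])
    else:
        adj = spot_adjacency(ab, scale=scale)[cand][:, cand]
        _, comp_labels = connected_components(adj, directed=False)
    ids = np.array(ab.spot_ids, dtype=object)
    clusters, sizes, means = [], [], []
    for c in np.unique(comp_labels):
        members = cand[comp_labels == c]
        if len(members) > min_cluster:
            clusters.append(set(ids[members]))
            sizes.append(int(len(members)))
            means.append(float(product[members].mean()))
    return NicheCallResult(clusters, sizes, means)
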