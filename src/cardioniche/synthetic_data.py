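"""Seeded generators for every input the toolkit consumes.

Each generator plants known structure — marker-gene programs, spatial
niches, state-specific open chromatin with SNP enrichment, drug hits and
decoys — so every analysis stage has a ground truth to recover. Counts are
negative-binomial with moderate overdispersion; spots sit on a hex-offset
lattice like a Visium capture array; abundances emulate the output format
of a spatial deconvolution model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import Annotation, CountMatrix, IntervalSet, ValidationError
from .spatial_enrichment import AbundanceMatrix
from .snp_enrichment import PeakMatrix, binarize_counts


def _default_states() -> dict[str, int]:
    # state -> number of marker genes
    return {"P_cell": 10, "FB_act": 10, "vCM_str": 10}


def _default_regions() -> list[tuple[str, float, float]]:
    # (name, row-fraction lo, row-fraction hi); bands tile the grid
    return [
        ("background", 0.0, 0.4),
        ("central", 0.4, 0.6),
        ("peripheral", 0.6, 0.8),
        ("stress", 0.8, 1.0),
    ]


def _default_mixtures() -> dict[str, dict[str, float]]:
    return {
        "background": {"aCM": 0.60, "EC": 0.20, "SMC": 0.13, "MP": 0.05,
                       "FB_act": 0.005, "vCM_str": 0.005, "P_cell": 0.005,
                       "glial": 0.005},
        # the two node compartments carry disjoint dominant programs
        "central": {"P_cell": 0.55, "aCM": 0.25, "EC": 0.13, "SMC": 0.03,
                    "MP": 0.02, "glial": 0.005, "FB_act": 0.0075,
                    "vCM_str": 0.0075},
        "peripheral": {"glial": 0.45, "MP": 0.30, "EC": 0.13, "aCM": 0.08,
                       "SMC": 0.02, "P_cell": 0.005, "FB_act": 0.0075,
                       "vCM_str": 0.0075},
        "stress": {"FB_act": 0.35, "vCM_str": 0.35, "EC": 0.15, "aCM": 0.13,
                   "SMC": 0.005, "MP": 0.005, "P_cell": 0.005,
                   "glial": 0.005},
    }


@dataclass
class SynthSpec:
    """Parameters of the planted synthetic study.

    Defaults are the package's standing study conditions; generators are
    bit-reproducible for a given seed.
    """

    seed: int = 0
    # expression
    n_cells: int = 600
    n_genes: int = 400
    states: dict[str, int] = field(default_factory=_default_states)
    marker_effect: float = 4.0          # log2 shift of marker means in-state
    marker_base_mean: float = 0.3       # markers near-silent out of state
    dispersion: float = 0.5             # NB: var = mu + dispersion * mu^2
    base_mean: float = 1.0              # lognormal median of per-gene means
    base_sigma: float = 0.8
    # spots
    grid_rows: int = 20
    grid_cols: int = 20
    regions: list = field(default_factory=_default_regions)
    mixtures: dict = field(default_factory=_default_mixtures)
    n_filler_states: int = 8            # low-abundance bystander states
    filler_weight: float = 0.005
    cells_per_spot: float = 7.0         # Visium-scale spot occupancy
    spot_sigma: float = 0.2             # lognormal spread of spot totals
    dirichlet_conc: float = 50.0
    spot_depth_log_mu: float = 8.0      # lognormal UMI depth of spot counts
    spot_depth_log_sigma: float = 0.3
    # peaks / SNPs
    n_peaks: int = 120
    peak_width: int = 501
    peak_gap: int = 1500
    atac_states: tuple = ("stateA", "stateB", "stateC")
    barcodes_per_state: int = 100
    open_fraction: float = 0.3          # peaks open per state
    p_detect_open: float = 0.3          # per-barcode detection in open peaks
    p_detect_closed: float = 0.01
    n_snps: int = 200
    snp_enrichment: float = 5.0         # fold over uniform for the target state
    target_state: str = "stateA"
    # drug table
    n_decoy_drugs: int = 5

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValidationError("counts must be positive")
        if sum(self.states.values()) > self.n_genes:
            raise ValidationError("marker programs exceed the gene count")
        for name, mix in self.mixtures.items():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValidationError(f"mixture {name!r} does not sum to 1")

    def marker_genes(self, state: str) -> list[str]:
        """Marker program of a state (disjoint blocks of the gene list)."""
        start = 0
        for s, k in self.states.items():
            if s == state:
                return [f"g{start + i:04d}" for i in range(k)]
            start += k
        raise ValidationError(f"unknown state {state!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_expression(spec: SynthSpec, row_kind: str = "cell"
                   ) -> tuple[CountMatrix, Annotation]:
    """Negative-binomial counts with planted marker programs.

    Marker genes of state s have their mean multiplied by
    2**marker_effect in rows of s. Rows are assigned to states
    round-robin; gene base means are lognormal. With ``row_kind='spot'``
    each row's mean profile is rescaled so total depth follows the
    lognormal Visium-like distribution of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    rows = [f"{row_kind}{i:05d}" for i in range(spec.n_cells)]
    state_names = list(spec.states)
    labels = np.array([state_names[i % len(state_names)]
                       for i in range(spec.n_cells)])
    base = spec.base_mean * rng.lognormal(0.0, spec.base_sigma, spec.n_genes)
    n_markers = sum(spec.states.values())
    base[:n_markers] = spec.marker_base_mean   # marker baseline out of state
    mean = np.tile(base, (spec.n_cells, 1))
    for s in state_names:
        idx = [int(g[1:]) for g in spec.marker_genes(s)]
        mean[np.ix_(labels == s, idx)] *= 2.0 ** spec.marker_effect
    if row_kind == "spot":
        depth = rng.lognormal(spec.spot_depth_log_mu,
                              spec.spot_depth_log_sigma, spec.n_cells)
        mean *= (depth / mean.sum(axis=1))[:, None]
    counts = _nb_draw(rng, mean, spec.dispersion)
    cm = CountMatrix(sp.csr_matrix(counts), rows, genes, row_kind)
    ann = Annotation(pd.Series(labels, index=rows))
    return cm, ann


def hex_grid(n_rows: int, n_cols: int) -> pd.DataFrame:
    """Hex-offset lattice coordinates (unit nearest-neighbour spacing)."""
    rows, cols, x, y, ids = [], [], [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"spot_{r:02d}_{c:02d}")
            rows.append(r)
            cols.append(c)
            x.append(c + 0.5 * (r % 2))
            y.append(r * math.sqrt(3.0) / 2.0)
    return pd.DataFrame(
        {"grid_row": rows, "grid_col": cols, "array_row": y, "array_col": x},
        index=ids,
    )


def gen_spots(spec: SynthSpec) -> AbundanceMatrix:
    """Spot x state abundances over a hex grid with planted region niches.

    Row bands of the grid carry named structures; each spot's abundances
    are its region mixture perturbed by a Dirichlet draw and scaled by a
    lognormal total around ``cells_per_spot``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    grid = hex_grid(spec.grid_rows, spec.grid_cols)
    bounds = sorted(spec.regions, key=lambda r: r[1])
    for (_, _, hi), (_, lo2, _) in zip(bounds, bounds[1:]):
        if not math.isclose(hi, lo2):
            raise ValidationError("regions must tile the grid without overlap")
    states = sorted({s for mix in spec.mixtures.values() for s in mix})
    states += [f"misc{i}" for i in range(spec.n_filler_states)]
    frac = grid["grid_row"].to_numpy() / spec.grid_rows
    structure = np.empty(len(grid), dtype=object)
    for name, lo, hi in spec.regions:
        structure[(frac >= lo) & (frac < hi)] = name
    structure[frac >= bounds[-1][2] - 1e-12] = bounds[-1][0]
    values = np.zeros((len(grid), len(states)))
    totals = rng.lognormal(math.log(spec.cells_per_spot), spec.spot_sigma,
                           len(grid))
    for i, region in enumerate(structure):
        mix = spec.mixtures[region]
        alpha = np.array([
            spec.dirichlet_conc * mix.get(s, spec.filler_weight)
            for s in states
        ])
        values[i] = totals[i] * rng.dirichlet(alpha)
    return AbundanceMatrix(
        pd.DataFrame(values, index=grid.index, columns=states),
        grid[["array_row", "array_col"]],
        pd.Series(structure, index=grid.index),
    )


def gen_peaks_snps(spec: SynthSpec
                   ) -> tuple[PeakMatrix, Annotation, dict[str, IntervalSet]]:
    """Binary peak matrix, barcode states and trait SNPs with planted
    enrichment.

    Peaks are fixed-width, non-overlapping intervals on one chromosome.
    Each state opens a random subset of peaks; barcodes detect open peaks
    with probability ``p_detect_open`` and closed ones with
    ``p_detect_closed``. The trait's SNPs fall inside the target state's
    open peaks at ``snp_enrichment`` times the uniform rate; a matched
    null trait is uniform.
    """
    rng = np.random.default_rng(spec.seed + 2)
    step = spec.peak_width + spec.peak_gap
    genome = spec.n_peaks * step + spec.peak_gap
    starts = np.arange(spec.n_peaks) * step + spec.peak_gap
    peaks = IntervalSet(pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + spec.peak_width,
        "name": [f"peak{i:04d}" for i in range(spec.n_peaks)],
    }))
    n_open = max(1, int(round(spec.open_fraction * spec.n_peaks)))
    open_sets = {
        s: rng.choice(spec.n_peaks, size=n_open, replace=False)
        for s in spec.atac_states
    }
    barcodes, labels, blocks = [], [], []
    for s in spec.atac_states:
        probs = np.full(spec.n_peaks, spec.p_detect_closed)
        probs[open_sets[s]] = spec.p_detect_open
        draw = rng.random((spec.barcodes_per_state, spec.n_peaks)) < probs
        blocks.append(draw.astype(np.int8))
        barcodes += [f"{s}_bc{i:04d}" for i in range(spec.barcodes_per_state)]
        labels += [s] * spec.barcodes_per_state
    pm = binarize_counts(sp.csr_matrix(np.vstack(blocks)), barcodes,
                         peaks.records["name"].tolist(), peaks)
    ann = Annotation(pd.Series(labels, index=barcodes))

    open_target = open_sets[spec.target_state]
    coverage = len(open_target) * spec.peak_width / genome
    q = min(1.0, spec.snp_enrichment * coverage)

    def draw_snps(enriched: bool) -> IntervalSet:
        pos = np.empty(spec.n_snps, dtype=np.int64)
        inside = rng.random(spec.n_snps) < (q if enriched else coverage)
        for i in range(spec.n_snps):
            if inside[i]:
                pk = int(rng.choice(open_target))
                pos[i] = starts[pk] + rng.integers(spec.peak_width)
            else:
                # uniform over the genome outside the target's open peaks
                while True:
                    cand = int(rng.integers(genome))
                    k = (cand - spec.peak_gap) // step
                    in_peak = (
                        0 <= k < spec.n_peaks
                        and starts[k] <= cand < starts[k] + spec.peak_width
                    )
                    if not (in_peak and k in set(open_target)):
                        pos[i] = cand
                        break
        return IntervalSet(pd.DataFrame({
            "chrom": "chr1", "start": pos, "end": pos + 1,
            "name": [f"rs{i:05d}" for i in range(spec.n_snps)],
        }))

    traits = {
        "planted_trait": draw_snps(True),
        "null_trait": draw_snps(False),
    }
    return pm, ann, traits


def gen_drug_table(spec: SynthSpec) -> pd.DataFrame:
    """ChEMBL-export-like rows: one planted hit drug per expression state
    plus decoys failing the organism / phase / potency gates."""
    rng = np.random.default_rng(spec.seed + 3)
    rows = []
    for i, state in enumerate(spec.states):
        for gene in spec.marker_genes(state):
            rows.append({
                "drug_id": f"HIT_{state}",
                "drug_name": f"drug targeting {state}",
                "max_phase": 4,
                "organism": "Homo sapiens",
                "target_gene": gene,
                "target_family": "gpcr",
                "pchembl": 7.5,
                "atc_codes": f"C0{i + 1}AA",
            })
    all_genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    fails = [
        {"pchembl": 6.0},                         # below the GPCR cutoff
        {"organism": "Rattus norvegicus"},
        {"max_phase": 2},
        {"pchembl": float("nan")},
        {"target_family": "kinase", "pchembl": 7.0},  # below kinase cutoff
    ]
    for d in range(spec.n_decoy_drugs):
        tweak = fails[d % len(fails)]
        for gene in rng.choice(all_genes, size=5, replace=False):
            row = {
                "drug_id": f"DECOY_{d}",
                "drug_name": f"decoy {d}",
                "max_phase": 4,
                "organism": "Homo sapiens",
                "target_gene": gene,
                "target_family": "gpcr",
                "pchembl": 7.2,
                "atc_codes": "",
            }
            row.update(tweak)
            rows.append(row)
    return pd.DataFrame(rows)


def gen_lr_tables(spec: SynthSpec, n_decoys: int = 10
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction + complex tables with one planted pair.

    The planted ligand is a marker of the first state and the planted
    receptor a two-member complex of markers of the second state, so the
    screen should call (first -> second) and not the reverse. Decoy
    interactions pair non-marker genes.
    """
    states = list(spec.states)
    if len(states) < 2:
        raise ValidationError("need >= 2 states for LR planting")
    lig = spec.marker_genes(states[0])[0]
    rec_members = spec.marker_genes(states[1])[:2]
    inter = [{"partner_a": lig, "partner_b": "planted_receptor_complex",
              "proxy_a": False, "proxy_b": False}]
    n_markers = sum(spec.states.values())
    rng = np.random.default_rng(spec.seed + 4)
    pool = [f"g{i:04d}" for i in range(n_markers, spec.n_genes)]
    for i in range(n_decoys):
        a, b = rng.choice(pool, size=2, replace=False)
        inter.append({"partner_a": a, "partner_b": b,
                      "proxy_a": bool(i % 2), "proxy_b": False})
    complexes = pd.DataFrame([
        {"complex_name": "planted_receptor_complex",
         "member_1": rec_members[0], "member_2": rec_members[1]},
    ])
    return pd.DataFrame(inter), complexes
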