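"""Run configuration: every tunable threshold with its standing default."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .io_core import ValidationError


@dataclass
class RunConfig:
    """Flat configuration for the pipeline; defaults are the standing
    analysis parameters documented in docs/methods.md."""

    seed: int = 0
    outdir: str = "cardioniche_out"
    verbosity: str = "info"
    # QC
    qc_min_genes: int = 200
    qc_max_frac_cells: float = 0.20
    qc_max_frac_nuclei: float = 0.05
    spot_min_umi: int = 500
    spot_min_genes: int = 300
    # drug filtering / ranking
    max_phase_min: int = 4
    organism: str = "Homo sapiens"
    rank_lfc_min: float = 2.0
    rank_p_adj_max: float = 0.05
    # spatial / niche
    niche_product_threshold: float = 0.03
    niche_min_cluster: int = 5
    adjacency_scale: float = 1.5
    nmf_n_fact_min: int = 5
    nmf_n_fact_max: int = 14
    nmf_proportion: float = 0.5
    nmf_alpha: float = 0.05
    # GWAS
    open_peak_frac: float = 0.05
    n_perm: int = 1000
    # LR screen
    lr_expressed_frac: float = 0.1
    lr_p_max: float = 0.05
    lr_lfc_min: float = 0.1

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.qc_max_frac_cells <= 1, "qc_max_frac_cells in [0,1]"),
            (0 <= self.qc_max_frac_nuclei <= 1, "qc_max_frac_nuclei in [0,1]"),
            (0 <= self.open_peak_frac <= 1, "open_peak_frac in [0,1]"),
            (0 < self.nmf_proportion <= 1, "nmf_proportion in (0,1]"),
            (self.nmf_n_fact_min <= self.nmf_n_fact_max, "n_fact range order"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (0 <= self.lr_expressed_frac <= 1, "lr_expressed_frac in [0,1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"config: {msg}")

    def n_fact_range(self) -> range:
        return range(self.nmf_n_fact_min, self.nmf_n_fact_max + 1)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
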