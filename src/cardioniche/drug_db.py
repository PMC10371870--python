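"""Drug-target database filtering: ChEMBL-export-like tables to gene sets.

A drug-target table holds one row per (drug, target gene) bioactivity
record. Filtering keeps clinically approved (or, in preclinical mode,
phase 1-3) human drugs whose best recorded bioactivity against a target
passes a per-family potency cutoff, and emits per-drug target-gene sets
grouped by WHO ATC class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io_core import ValidationError

#: Potency cutoffs in nM per target family. pChEMBL = -log10(molar activity),
#: so a cutoff of c nM corresponds to pChEMBL >= 9 - log10(c).
FAMILY_CUTOFF_NM = {
    "kinase": 30.0,
    "gpcr": 100.0,
    "nuclear_receptor": 100.0,
    "ion_channel": 10_000.0,
    "other": 1_000.0,
}

REQUIRED_COLUMNS = [
    "drug_id", "drug_name", "max_phase", "organism",
    "target_gene", "target_family", "pchembl", "atc_codes",
]


def family_pchembl_threshold(family: str) -> float:
    """pChEMBL equivalent of the family's nM activity cutoff."""
    try:
        cutoff_nm = FAMILY_CUTOFF_NM[family]
    except KeyError:
        raise ValidationError(
            f"unknown target family {family!r}; expected one of "
            f"{sorted(FAMILY_CUTOFF_NM)}"
        ) from None
    return 9.0 - math.log10(cutoff_nm)


@dataclass
class DrugGeneSets:
    """Per-drug target-gene sets surviving the activity filter."""

    sets: dict[str, set[str]]
    drug_names: dict[str, str] = field(default_factory=dict)
    atc_codes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"empty gene set for drug {drug!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.sets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": list(self.sets),
                "drug_name": [self.drug_names.get(d, d) for d in self.sets],
                "atc_codes": [";".join(self.atc_codes.get(d, [])) for d in self.sets],
                "target_genes": [";".join(sorted(g)) for g in self.sets.values()],
            }
        )


def read_drug_table(path) -> pd.DataFrame:
    """Read a drug-target CSV (atc_codes semicolon-separated, may be empty)."""
    df = pd.read_csv(path, dtype={"atc_codes": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"drug table missing columns: {missing}")
    return df


def _parse_atc(value) -> list[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return []
    codes = [c.strip() for c in str(value).split(";")]
    return [c for c in codes if c]


def filter_drug_targets(table: pd.DataFrame, max_phase_min: int = 4,
                        organism: str = "Homo sapiens",
                        require_active: bool = True,
                        family_override: dict[str, str] | None = None,
                        ) -> DrugGeneSets:
    """Filter bioactivity records into per-drug target-gene sets.

    Keeps records matching ``organism`` with ``max_phase >= max_phase_min``;
    with ``require_active``, the best (maximum) pChEMBL per (drug, target)
    pair must meet the family threshold inclusively. Records with missing
    pChEMBL are dropped when the activity gate is on and kept otherwise.
    ``family_override`` optionally remaps target_gene -> family.
    """
    df = pd.DataFrame(table)
    if df.empty:
        warnings.warn("empty drug-target table", stacklevel=2)
        return DrugGeneSets({}, {}, {})
    df = df[(df["organism"] == organism) & (df["max_phase"] >= max_phase_min)]
    if family_override:
        df = df.assign(
            target_family=[
                family_override.get(g, f)
                for g, f in zip(df["target_gene"], df["target_family"])
            ]
        )
    if require_active:
        df = df.dropna(subset=["pchembl"])
        if not df.empty:
            # activity gate on the best recorded pChEMBL per drug-target pair
            best = df.groupby(["drug_id", "target_gene"], sort=False)["pchembl"].transform("max")
            thr = df["target_family"].map(family_pchembl_threshold)
            df = df[best >= thr]
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    atc: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        sets.setdefault(row.drug_id, set()).add(row.target_gene)
        names.setdefault(row.drug_id, row.drug_name)
        codes = _parse_atc(row.atc_codes)
        merged = atc.setdefault(row.drug_id, [])
        for c in codes:
            if c not in merged:
                merged.append(c)
    if not sets:
        warnings.warn("no drug survived filtering", stacklevel=2)
    return DrugGeneSets(sets, names, atc)


def group_by_atc(sets: DrugGeneSets, level: int = 1) -> dict[str, list[str]]:
    """Group drug ids by ATC code prefix at the given level.

    Level 1 is the anatomical main-group letter; levels 2-5 use the standard
    ATC prefix lengths (3, 4, 5, 7 characters). A drug with several codes
    appears under each distinct prefix; drugs with no code go under
    "unclassified".
    """
    prefix_len = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}[level]
    groups: dict[str, list[str]] = {}
    for drug in sets.sets:
        codes = sets.atc_codes.get(drug, [])
        prefixes = sorted({c[:prefix_len] for c in codes}) or ["unclassified"]
        for p in prefixes:
            groups.setdefault(p, []).append(drug)
    return groups
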