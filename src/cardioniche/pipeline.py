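"""End-to-end orchestration over a synthetic or user-supplied input bundle."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .io_core import normalize_log, qc_filter_cells, write_tsv
from .drug_db import filter_drug_targets, group_by_atc
from .cell_scoring import (
    correlate_genes_with_score,
    rank_sets_for_group,
    score_gene_set_mean,
    score_gene_sets,
)
from .spatial_enrichment import call_product_niche, structure_enrichment
from .niche_nmf import nmf_scan, select_factors
from .snp_enrichment import call_open_peaks, trait_state_scan
from .interactions import LRDatabase, niche_interaction_screen
from .synthetic_data import (
    SynthSpec,
    gen_drug_table,
    gen_expression,
    gen_lr_tables,
    gen_peaks_snps,
    gen_spots,
)

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, spec: SynthSpec | None = None,
                 n_perm: int | None = None, nmf_n_perm: int | None = None
                 ) -> dict:
    """Run every stage on a (by default synthetic) input bundle.

    Writes one TSV per stage plus a machine-readable ``report.json`` into
    ``config.outdir`` and returns the report. Stage seeds are derived from
    the top-level seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = SynthSpec(seed=config.seed)
    n_perm = config.n_perm if n_perm is None else n_perm
    nmf_n_perm = n_perm if nmf_n_perm is None else nmf_n_perm
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {"n_perm": n_perm, "nmf_n_perm": nmf_n_perm},
        "stages": {},
    }

    # --- expression: synth -> QC -> normalize -----------------------------
    counts, states = gen_expression(spec)
    kept = qc_filter_cells(counts, min_genes=min(config.qc_min_genes,
                                                 spec.n_genes // 2),
                           max_frac=config.qc_max_frac_cells)
    norm = normalize_log(kept)
    state_labels = states.labels.loc[kept.row_ids]
    from .io_core import Annotation

    ann = Annotation(state_labels)
    report["stages"]["qc"] = {
        "cells_in": counts.shape[0],
        "cells_kept": kept.shape[0],
        "genes": kept.shape[1],
    }

    # --- drug scoring and ranking ----------------------------------------
    table = gen_drug_table(spec)
    sets = filter_drug_targets(table, max_phase_min=config.max_phase_min,
                               organism=config.organism)
    scores = score_gene_sets(norm, sets.sets, method="mean")
    first_state = next(iter(spec.states))
    ranking = rank_sets_for_group(scores, ann, first_state,
                                  lfc_min=config.rank_lfc_min,
                                  p_adj_max=config.rank_p_adj_max)
    write_tsv(ranking, outdir / "drug_ranking.tsv")
    report["stages"]["drug"] = {
        "records_in": len(table),
        "drugs_kept": len(sets),
        "atc_groups": len(group_by_atc(sets)),
        "flagged": ranking["flagged"].sum().item(),
        "top_flagged": (
            ranking.loc[ranking["flagged"], "set"].iloc[0]
            if ranking["flagged"].any() else None
        ),
    }

    # --- spatial enrichment + product niche -------------------------------
    ab = gen_spots(spec)
    enr = pd.concat(
        [structure_enrichment(ab, s) for s in sorted(ab.structure.unique())],
        ignore_index=True,
    )
    write_tsv(enr, outdir / "structure_enrichment.tsv")
    niches = call_product_niche(ab, "FB_act", "vCM_str",
                                threshold=config.niche_product_threshold,
                                min_cluster=config.niche_min_cluster,
                                scale=config.adjacency_scale)
    niche_rows = [
        {"cluster": i, "size": n, "mean_product": m,
         "spots": ";".join(sorted(c))}
        for i, (c, n, m) in enumerate(
            zip(niches.clusters, niches.sizes, niches.mean_products))
    ]
    write_tsv(pd.DataFrame(niche_rows), outdir / "product_niche.tsv")
    report["stages"]["spatial"] = {
        "n_spots": len(ab.spot_ids),
        "structures": sorted(ab.structure.unique()),
        "niche_clusters": len(niches),
        "niche_spots": len(niches.all_spots()),
    }

    # --- NMF niche discovery ----------------------------------------------
    results = nmf_scan(ab, config.n_fact_range(), seed=config.seed)
    selection = select_factors(results,
                               ab.structure_mask(["central", "peripheral"]),
                               alpha=config.nmf_alpha,
                               proportion=config.nmf_proportion,
                               n_perm=nmf_n_perm, seed=config.seed)
    write_tsv(selection.table, outdir / "nmf_factors.tsv")
    report["stages"]["nmf"] = {
        "total_factors": sum(r.n_fact for r in results),
        "best": selection.best,
        "best_effect": None if selection.empty else selection.best_effect,
        "chosen_n_fact": selection.chosen_n_fact,
        "n_fine_factors": len(selection.fine_factors),
    }

    # --- GWAS SNP enrichment ----------------------------------------------
    pm, atac_ann, traits = gen_peaks_snps(spec)
    calls = call_open_peaks(pm, atac_ann, frac=config.open_peak_frac)
    grid = trait_state_scan(calls, traits, n_perm=n_perm, seed=config.seed)
    write_tsv(grid, outdir / "snp_enrichment.tsv")
    hit = grid[(grid["trait"] == "planted_trait")
               & (grid["state"] == spec.target_state)]
    report["stages"]["gwas"] = {
        "n_traits": len(traits),
        "n_states": len(calls.states),
        "planted_p_adj": float(hit["p_adj"].iloc[0]),
    }

    # --- ligand-receptor screen -------------------------------------------
    inter, comp = gen_lr_tables(spec)
    comp_dict = {
        r.complex_name: [m for m in (r.member_1, r.member_2)
                         if isinstance(m, str)]
        for r in comp.itertuples(index=False)
    }
    db = LRDatabase(inter, comp_dict)
    screen = niche_interaction_screen(
        norm, ann, db, list(spec.states), mode="statistical",
        frac_min=config.lr_expressed_frac, p_max=config.lr_p_max,
        n_perm=n_perm, seed=config.seed,
    )
    write_tsv(screen, outdir / "lr_screen.tsv")
    report["stages"]["lr"] = {
        "interactions": len(db),
        "pairs_tested": int(screen["passed_fraction"].sum()),
        "pairs_passed": int(screen["passed"].sum()),
    }

    # --- marker-score correlation ------------------------------------------
    markers = spec.marker_genes(first_state)
    score = score_gene_set_mean(norm, markers, set_name="planted markers")
    corr = correlate_genes_with_score(norm, score)
    write_tsv(corr, outdir / "score_correlation.tsv")
    top = corr.sort_values("pearson_r", ascending=False).head(len(markers))
    report["stages"]["correlate"] = {
        "n_genes": len(corr),
        "markers_in_top": int(top["gene"].isin(markers).sum()),
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
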