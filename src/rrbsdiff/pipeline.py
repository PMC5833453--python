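"""End-to-end orchestration: simulate -> quantify -> DMC -> DMR -> merge ->
annotate -> cluster -> report.

``run_pipeline`` chains every stage on a synthetic dataset, writes all
intermediate tables into an artifact directory, and records a manifest with
seeds, thresholds and per-stage row counts (including the coverage-gate
accounting sites_in = sites_gated + sites_dropped). Given identical config
and seed the tabular outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, annotate, cluster_report, diff_meth, meth_quant
from . import io as rio
from . import rrbs_sim, synth_genome
from .io import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineConfig"]


def _comparisons(cell_types: tuple[str, ...]) -> list[tuple[str, str]]:
    """Each later-listed cell type vs each earlier one (A = later = test)."""
    out = []
    for j in range(len(cell_types)):
        for i in range(j):
            out.append((cell_types[j], cell_types[i]))
    return out


def _slug(name: str) -> str:
    return name.replace("/", "_").replace(" ", "_")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Stage failures abort with the stage name; the partial manifest written so
    far is saved alongside the outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {k: str(v) for k, v in config.thresholds().items()},
        "stages": {},
    }
    stage = "init"
    try:
        # ---- simulate ---------------------------------------------------
        stage = "simulate"
        genome, catalogue = synth_genome.generate_genome(
            n_contigs=config.n_contigs, contig_length=config.contig_length,
            n_promoters=config.n_promoters, n_repeats=config.n_repeats,
            n_imprinted_clusters=config.n_imprinted_clusters,
            cpg_island_fraction=config.cpg_island_fraction, seed=config.seed,
            promoter_flank=config.promoter_flank,
        )
        profiles = {ct: synth_genome.default_profiles()[ct]
                    for ct in config.cell_types}
        state_map = synth_genome.assign_methylation_states(
            genome, catalogue, profiles, seed=config.seed + 1
        )
        rio.write_fasta(genome, outdir / "genome.fa")
        rio.write_bed(catalogue, outdir / "features.bed")
        rio.write_state_map(state_map, outdir / "state_map.tsv")

        fragments = rrbs_sim.digest_mspi(genome)
        retained = rrbs_sim.size_select(fragments, config.size_min,
                                        config.size_max)
        rio.write_table(rrbs_sim.fragments_to_frame(retained),
                        outdir / "fragments.tsv",
                        params={"size_min": config.size_min,
                                "size_max": config.size_max})
        sample_plan = {
            f"{ct}_rep{r + 1}": ct
            for ct in config.cell_types for r in range(config.n_replicates)
        }
        counts = rrbs_sim.simulate_counts(
            retained, state_map, mean_coverage=config.mean_coverage,
            conversion_efficiency=config.conversion_efficiency,
            replicate_dispersion=config.replicate_dispersion,
            sample_plan=sample_plan, seed=config.seed + 2,
        )
        rio.write_counts(counts, outdir / "counts.tsv",
                         params={"mean_coverage": config.mean_coverage,
                                 "conversion_efficiency":
                                     config.conversion_efficiency})
        manifest["stages"][stage] = {
            "n_cpgs_genome": int(sum(len(v) for v in
                                     synth_genome.find_cpg_sites(genome).values())),
            "n_fragments": len(fragments),
            "n_fragments_retained": len(retained),
            "n_count_records": int(len(counts)),
        }

        # ---- quantify ---------------------------------------------------
        stage = "quantify"
        wide = meth_quant.to_wide(counts)
        groups = {ct: [f"{ct}_rep{r + 1}" for r in range(config.n_replicates)]
                  for ct in config.cell_types}
        merged = meth_quant.merge_replicates(wide, groups)
        gated = meth_quant.filter_coverage(merged, min_cov=config.min_cov)
        levels = meth_quant.methylation_levels(gated)
        corr = meth_quant.sample_correlation(levels)
        fractions = meth_quant.categorize_counts(gated)
        hist = meth_quant.level_histogram(levels)
        tparams = {"min_cov": config.min_cov, "low_cut": config.low_cut,
                   "high_cut": config.high_cut}
        rio.write_table(levels.reset_index(), outdir / "levels.tsv", tparams)
        rio.write_table(corr, outdir / "correlation.tsv", tparams, index=True)
        rio.write_table(fractions.map(float).reset_index(),
                        outdir / "category_fractions.tsv", tparams)
        rio.write_table(hist, outdir / "level_histogram.tsv", tparams)
        manifest["stages"][stage] = {
            "sites_in": int(len(merged)),
            "sites_gated": int(len(gated)),
            "sites_dropped": int(len(merged) - len(gated)),
        }

        # ---- differential calls -----------------------------------------
        stage = "dmc"
        dparams = {"delta_threshold": str(config.delta_threshold),
                   "p_threshold": config.p_threshold}
        dmcs: dict[tuple[str, str], pd.DataFrame] = {}
        for a, b in _comparisons(config.cell_types):
            table = diff_meth.call_strong_dmcs(
                gated, (a, b), delta_threshold=config.delta_threshold,
                p_threshold=config.p_threshold,
            )
            dmcs[(a, b)] = table
            rio.write_table(table, outdir / f"dmcs_{_slug(a)}_vs_{_slug(b)}.tsv",
                            dparams)
        manifest["stages"][stage] = {
            f"{a}_vs_{b}": {
                "n_sites": int(len(t)),
                "n_strong_hyper": int((t["is_strong"] &
                                       (t["direction"] == "hyper")).sum()),
                "n_strong_hypo": int((t["is_strong"] &
                                      (t["direction"] == "hypo")).sum()),
            } for (a, b), t in dmcs.items()
        }

        stage = "dmr"
        rparams = dict(dparams, max_gap=config.max_gap, min_cpgs=config.min_cpgs)
        dmrs: dict[tuple[str, str], pd.DataFrame] = {}
        for key, table in dmcs.items():
            regions = diff_meth.call_dmrs(table, levels,
                                          max_gap=config.max_gap,
                                          min_cpgs=config.min_cpgs)
            dmrs[key] = regions
            a, b = key
            rio.write_table(regions,
                            outdir / f"dmrs_{_slug(a)}_vs_{_slug(b)}.tsv",
                            rparams)
        manifest["stages"][stage] = {
            f"{a}_vs_{b}": int(len(t)) for (a, b), t in dmrs.items()
        }

        # ---- cross-comparison merge & set comparisons --------------------
        stage = "merge"
        base = config.cell_types[0]
        vs_base = [k for k in dmrs if k[1] == base]
        merged_dmrs = pd.DataFrame()
        if len(vs_base) >= 2:
            merged_dmrs = diff_meth.merge_dmr_sets(
                dmrs[vs_base[0]], dmrs[vs_base[1]], levels
            )
            rio.write_table(merged_dmrs, outdir / "merged_dmrs.tsv", rparams)
        venn = None
        dmc_vs_base = [k for k in dmcs if k[1] == base]
        if len(dmc_vs_base) >= 2:
            hyper = {
                k: dmcs[k][dmcs[k]["is_strong"] &
                           (dmcs[k]["direction"] == "hyper")]
                for k in dmc_vs_base
            }
            venn = diff_meth.compare_dmc_sets(hyper[dmc_vs_base[0]],
                                              hyper[dmc_vs_base[1]])
            rio.write_table(pd.DataFrame({
                "set_a": [f"{dmc_vs_base[0][0]}_vs_{base}"],
                "set_b": [f"{dmc_vs_base[1][0]}_vs_{base}"],
                "common": [venn.counts[0]],
                "only_a": [venn.counts[1]],
                "only_b": [venn.counts[2]],
            }), outdir / "venn_strong_hyper.tsv", dparams)
            contrast = (config.cell_types[-1], config.cell_types[1]) \
                if len(config.cell_types) >= 3 else dmc_vs_base[0]
            volcano = diff_meth.volcano_table(venn.common, gated,
                                              contrast[0], contrast[1])
            rio.write_table(volcano, outdir / "volcano.tsv", dparams)
        manifest["stages"][stage] = {
            "n_merged_dmrs": int(len(merged_dmrs)),
            "venn": None if venn is None else dict(zip(
                ("common", "only_a", "only_b"), venn.counts)),
        }

        # ---- annotation --------------------------------------------------
        stage = "annotate"
        promoter_rows = catalogue.by_class("promoter")
        tss_table = pd.DataFrame({
            "gene": promoter_rows["name"],
            "chrom": promoter_rows["chrom"],
            "pos": promoter_rows["tss"] if "tss" in promoter_rows.columns
                   else (promoter_rows["start"] + promoter_rows["end"]) // 2,
            "strand": promoter_rows["strand"],
        })
        promoters = annotate.define_promoters(tss_table,
                                              genome.contig_lengths,
                                              flank=config.promoter_flank)
        promoters = annotate.classify_promoters(
            promoters, genome, window=config.window, step=config.step,
            oe_high=config.oe_high, oe_low=config.oe_low, gc_min=config.gc_min,
        )
        rio.write_table(pd.DataFrame([
            {"gene": p.gene, "chrom": p.chrom, "tss": p.tss,
             "strand": p.strand, "start": p.start, "end": p.end,
             "cpg_class": p.cpg_class,
             "best_window_offset": p.best_window[0],
             "best_window_gc": p.best_window[1],
             "best_window_oe": p.best_window[2]} for p in promoters
        ]), outdir / "promoter_classes.tsv",
            {"window": config.window, "step": config.step,
             "oe_high": config.oe_high, "oe_low": config.oe_low,
             "gc_min": config.gc_min})

        key_contrast = (config.cell_types[-1], base)
        strong = dmcs[key_contrast]
        strong = strong[strong["is_strong"]]
        locations = annotate.assign_genomic_location(strong, catalogue)
        rio.write_table(locations, outdir / "dmc_locations.tsv")
        annotated = annotate.annotate_dmrs(
            merged_dmrs if len(merged_dmrs) else dmrs[key_contrast], catalogue
        )
        rio.write_table(annotated, outdir / "annotated_dmrs.tsv")
        manifest["stages"][stage] = {
            "n_promoters": len(promoters),
            "promoter_classes": pd.Series(
                [p.cpg_class for p in promoters]).value_counts().to_dict(),
            "dmc_locations": locations["location"].value_counts().to_dict(),
            "n_promoter_dmrs": int(annotated["promoter_dmr"].sum()),
            "n_imprinted_dmrs": int(annotated["imprinted_dmr"].sum()),
        }

        # ---- clustering & report -----------------------------------------
        stage = "cluster"
        level_cols = [f"level_{ct}" for ct in config.cell_types]
        promoter_dmrs = annotated[annotated["promoter_dmr"]]
        clusters = None
        if len(promoter_dmrs) >= config.k:
            matrix = promoter_dmrs[level_cols].copy()
            matrix.index = [f"{c}:{s}-{e}" for c, s, e in zip(
                promoter_dmrs["chrom"], promoter_dmrs["start"],
                promoter_dmrs["end"])]
            clusters = cluster_report.kmeans_rows(matrix, k=config.k,
                                                  seed=config.seed)
            rio.write_table(
                clusters.labels.rename_axis("region").reset_index(),
                outdir / "promoter_dmr_clusters.tsv", {"k": config.k})
        fpkm = synth_genome.simulate_expression(catalogue, state_map,
                                                seed=config.seed + 3)
        rio.write_table(fpkm.reset_index(), outdir / "fpkm.tsv")
        zscores = cluster_report.expression_zscore(fpkm)
        rio.write_table(zscores.reset_index(), outdir / "expression_zscores.tsv")
        if len(zscores) >= 2:
            _, leaf_order = cluster_report.hierarchical_rows(zscores)
            rio.write_table(pd.DataFrame({"gene": leaf_order}),
                            outdir / "expression_leaf_order.tsv")
        stage = "report"
        tables = cluster_report.build_report_tables(
            annotated, expression_z=zscores, clusters=clusters
        )
        rio.write_table(tables["methylation"].reset_index(),
                        outdir / "heatmap_methylation.tsv")
        if "expression" in tables:
            rio.write_table(tables["expression"].reset_index(),
                            outdir / "heatmap_expression.tsv")
            rio.write_table(tables["join_report"], outdir / "join_report.tsv")
        manifest["stages"]["cluster"] = {
            "n_promoter_dmrs_clustered": 0 if clusters is None
            else int(len(clusters.labels)),
            "n_genes_expressed": int(len(zscores)),
            "n_genes_all_zero_removed": zscores.attrs.get(
                "n_all_zero_removed", 0),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
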