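"""End-to-end seeded pipeline driver.

One call wires the whole analysis together: inputs (read from files, or
generated by the synthetic module when no paths are configured) -> balanced
allocation -> preprocessing + differential abundance -> QTL scan with
permutation threshold and calls -> correlation network, DPClus clusters and
enrichment -> metabolome/phenotype integration. Every stage draws its
randomness from a child seed spawned from the single configured seed, and a
JSON manifest records the seeds, package versions and parameter echo so an
identical config reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, design, integrate, io, network, preprocess, qtl, simulate
from .io import PipelineConfig

log = logging.getLogger(__name__)

STAGES = ("simulate", "allocate", "preprocess", "rankprod", "scan",
          "threshold", "network", "cluster", "integrate")


def child_seeds(seed: int) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s % (2**31 - 1)) for stage, s in zip(STAGES, states)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and persist all outputs under ``config.output_dir``.

    Returns a dict of in-memory results keyed by stage; raises with the stage
    name on failure, leaving earlier outputs in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed)
    results: dict = {}
    manifest = {
        "package": "gggqtl",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {k: getattr(config, k) for k in sorted(config.__dataclass_fields__)},
        "outputs": [],
    }

    def emit(name, writer, *args):
        path = out / name
        writer(*args, path)
        manifest["outputs"].append(name)

    stage = "simulate"
    try:
        if config.genotypes and config.map:
            geno = io.read_genotypes(config.genotypes, config.map)
        else:
            gmap = simulate.simulate_map(config.n_chrom, config.n_markers,
                                         config.chrom_length_cm, seed=seeds["simulate"])
            geno = simulate.simulate_ril_genotypes(gmap, config.n_lines,
                                                   seed=seeds["simulate"] + 1)
            emit("genotypes.csv", lambda g, p: io.write_genotypes(g, p), geno)
            emit("map.tsv", io.write_map, geno.map)
        results["geno"] = geno

        stage = "allocate"
        alloc = design.allocate(geno, 2, n_restarts=config.n_restarts,
                                seed=seeds["allocate"])
        emit("allocation.tsv", io.write_allocation, alloc)
        results["design"] = alloc

        stage = "simulate"
        if config.metabolites:
            metab = io.read_matrix(config.metabolites, "metabolite")
            raw_scale = config.log2
        else:
            truth = simulate.default_truth_table(geno.map, config.n_metabolites,
                                                 seed=seeds["simulate"] + 2)
            metab = simulate.plant_metabolome(geno, alloc, truth,
                                              missing_rate=config.missing_rate,
                                              seed=seeds["simulate"] + 3)
            emit("truth.tsv", io.write_truth, truth)
            results["truth"] = truth
            raw_scale = False  # generator output is already log2-scale
        if config.phenotypes:
            pheno = io.read_matrix(config.phenotypes, "phenotype")
        else:
            pheno = simulate.plant_phenotypes(metab, seed=seeds["simulate"] + 4)
        results["pheno"] = pheno

        stage = "preprocess"
        metab_pp = preprocess.preprocess(metab, log2=raw_scale,
                                         z_cutoff=config.z_cutoff,
                                         impute_k=config.impute_k)
        emit("metabolites_preprocessed.tsv", io.write_matrix, metab_pp)
        results["metab"] = metab_pp

        stage = "rankprod"
        rp = preprocess.rank_product_test(metab_pp, n_perm=config.rp_n_perm,
                                          seed=seeds["rankprod"])
        anova = preprocess.anova_per_metabolite(metab_pp)
        diff = rp.table.join(anova[["F", "p", "q"]])
        emit("differential_abundance.tsv",
             lambda df, p: df.to_csv(p, sep="\t"), diff)
        results["rankprod"] = rp

        stage = "scan"
        mscan = qtl.scan(metab_pp, geno, alloc)
        emit("scan_metabolites.tsv", lambda s, p: s.to_long().to_csv(p, sep="\t", index=False), mscan)
        pscan = qtl.scan(pheno, geno, alloc)
        results["scan"] = mscan

        stage = "threshold"
        thr = qtl.permutation_threshold(metab_pp, geno, alloc,
                                        n_perm=config.n_perm, alpha=config.alpha,
                                        seed=seeds["threshold"])
        results["threshold"] = thr
        mcalls = qtl.call_qtl(mscan, thr)
        pcalls = qtl.call_qtl(pscan, thr)
        hotspots = qtl.hotspot_table(mcalls, geno.map, config.hotspot_window_cm)
        overlap = qtl.qtl_overlap(mcalls, pcalls, config.overlap_window_cm)
        emit("qtl_calls_metabolites.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), mcalls)
        emit("qtl_calls_phenotypes.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), pcalls)
        emit("hotspots.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), hotspots)
        emit("qtl_overlap.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), overlap)
        results["calls"] = mcalls

        stage = "network"
        corr = network.spearman_matrix(metab_pp)
        net = network.build_network(corr, config.corr_threshold, config.corr_fdr)
        emit("correlations.tsv", io.write_correlation_long, corr)
        emit("network_edges.tsv", io.write_edge_list, net)
        emit("network.graphml", io.write_graphml, net)
        if config.sweep:
            sweep = network.property_sweep(metab_pp.values,
                                           n_random=config.sweep_n_random,
                                           seed=seeds["network"])
            emit("network_sweep.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), sweep)
        results["network"] = net

        stage = "cluster"
        clusters = clustering.dpclus(net, config.d_in, config.cp_in, config.overlapping)
        emit("clusters.tsv", lambda c, p: c.membership().to_csv(p, sep="\t", index=False), clusters)
        if config.annotations:
            pathways = io.read_gmt(config.annotations)
        elif metab.annotations is not None:
            pathways = io.annotation_to_pathways(metab.annotations)
        else:
            pathways = {}
        if pathways:
            enr = clustering.enrich(clusters, pathways, universe=set(metab_pp.values.columns))
            emit("enrichment.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), enr)
        results["clusters"] = clusters

        stage = "integrate"
        pairwise = integrate.pairwise_trait_correlation(metab_pp, pheno)
        emit("pairwise_correlations.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), pairwise)
        cca = integrate.canonical_correlation(metab_pp.values, pheno.values.dropna(axis=1, how="any"),
                                              reduction=config.reduction)
        emit("cca_x_weights.tsv", lambda d, p: d.to_csv(p, sep="\t"), cca.x_weights)
        emit("cca_y_weights.tsv", lambda d, p: d.to_csv(p, sep="\t"), cca.y_weights)
        pls = integrate.pls_cross_validate(metab_pp.values, pheno.values.iloc[:, 0],
                                           max_components=config.pls_max_components,
                                           folds=config.pls_folds,
                                           seed=seeds["integrate"])
        emit("pls_cv.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), pls)
        results["cca"] = cca
        results["pls"] = pls
    except Exception as err:  # annotate the failing stage, keep partial outputs
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    summary = {
        "balance_score": alloc.balance_score,
        "lod_threshold": thr.threshold,
        "n_mqtl": len(mcalls),
        "n_phqtl": len(pcalls),
        "n_network_edges": net.n_edges,
        "n_clusters": len(clusters),
        "cca_rho1": float(cca.correlations[0]),
    }
    manifest["summary"] = summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
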