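"""End-to-end orchestration of the per-condition analysis.

``run_all`` reads the input bundle, calls sex bias per condition with the
moderated Welch test, and runs the downstream analyses — crosstalk, hub
ranking, inparalog concordance, and module discovery — writing every
module's TSV outputs plus a machine-readable run manifest. Conditions with
no sex-biased genes (as happens in the embryonic brain) are skipped for
the bias-dependent stages with an explicit notice.

The master seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence(master_seed).spawn``: stage *k* of condition
*c* always receives the same seed for the same master seed, so any stage
can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crosstalk import (
    DEFAULT_N_RAND,
    DEFAULT_SWAPS_PER_LINK,
    compose_bias_partition,
    crosstalk,
    write_crosstalk,
)
from .diffexpr import (
    DEFAULT_FDR_CUTOFF,
    classify_bias,
    moderated_welch,
    read_expression,
    write_de_table,
)
from .hubs import (
    DEFAULT_TOP_N,
    bias_degree_correlation,
    rank_hubs,
    write_correlations,
    write_hubs,
)
from .netmodules import (
    DEFAULT_BONFERRONI_CUTOFF,
    DEFAULT_INFLATION,
    DEFAULT_N_RAND_MODULES,
    build_subnetwork,
    clustering_significance,
    compare_clusterings,
    mcl_cluster,
    read_annotations,
    sharedneighbor_cluster,
    write_clustering,
    write_significance,
)
from .network_io import (
    DEFAULT_CUTOFF,
    degrees,
    read_chromosome_classes,
    read_network,
)
from .paralogs import (
    DEFAULT_N_REP,
    load_groups,
    resample_null,
    write_resample_null,
)

logger = logging.getLogger(__name__)

_N_STAGE_SEEDS = 8  # per condition: crosstalk, paralogs, modules(m/f), spare


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline invocation.

    Defaults: confidence cutoff 0.25, FDR cutoff 0.1, 100 crosstalk
    randomizations, 1000 paralog resampling replicates, 500 random modules,
    Bonferroni cutoff 0.1, MCL inflation 3.5, top 20 hubs.
    """

    network_path: str
    expression_path: str
    sample_meta_path: str
    groups_path: str | None = None
    chromosome_path: str | None = None
    annotations_path: str | None = None
    outdir: str = "results/pipeline"
    confidence_cutoff: float = DEFAULT_CUTOFF
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF
    n_rand_crosstalk: int = DEFAULT_N_RAND
    swaps_per_link: int = DEFAULT_SWAPS_PER_LINK
    n_rep_paralogs: int = DEFAULT_N_REP
    n_rand_modules: int = DEFAULT_N_RAND_MODULES
    bonferroni_cutoff: float = DEFAULT_BONFERRONI_CUTOFF
    inflation: float = DEFAULT_INFLATION
    top_n_hubs: int = DEFAULT_TOP_N
    #: a condition with fewer sex-biased genes than this (like the
    #: embryonic brain) is excluded from crosstalk and module discovery
    min_biased_genes: int = 10
    master_seed: int = 0


def stage_seeds(master_seed: int, condition_index: int) -> list[int]:
    """Deterministic per-stage seeds for one condition."""
    children = np.random.SeedSequence(master_seed).spawn(condition_index + 1)
    grand = children[condition_index].spawn(_N_STAGE_SEEDS)
    return [int(s.generate_state(1)[0] % (2**31)) for s in grand]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    On any stage failure, partially written outputs are removed and the
    error is re-raised with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "read inputs"
        network = read_network(config.network_path, cutoff=config.confidence_cutoff)
        matrix = read_expression(config.expression_path, config.sample_meta_path)
        chrom = (
            read_chromosome_classes(config.chromosome_path)
            if config.chromosome_path
            else None
        )
        annot = (
            read_annotations(config.annotations_path)
            if config.annotations_path
            else None
        )
        groups = (
            load_groups(config.groups_path, set(matrix.genes))
            if config.groups_path
            else None
        )
        deg = degrees(network)

        manifest: dict = {
            "biasnet_version": __version__,
            "config": asdict(config),
            "conditions": {},
            "notices": [],
        }

        for ci, condition in enumerate(matrix.conditions()):
            cname = "_".join(condition)
            seeds = stage_seeds(config.master_seed, ci)
            cond_info: dict = {"seeds": seeds}

            stage = f"diffexpr [{cname}]"
            de = moderated_welch(matrix, condition, fdr_cutoff=config.fdr_cutoff)
            bias = classify_bias(de, fdr_cutoff=config.fdr_cutoff)
            write_de_table(de, bias, outdir / f"de_{cname}.tsv")
            counts = bias.counts()
            cond_info["bias_counts"] = counts
            cond_info["d0"] = de.d0

            n_biased = counts["male"] + counts["female"]
            if n_biased < config.min_biased_genes:
                msg = (
                    f"condition {cname}: only {n_biased} sex-biased genes at "
                    f"FDR < {config.fdr_cutoff} (minimum "
                    f"{config.min_biased_genes}); crosstalk and module "
                    "discovery skipped"
                )
                logger.warning(msg)
                manifest["notices"].append(msg)
                manifest["conditions"][cname] = cond_info
                continue

            stage = f"crosstalk [{cname}]"
            partition = compose_bias_partition(bias, chrom)
            partition = {g: l for g, l in partition.items() if g in network.genes}
            ct = crosstalk(
                network,
                partition,
                n_rand=config.n_rand_crosstalk,
                seed=seeds[0],
                swaps_per_link=config.swaps_per_link,
            )
            write_crosstalk(ct, outdir / f"crosstalk_{cname}.tsv")

            stage = f"hubs [{cname}]"
            corr = bias_degree_correlation(de, deg, bias)
            write_correlations(corr, outdir / f"correlation_{cname}.tsv")
            hubs_table = rank_hubs(de, deg, top_n=config.top_n_hubs)
            write_hubs(hubs_table, outdir / f"hubs_{cname}.tsv")

            if groups is not None and groups.groups:
                stage = f"paralogs [{cname}]"
                null = resample_null(
                    groups, bias, n_rep=config.n_rep_paralogs, seed=seeds[1]
                )
                write_resample_null(null, outdir / f"paralogs_{cname}.tsv")

            if annot is not None:
                stage = f"netmodules [{cname}]"
                for si, sex in enumerate(("male", "female")):
                    if counts[sex] == 0:
                        manifest["notices"].append(
                            f"condition {cname}: no {sex}-biased genes; "
                            f"{sex} module discovery skipped"
                        )
                        continue
                    sub = build_subnetwork(
                        network, bias, sex, config.bonferroni_cutoff
                    )
                    mcl = mcl_cluster(sub, inflation=config.inflation)
                    sn = sharedneighbor_cluster(sub)
                    write_clustering(
                        mcl, bias, outdir / f"modules_{cname}_{sex}_mcl.tsv"
                    )
                    write_clustering(
                        sn, bias, outdir / f"modules_{cname}_{sex}_mgclus_like.tsv"
                    )
                    sigs = []
                    for clu in (mcl, sn):
                        if clu.clusters:
                            sigs.append(
                                clustering_significance(
                                    clu,
                                    sub,
                                    annot,
                                    n_rand=config.n_rand_modules,
                                    seed=seeds[2 + si],
                                )
                            )
                    if sigs:
                        write_significance(
                            sigs, outdir / f"significance_{cname}_{sex}.tsv"
                        )
                    if mcl.clusters and sn.clusters:
                        cmp_ = compare_clusterings(
                            mcl, sn, annot, background=set(sub.genes)
                        )
                        (outdir / f"upgma_genes_{cname}_{sex}.nwk").write_text(
                            cmp_.gene_tree.newick + "\n"
                        )
                        (outdir / f"upgma_terms_{cname}_{sex}.nwk").write_text(
                            cmp_.term_tree.newick + "\n"
                        )
                    cond_info[f"subnetwork_{sex}"] = {
                        "seed_genes": len(sub.seed_genes),
                        "recruited": len(sub.recruited_genes),
                        "mcl_clusters": len(mcl.clusters),
                        "mgclus_like_clusters": len(sn.clusters),
                    }

            manifest["conditions"][cname] = cond_info

        stage = "manifest"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
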