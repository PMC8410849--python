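"""End-to-end orchestration of the compartmentalization analysis.

``run_pipeline`` composes the stages — synthetic data generation (or file
inputs), conservation statistics, expression normalization, contact-map
construction and normalization, frontier-index boundary calling and the
dispersion index — and writes a result bundle (TSV tables, BED/bedGraph
tracks, a JSON summary) into an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import contacts, conservation, expression, frontiers, io, synthdata
from .genome import genes_to_frame

logger = logging.getLogger("strepfold")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (all stages on synthetic inputs)."""

    out_dir: str = "strepfold_run"
    seed: int = 0
    bin_size: int = 10_000
    n_bins: int = 670
    n_genes: int = 2000
    n_genomes: int = 8
    alpha: float = 1.0
    boundary_strength: float = 3.0
    boundary_spacing: int = 40
    arm_noise_mult: float = 3.0
    n_pairs: int = 2_000_000
    max_dist_bp: int = 600_000
    thresh_mult: float = 2.0
    cat_thresholds: list | None = None

    def validate(self) -> None:
        missing = [k for k, v in asdict(self).items() if v is None
                   and k != "cat_thresholds"]
        if missing:
            raise ValueError(f"missing config fields: {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on a seeded synthetic bundle; return the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2))
    rng_seed = int(config.seed)

    logger.info("stage 1/4: genome + conservation")
    genes, partition = synthdata.synth_genome(
        n_genes=config.n_genes, seed=rng_seed
    )
    genes_to_frame(genes).to_csv(out / "genes.tsv", sep="\t", index=False)
    otable, _ = synthdata.synth_orthologs(
        genes, partition, n_genomes=config.n_genomes, seed=rng_seed + 1
    )
    pers = conservation.compute_persistence(otable)
    pers.to_csv(out / "persistence.tsv", sep="\t", index=False)
    goc = conservation.compute_goc_profile(otable, "genome_0")
    goc.to_csv(out / "goc.tsv", sep="\t", index=False)
    blocks = {
        g: conservation.detect_synteny_blocks(otable, g)
        for g in otable.presence
    }
    islands = conservation.call_genomic_islands(blocks, genes, otable)
    io.write_bed(
        [(i.start_bp, i.end_bp) for i in islands if not i.is_insertion_point],
        out / "islands.bed",
    )
    enrich = conservation.fisher_enrichment("SMBGC", partition, genes)

    logger.info("stage 2/4: expression")
    raw_s, raw_a, reps = synthdata.synth_counts(
        genes, partition, seed=rng_seed + 2
    )
    eset = expression.ExpressionSet(
        raw_sense=raw_s,
        raw_antisense=raw_a,
        replicates=reps,
        gene_lengths=genes_to_frame(genes).set_index("gene_id")["length"],
        excluded={g.gene_id for g in genes if "rRNA" in g.features},
    )
    expr = eset.analyse(config.cat_thresholds)
    expr["normRPK"].to_csv(out / "normrpk.tsv", sep="\t")
    expr["as_index"].to_csv(out / "as_index.tsv", sep="\t")

    logger.info("stage 3/4: contact map + SCN")
    boundaries_true = list(
        range(config.boundary_spacing, config.n_bins, config.boundary_spacing)
    )
    cmap_raw, truth = synthdata.synth_contact_map(
        n_bins=config.n_bins,
        alpha=config.alpha,
        boundaries=boundaries_true,
        boundary_strength=config.boundary_strength,
        arm_noise_mult=config.arm_noise_mult,
        n_pairs=config.n_pairs,
        bin_size=config.bin_size,
        seed=rng_seed + 3,
    )
    masked = contacts.mask_low_coverage(cmap_raw)
    cmap = contacts.scn_normalize(masked)
    io.write_matrix_tsv(cmap, out / "matrix_scn.tsv")
    regions = synthdata.truth_regions(truth)
    disp = contacts.long_range_dispersion(cmap_raw, regions)
    rows = []
    for name, region in regions.items():
        d = contacts.dispersion_index(contacts.contact_probability(cmap_raw, region))
        d.insert(0, "region", name)
        rows.append(d)
    import pandas as pd

    pd.concat(rows).to_csv(out / "dispersion.tsv", sep="\t", index=False)

    logger.info("stage 4/4: frontier index")
    bin_partition = _bin_partition(truth, config.bin_size)
    result = frontiers.call_frontiers(
        cmap, bin_partition, config.max_dist_bp, config.thresh_mult
    )
    io.write_bedgraph(result.fi_up, config.bin_size, out / "fi_up.bedgraph")
    io.write_bedgraph(result.fi_down, config.bin_size, out / "fi_down.bedgraph")
    io.write_boundaries_bed(result.boundaries, config.bin_size, out / "boundaries.bed")
    domains = frontiers.segment_domains(result.boundaries, config.bin_size)
    domains.to_csv(out / "domains.tsv", sep="\t", index=False)

    per_comp = {
        name: sum(
            1 for b in result.boundaries if lo <= b.position <= hi
        )
        for name, (lo, hi) in truth.compartment_bins.items()
    }
    summary = {
        "seed": rng_seed,
        "n_boundaries": len(result.boundaries),
        "boundaries_per_compartment": per_comp,
        "n_planted_boundaries": len(truth.boundaries),
        "domain_size_range_kb": (
            [float(domains["size_kb"].min()), float(domains["size_kb"].max())]
            if len(domains)
            else None
        ),
        "dispersion_long_range": disp,
        "dispersion_arm_center_ratio": (
            0.5 * (disp["left"] + disp["right"]) / disp["central"]
            if disp.get("central")
            else None
        ),
        "smbgc_arm_enrichment_odds_ratio": enrich["odds_ratio"],
        "smbgc_arm_enrichment_p": enrich["p_value"],
        "n_genomic_islands": sum(1 for i in islands if not i.is_insertion_point),
        "n_switch_genes": int(expr["switch"].sum()),
        "mean_as_index_arm_exponential": _mean_as(expr["as_index"], genes,
                                                  partition, "C1"),
        "mean_as_index_arm_stationary": _mean_as(expr["as_index"], genes,
                                                 partition, "C4"),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return summary


def _bin_partition(truth: synthdata.SyntheticTruth, bin_size: int):
    from .genome import CompartmentPartition

    lo, hi = truth.compartment_bins["central"]
    n_bins = truth.compartment_bins["right"][1] + 1
    return CompartmentPartition(
        chrom_length=n_bins * bin_size,
        first_rdna_start=lo * bin_size + 1,
        last_rdna_end=(hi + 1) * bin_size,
    )


def _mean_as(as_index, genes, partition, cond) -> float:
    arm_ids = [
        g.gene_id for g in genes
        if partition.compartment(int(g.midpoint)) != "central"
    ]
    vals = as_index.reindex(arm_ids)[cond]
    return float(np.nanmean(vals.to_numpy(dtype=float)))
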