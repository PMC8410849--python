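"""Synthetic data generators with ground truth.

Each generator emulates one layer of the compartmentalized linear
chromosome the pipeline analyses, returning the planted truth alongside
the data so every downstream stage can be validated without external
downloads:

* :func:`synth_genome` — genes tiling a linear chromosome whose central
  region is enriched in core genes while SMBGCs and genomic islands
  concentrate in the terminal arms;
* :func:`synth_orthologs` — per-genome ortholog presence with
  compartment-specific persistence and locally co-linear target order,
  with planted island gaps;
* :func:`synth_counts` — stranded negative-binomial counts with
  compartment- and growth-phase-dependent means (arms quiescent early,
  induced late) and binomially split antisense reads;
* :func:`synth_contact_map` — 10-kb contact maps with power-law distance
  decay, planted domain blocks, an optional tilted secondary (inter-arm)
  diagonal and inflated multiplicative noise in the arms.

All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .conservation import OrthologTable
from .genome import CompartmentPartition, GeneRecord

# default chromosome layout: ~6.7 Mb TIR-trimmed linear chromosome with the
# outermost rDNA operons at ~1.47 Mb and ~5.80 Mb (printed coordinates)
DEFAULT_CHROM_LENGTH = 6_700_000
DEFAULT_FIRST_RDNA = (1_469_670, 1_474_823)
DEFAULT_LAST_RDNA = (5_802_471, 5_807_629)
DEFAULT_ORIC = 3_600_000


@dataclass
class SyntheticTruth:
    """Ground truth underlying one synthetic contact map."""

    boundaries: list[int]
    compartment_bins: dict[str, tuple[int, int]]
    alpha: float
    boundary_strength: float
    secondary_diag_weight: float
    secondary_diag_tilt: int
    arm_noise_mult: float
    n_pairs: int
    seed: int
    extra: dict = field(default_factory=dict)


def default_partition(chrom_length: int = DEFAULT_CHROM_LENGTH) -> CompartmentPartition:
    return CompartmentPartition(
        chrom_length=chrom_length,
        first_rdna_start=DEFAULT_FIRST_RDNA[0],
        last_rdna_end=DEFAULT_LAST_RDNA[1],
        oriC_pos=DEFAULT_ORIC,
    )


def synth_genome(
    n_genes: int = 2000,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    rdna_positions: tuple[tuple[int, int], tuple[int, int]] = (
        DEFAULT_FIRST_RDNA,
        DEFAULT_LAST_RDNA,
    ),
    seed: int = 0,
    feature_probs: dict[str, dict[str, float]] | None = None,
    mean_gene_length: int = 1000,
) -> tuple[list[GeneRecord], CompartmentPartition]:
    """Genes tiling a linear chromosome with compartment-dependent features.

    ``feature_probs[label][compartment]`` gives the probability that a gene
    in that compartment carries the label.  Defaults follow the study's
    qualitative layout: core genes concentrate in the central region;
    SMBGCs and GIs in the arms.
    """
    (r1s, r1e), (r2s, r2e) = rdna_positions
    if not (1 <= r1s <= r1e < r2s <= r2e <= chrom_length):
        raise ValueError("rDNA operons must lie ordered inside the chromosome")
    partition = CompartmentPartition(chrom_length, r1s, r2e, DEFAULT_ORIC)
    if feature_probs is None:
        feature_probs = {
            "core": {"left": 0.15, "central": 0.80, "right": 0.15},
            "SMBGC": {"left": 0.25, "central": 0.02, "right": 0.25},
            "GI": {"left": 0.15, "central": 0.01, "right": 0.15},
            "tRNA": {"left": 0.01, "central": 0.02, "right": 0.01},
        }
    genes: list[GeneRecord] = []
    if n_genes == 0:
        return genes, partition
    if n_genes * (mean_gene_length // 2) > chrom_length:
        raise ValueError("infeasible gene density for chromosome length")
    rng = np.random.default_rng(seed)
    # genes tile the chromosome: draw lengths, scale spacing to fit
    lengths = rng.integers(mean_gene_length // 2, mean_gene_length * 3 // 2 + 1,
                           size=n_genes)
    gap = max(1, (chrom_length - int(lengths.sum())) // (n_genes + 1))
    pos = 1
    for i, ln in enumerate(lengths):
        start = pos + gap
        end = min(start + int(ln) - 1, chrom_length)
        if start > chrom_length:
            break
        comp = partition.compartment(min((start + end) // 2, chrom_length))
        feats = {
            label for label, probs in feature_probs.items()
            if rng.random() < probs.get(comp, 0.0)
        }
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"SYN_{i:05d}", start, end, strand, feats))
        pos = end
    return genes, partition


def synth_orthologs(
    genes: list[GeneRecord],
    partition: CompartmentPartition,
    n_genomes: int = 8,
    persistence_by_compartment: dict[str, float] | None = None,
    island_spec: list[dict] | None = None,
    seed: int = 0,
) -> tuple[OrthologTable, list[dict]]:
    """Ortholog table with compartment-specific persistence and planted gaps.

    ``island_spec`` entries: ``{"ref_start": gene index, "n_cds": int,
    "side": "reference" | "target"}``.  Reference-side islands are blocks
    of reference genes absent from every target genome (a horizontal
    acquisition of the reference); target-side islands insert ``n_cds``
    extra genes into every target at the given reference position
    (an insertion point for the reference).  Away from islands the target
    gene order is co-linear with the reference.
    """
    if persistence_by_compartment is None:
        persistence_by_compartment = {"left": 0.35, "central": 0.92, "right": 0.35}
    for v in persistence_by_compartment.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("persistence parameters must be in [0, 1]")
    island_spec = island_spec or []
    g = len(genes)
    for isl in island_spec:
        if isl["ref_start"] + isl.get("n_cds", 0) > g and isl["side"] == "reference":
            raise ValueError("island exceeds genome")
    ref_island = np.zeros(g, dtype=bool)
    for isl in island_spec:
        if isl["side"] == "reference":
            ref_island[isl["ref_start"]: isl["ref_start"] + isl["n_cds"]] = True

    rng = np.random.default_rng(seed)
    table = OrthologTable(gene_ids=[gn.gene_id for gn in genes])
    comp = np.array([partition.compartment(int(gn.midpoint)) for gn in genes])
    p_gene = np.array([persistence_by_compartment[c] for c in comp])
    for k in range(n_genomes):
        present = (rng.random(g) < p_gene) & ~ref_island
        # co-linear target order with target-side insertions shifting indices
        shift = np.zeros(g, dtype=np.int64)
        for isl in island_spec:
            if isl["side"] == "target":
                shift[isl["ref_start"]:] += isl["n_cds"]
        tpos = np.cumsum(present) - 1 + shift
        mapping = {int(i): int(tpos[i]) for i in np.flatnonzero(present)}
        table.add_genome(f"genome_{k}", mapping)
    truth = [dict(isl) for isl in island_spec]
    return table, truth


def synth_counts(
    genes: list[GeneRecord],
    partition: CompartmentPartition,
    conditions: dict[str, tuple[str, int]] | None = None,
    mean_expression: dict[str, dict[str, float]] | None = None,
    antisense_fraction: dict[str, dict[str, float]] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Stranded count matrices with compartment/phase structure.

    ``conditions`` maps a condition label to (growth phase, n replicates);
    ``mean_expression[phase][compartment]`` is the mean total read count per
    gene; ``antisense_fraction[phase][compartment]`` the expected fraction
    of antisense reads.  Totals are negative-binomial (gamma-mixed Poisson
    with squared coefficient of variation ``dispersion``); each gene's reads
    are split binomially between antisense and sense.

    Returns (raw_sense, raw_antisense, replicates).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if conditions is None:
        conditions = {"C1": ("exponential", 3), "C4": ("stationary", 3),
                      "C6": ("exponential", 3)}
    if mean_expression is None:
        mean_expression = {
            "exponential": {"left": 0.5, "central": 300.0, "right": 0.5},
            "stationary": {"left": 200.0, "central": 250.0, "right": 200.0},
        }
    if antisense_fraction is None:
        antisense_fraction = {
            "exponential": {"left": 0.35, "central": 0.03, "right": 0.35},
            "stationary": {"left": 0.10, "central": 0.03, "right": 0.10},
        }
    rng = np.random.default_rng(seed)
    comp = [partition.compartment(int(g.midpoint)) for g in genes]
    gene_ids = [g.gene_id for g in genes]
    # fixed per-gene relative activity so replicates are correlated
    activity = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
    sense, anti, replicates = {}, {}, {}
    for cond, (phase, n_rep) in conditions.items():
        replicates[cond] = []
        mu = np.array([mean_expression[phase][c] for c in comp]) * activity
        frac = np.array([antisense_fraction[phase][c] for c in comp])
        for r in range(n_rep):
            name = f"{cond}_rep{r + 1}"
            replicates[cond].append(name)
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
            total = rng.poisson(lam)
            a = rng.binomial(total, frac)
            anti[name] = a
            sense[name] = total - a
    raw_sense = pd.DataFrame(sense, index=gene_ids)
    raw_anti = pd.DataFrame(anti, index=gene_ids)
    return raw_sense, raw_anti, replicates


def synth_contact_map(
    n_bins: int = 670,
    alpha: float = 1.0,
    boundaries: list[int] | None = None,
    boundary_strength: float = 3.0,
    secondary_diag_weight: float = 0.0,
    secondary_diag_tilt: int = 0,
    secondary_diag_sigma: float = 3.0,
    arm_noise_mult: float = 1.0,
    arm_bins: tuple[int, int] | None = None,
    n_pairs: int = 2_000_000,
    bin_size: int = 10_000,
    seed: int = 0,
) -> tuple[ContactMap, SyntheticTruth]:
    """Raw Poisson-sampled contact map with planted structure.

    The contact intensity decays as ``(s + 1)^-alpha`` with genomic
    separation ``s`` (bins); pairs within a planted domain (the interval
    between consecutive boundaries) are ``boundary_strength`` times more
    frequent; a secondary anti-diagonal of Gaussian cross-section can be
    added at ``j = n - 1 - i + tilt`` to mimic inter-arm contacts; entries
    with both ends in a terminal arm (outside ``arm_bins = (left_end,
    right_start)``) receive multiplicative gamma noise with unit mean and
    variance ``arm_noise_mult - 1``, inflating their dispersion index.
    Counts are Poisson with total intensity ``n_pairs``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if arm_bins is None:
        # rDNA-delimited layout of the reference chromosome: left arm ends at
        # ~22% of the length, right arm starts at ~87% (670-bin map: 147/580)
        arm_bins = (int(round(0.22 * n_bins)), int(round(0.866 * n_bins)))
    boundaries = sorted(boundaries or [])
    if boundaries and (boundaries[0] < 0 or boundaries[-1] >= n_bins):
        raise ValueError("boundaries must lie inside the map")
    rng = np.random.default_rng(seed)

    idx = np.arange(n_bins)
    s = np.abs(idx[:, None] - idx[None, :])
    lam = (s + 1.0) ** (-alpha)

    # planted blocks: same-domain pairs are boundary_strength x more frequent
    edges = [0] + boundaries + [n_bins]
    domain = np.empty(n_bins, dtype=int)
    for d, (a, b) in enumerate(zip(edges, edges[1:])):
        domain[a:b] = d
    same = domain[:, None] == domain[None, :]
    lam = np.where(same, lam * boundary_strength, lam)

    if secondary_diag_weight > 0:
        dist = np.abs(idx[:, None] + idx[None, :] - (n_bins - 1) - secondary_diag_tilt)
        lam = lam + secondary_diag_weight * lam.max() * np.exp(
            -0.5 * (dist / secondary_diag_sigma) ** 2
        )

    left_end, right_start = arm_bins
    arm = (idx < left_end) | (idx >= right_start)
    both_arm = arm[:, None] & arm[None, :]
    if arm_noise_mult > 1.0:
        var = arm_noise_mult - 1.0
        noise = rng.gamma(shape=1.0 / var, scale=var, size=lam.shape)
        noise = np.triu(noise) + np.triu(noise, 1).T  # symmetric noise field
        lam = np.where(both_arm, lam * noise, lam)

    upper = np.triu(lam)
    lam_scaled = lam * (n_pairs / upper.sum())
    counts = rng.poisson(np.triu(lam_scaled))
    mat = counts + np.triu(counts, 1).T

    truth = SyntheticTruth(
        boundaries=list(boundaries),
        compartment_bins={
            "left": (0, left_end - 1),
            "central": (left_end, right_start - 1),
            "right": (right_start, n_bins - 1),
        },
        alpha=alpha,
        boundary_strength=boundary_strength,
        secondary_diag_weight=secondary_diag_weight,
        secondary_diag_tilt=secondary_diag_tilt,
        arm_noise_mult=arm_noise_mult,
        n_pairs=n_pairs,
        seed=seed,
    )
    return ContactMap(mat.astype(float), bin_size=bin_size, state="raw"), truth


def truth_regions(truth: SyntheticTruth) -> dict[str, np.ndarray]:
    """Bin-index arrays of the planted compartments."""
    return {
        name: np.arange(lo, hi + 1)
        for name, (lo, hi) in truth.compartment_bins.items()
    }
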