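"""Orthology, persistence, gene-order conservation and genomic islands.

This module quantifies the genetic compartmentalization of a reference
chromosome against a panel of related genomes:

* reciprocal-best-hit (RBH) orthologs from pairwise protein homology searches;
* the persistence index ``N_orth / N`` (fraction of surveyed genomes carrying
  an ortholog of a gene);
* the gene-order-conservation (GOC) index in a sliding window of 8 CDSs
  (step 1): the number of orthologs participating in conserved adjacencies
  over the number of orthologs in the window;
* synteny blocks and genomic islands (GIs): a GI is the gap between two
  consecutive same-direction synteny blocks containing at least 15 CDSs in
  one of the two genomes;
* two-sided Fisher enrichment of gene features in chromosome compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CompartmentPartition, GeneRecord

BLAST_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass
class OrthologTable:
    """Per-genome ortholog presence and target positions for a reference.

    ``presence[genome]`` is a boolean array over reference gene indices;
    ``target_index[genome]`` holds the 0-based gene index of the ortholog in
    the target genome (-1 when absent).  The mapping is one-to-one within
    each genome (reciprocal best hits).
    """

    gene_ids: list[str]
    presence: dict[str, np.ndarray] = field(default_factory=dict)
    target_index: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.presence)

    def add_genome(self, name: str, mapping: dict[int, int]) -> None:
        """Register one target genome from {ref_index: target_index} pairs."""
        tgt = np.asarray(list(mapping.values()))
        if len(set(tgt.tolist())) != len(tgt):
            raise ValueError(f"genome {name}: ortholog mapping is not one-to-one")
        pres = np.zeros(self.n_genes, dtype=bool)
        tidx = np.full(self.n_genes, -1, dtype=np.int64)
        for r, t in mapping.items():
            pres[r] = True
            tidx[r] = t
        self.presence[name] = pres
        self.target_index[name] = tidx

    def n_orth(self) -> np.ndarray:
        """Per-gene count of genomes carrying an ortholog."""
        if not self.presence:
            return np.zeros(self.n_genes, dtype=np.int64)
        return np.sum([p for p in self.presence.values()], axis=0).astype(np.int64)


@dataclass(frozen=True)
class SyntenyBlock:
    """Maximal co-linear run shared by the reference and one target genome."""

    ref_start: int  # reference gene indices, inclusive
    ref_end: int
    tgt_start: int  # target gene indices at the matching run ends
    tgt_end: int
    direction: str  # 'same' or 'inverted'

    @property
    def n_genes(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass
class GenomicIsland:
    """Synteny-break region called as a genomic island on the reference."""

    ref_gene_start: int  # reference gene indices of break content, inclusive
    ref_gene_end: int
    start_bp: int
    end_bp: int
    supporting: list[str] = field(default_factory=list)
    cds_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    is_insertion_point: bool = False


def read_blast_hits(path) -> pd.DataFrame:
    """Read 12-column tabular homology hits (BLAST ``-outfmt 6``)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS)
    _validate_hits(df)
    return df


def _validate_hits(df: pd.DataFrame) -> None:
    for col in ("pident", "length", "evalue", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"malformed hit row {row}: non-numeric {col!r}")


def _best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: highest bitscore, then lowest E-value, then
    lexicographically smallest subject (deterministic tie-break)."""
    best: dict[str, tuple[float, float, str]] = {}
    for row in hits.itertuples(index=False):
        key = (-float(row.bitscore), float(row.evalue), str(row.subject))
        q = str(row.query)
        if q not in best or key < best[q]:
            best[q] = key
    return {q: key[2] for q, key in best.items()}


def reciprocal_best_hits(
    hits_forward: pd.DataFrame,
    hits_reverse: pd.DataFrame,
    min_identity: float = 40.0,
    min_coverage: float = 0.70,
    max_evalue: float = 1e-10,
    query_lengths: dict[str, int] | None = None,
    subject_lengths: dict[str, int] | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs passing identity / coverage / E-value.

    Thresholds follow the standard orthology protocol: at least 40% identity,
    70% coverage and E-value below 1e-10 in both directions.  Coverage is
    alignment length over query length; it is only enforced when the relevant
    length table is supplied (the 12-column hit format does not carry sequence
    lengths).

    Returns sorted (reference_gene, target_gene) pairs; the mapping is
    one-to-one by construction.
    """
    _validate_hits(hits_forward)
    _validate_hits(hits_reverse)

    def passes(row, lengths) -> bool:
        if float(row.pident) < min_identity:
            return False
        if float(row.evalue) > max_evalue:
            return False
        if lengths is not None:
            qlen = lengths.get(str(row.query))
            if qlen is None or float(row.length) / qlen < min_coverage:
                return False
        return True

    fwd_ok = hits_forward[
        [passes(r, query_lengths) for r in hits_forward.itertuples(index=False)]
    ]
    rev_ok = hits_reverse[
        [passes(r, subject_lengths) for r in hits_reverse.itertuples(index=False)]
    ]
    fwd_best = _best_hits(fwd_ok)
    rev_best = _best_hits(rev_ok)
    pairs = [
        (q, s) for q, s in fwd_best.items() if rev_best.get(s) == q
    ]
    return sorted(pairs)


def compute_persistence(table: OrthologTable) -> pd.DataFrame:
    """Persistence index ``N_orth / N`` per reference gene.

    Genes with persistence > 0.95 are flagged as highly persistent
    (the conserved-backbone track).
    """
    n = table.n_genomes
    if n == 0:
        raise ValueError("persistence requires at least one target genome (N >= 1)")
    n_orth = table.n_orth()
    persistence = n_orth / n
    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "N_orth": n_orth,
            "N": n,
            "persistence": persistence,
            "persistent_95": persistence > 0.95,
        }
    )


def compute_goc_profile(
    table: OrthologTable,
    target_genome: str,
    window: int = 8,
    step: int = 1,
) -> pd.DataFrame:
    """Gene-order-conservation profile against one target genome.

    For each sliding window of ``window`` reference CDSs (step ``step``):
    the denominator is the number of window genes carrying an ortholog; the
    numerator is the number of those genes participating in a conserved
    adjacency, i.e. belonging to a run of >= 2 genes at consecutive reference
    indices whose target indices are also consecutive (|delta| = 1).  Windows
    with no ortholog at all get GOC = NA; a lone ortholog gives 0.
    """
    if window < 2:
        raise ValueError("window must be >= 2 genes")
    g = table.n_genes
    if window > g:
        raise ValueError(f"window {window} exceeds gene count {g}")
    tidx = table.target_index[target_genome]
    pres = table.presence[target_genome]

    # conserved adjacency between reference neighbours i and i+1
    adj = np.zeros(g - 1, dtype=bool)
    both = pres[:-1] & pres[1:]
    adj[both] = np.abs(tidx[1:][both] - tidx[:-1][both]) == 1

    starts = list(range(0, g - window + 1, step))
    goc = np.full(len(starts), np.nan)
    denom = np.zeros(len(starts), dtype=np.int64)
    numer = np.zeros(len(starts), dtype=np.int64)
    for w, s in enumerate(starts):
        e = s + window  # exclusive
        d = int(pres[s:e].sum())
        denom[w] = d
        if d == 0:
            continue
        in_run = np.zeros(window, dtype=bool)
        for k in range(window - 1):
            if adj[s + k]:
                in_run[k] = True
                in_run[k + 1] = True
        numer[w] = int(in_run.sum())
        goc[w] = numer[w] / d
    return pd.DataFrame(
        {
            "window_start": starts,
            "n_orthologs": denom,
            "n_contiguous": numer,
            "goc": goc,
        }
    )


def detect_synteny_blocks(
    table: OrthologTable, target_genome: str, min_block: int = 2
) -> list[SyntenyBlock]:
    """Maximal co-linear runs between reference and one target genome.

    A block extends while successive ortholog-bearing reference genes are at
    strictly consecutive reference indices AND their target indices step by
    exactly +-1 in a fixed direction.  Runs shorter than ``min_block`` genes
    are discarded.
    """
    pres = table.presence[target_genome]
    tidx = table.target_index[target_genome]
    orth = np.flatnonzero(pres)
    blocks: list[SyntenyBlock] = []
    if len(orth) == 0:
        return blocks

    run_start = orth[0]
    prev = orth[0]
    direction = 0  # 0 unknown, +1 same, -1 inverted

    def flush(run_start: int, run_end: int, direction: int) -> None:
        n = run_end - run_start + 1
        if n >= min_block:
            blocks.append(
                SyntenyBlock(
                    ref_start=int(run_start),
                    ref_end=int(run_end),
                    tgt_start=int(tidx[run_start]),
                    tgt_end=int(tidx[run_end]),
                    direction="inverted" if direction < 0 else "same",
                )
            )

    for i in orth[1:]:
        step_ref = i - prev
        step_tgt = int(tidx[i] - tidx[prev])
        if step_ref == 1 and abs(step_tgt) == 1 and (
            direction == 0 or step_tgt == direction
        ):
            direction = step_tgt
            prev = i
            continue
        flush(run_start, prev, direction)
        run_start = i
        prev = i
        direction = 0
    flush(run_start, prev, direction)
    return blocks


def call_genomic_islands(
    blocks_by_genome: dict[str, list[SyntenyBlock]],
    genes: list[GeneRecord],
    table: OrthologTable,
    min_cds: int = 15,
) -> list[GenomicIsland]:
    """Call genomic islands from synteny breaks across pairwise comparisons.

    A break is the region between two consecutive same-direction synteny
    blocks.  It is a GI when at least ``min_cds`` CDSs lie within the break
    in at least one of the two genomes.  When the reference side carries
    fewer than 2 CDSs (or only tRNAs) while the target carries >= min_cds,
    the locus is recorded as an insertion point, not a GI.  GIs supported by
    several comparisons and overlapping are fused into a single island.
    """
    raw: list[GenomicIsland] = []
    for name, blocks in blocks_by_genome.items():
        ordered = sorted(blocks, key=lambda b: b.ref_start)
        tidx = table.target_index[name]
        for up, down in zip(ordered, ordered[1:]):
            if up.direction != down.direction:
                continue  # breaks only between same-direction blocks
            ref_lo, ref_hi = up.ref_end + 1, down.ref_start - 1
            ref_cds = max(0, ref_hi - ref_lo + 1)
            t_ends = sorted(
                [up.tgt_start, up.tgt_end, down.tgt_start, down.tgt_end]
            )
            # target genes strictly between the two blocks' facing ends
            tgt_cds = max(0, t_ends[2] - t_ends[1] - 1)
            if max(ref_cds, tgt_cds) < min_cds:
                continue
            ref_side_genes = [genes[i] for i in range(ref_lo, ref_hi + 1)]
            only_trna = len(ref_side_genes) > 0 and all(
                "tRNA" in g.features for g in ref_side_genes
            )
            insertion = (ref_cds < 2 or only_trna) and tgt_cds >= min_cds
            # bp span: end of last upstream-block gene to start of first
            # downstream-block gene (reference coordinates, 1-based inclusive)
            raw.append(
                GenomicIsland(
                    ref_gene_start=ref_lo,
                    ref_gene_end=ref_hi,
                    start_bp=genes[up.ref_end].end,
                    end_bp=genes[down.ref_start].start,
                    supporting=[name],
                    cds_counts={name: (ref_cds, tgt_cds)},
                    is_insertion_point=insertion,
                )
            )
    return _fuse_islands(raw)


def _fuse_islands(islands: list[GenomicIsland]) -> list[GenomicIsland]:
    """Fuse bp-overlapping GIs into maximal islands (order-independent).

    Insertion points are kept separate: they are loci, not islands, and do
    not fuse with true GIs.
    """
    out: list[GenomicIsland] = []
    for group_flag in (False, True):
        members = sorted(
            (i for i in islands if i.is_insertion_point == group_flag),
            key=lambda i: (i.start_bp, i.end_bp),
        )
        current: GenomicIsland | None = None
        for isl in members:
            if current is not None and isl.start_bp <= current.end_bp:
                current.end_bp = max(current.end_bp, isl.end_bp)
                current.ref_gene_start = min(current.ref_gene_start, isl.ref_gene_start)
                current.ref_gene_end = max(current.ref_gene_end, isl.ref_gene_end)
                for g in isl.supporting:
                    if g not in current.supporting:
                        current.supporting.append(g)
                current.cds_counts.update(isl.cds_counts)
            else:
                if current is not None:
                    out.append(current)
                current = GenomicIsland(
                    isl.ref_gene_start,
                    isl.ref_gene_end,
                    isl.start_bp,
                    isl.end_bp,
                    list(isl.supporting),
                    dict(isl.cds_counts),
                    isl.is_insertion_point,
                )
        if current is not None:
            out.append(current)
    out.sort(key=lambda i: (i.start_bp, i.end_bp))
    return out


def fisher_enrichment(
    feature: str,
    partition: CompartmentPartition,
    genes: list[GeneRecord],
    compartments: tuple[str, ...] = ("left", "right"),
) -> dict:
    """Two-sided Fisher's exact test: feature membership vs compartment.

    Builds the 2x2 table (has feature x lies in ``compartments``, by gene
    midpoint) and reports the sample odds ratio ``ad/bc`` (inf when bc = 0
    and ad > 0) together with the exact two-sided hypergeometric p-value.
    """
    if not genes:
        raise ValueError("empty gene list")
    a = b = c = d = 0
    for g in genes:
        in_comp = partition.compartment(int(g.midpoint)) in compartments
        has = feature in g.features
        if has and in_comp:
            a += 1
        elif has:
            b += 1
        elif in_comp:
            c += 1
        else:
            d += 1
    table = [[a, b], [c, d]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return {"odds_ratio": odds, "p_value": float(p), "table": table}
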