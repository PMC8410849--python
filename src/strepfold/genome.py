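"""Gene annotation and chromosome-compartment containers.

The linear *Streptomyces* chromosome is partitioned into three compartments
delimited by the outermost ribosomal RNA (rDNA) operons: a left terminal arm,
a conserved central region, and a right terminal arm.  All genomic coordinates
are 1-based inclusive internally; BED exports are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: feature labels recognised on GeneRecord.features
KNOWN_FEATURES = frozenset(
    {
        "core",
        "actino_signature",
        "SMBGC",
        "GI",
        "NAPSF",
        "rRNA",
        "tRNA",
        "functional_RNA",
        "translation",
        "unique",
    }
)


@dataclass
class GeneRecord:
    """A gene on the linear chromosome.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    start, end : int
        1-based inclusive coordinates, ``start <= end``.
    strand : str
        ``'+'`` or ``'-'``.
    features : set of str
        Annotation labels (``core``, ``SMBGC``, ``GI``, ``rRNA`` ...).
    """

    gene_id: str
    start: int
    end: int
    strand: str
    features: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.features = set(self.features)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class CompartmentPartition:
    """rDNA-delimited left / central / right partition of the chromosome.

    ``left = [1, first_rdna_start)``, ``central = [first_rdna_start,
    last_rdna_end]``, ``right = (last_rdna_end, chrom_length]``.  The three
    compartments tile the chromosome without overlap.
    """

    chrom_length: int
    first_rdna_start: int
    last_rdna_end: int
    oriC_pos: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.first_rdna_start <= self.last_rdna_end <= self.chrom_length):
            raise ValueError("rDNA limits must satisfy 1 <= first <= last <= length")

    def compartment(self, pos: int) -> str:
        """Compartment label of a 1-based bp position."""
        if pos < 1 or pos > self.chrom_length:
            raise ValueError(f"position {pos} outside chromosome")
        if pos < self.first_rdna_start:
            return "left"
        if pos <= self.last_rdna_end:
            return "central"
        return "right"

    @property
    def left_size(self) -> int:
        """Size of the left terminal compartment in bp."""
        return self.first_rdna_start - 1

    @property
    def right_size(self) -> int:
        return self.chrom_length - self.last_rdna_end

    @property
    def central_size(self) -> int:
        return self.last_rdna_end - self.first_rdna_start + 1

    def bin_compartments(self, bin_size: int, n_bins: int | None = None) -> "pd.Series":
        """Project the partition onto fixed-size bins.

        A bin takes the compartment of its midpoint.  Returns a Series of
        labels indexed by 0-based bin index.
        """
        if n_bins is None:
            n_bins = -(-self.chrom_length // bin_size)
        labels = []
        for b in range(n_bins):
            mid = min(b * bin_size + bin_size // 2 + 1, self.chrom_length)
            labels.append(self.compartment(mid))
        return pd.Series(labels, name="compartment")


def genes_to_frame(genes: list[GeneRecord]) -> pd.DataFrame:
    """Tabulate GeneRecords (one row per gene, features as ;-joined string)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "length": [g.length for g in genes],
            "features": [";".join(sorted(g.features)) for g in genes],
        }
    )


def frame_to_genes(df: pd.DataFrame) -> list[GeneRecord]:
    """Inverse of :func:`genes_to_frame`; also accepts bare TSV columns."""
    genes = []
    for row in df.itertuples(index=False):
        feats = getattr(row, "features", "") or ""
        if isinstance(feats, float):  # NaN from empty TSV cell
            feats = ""
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                features=set(f for f in str(feats).split(";") if f),
            )
        )
    return genes


def read_gene_table(path) -> list[GeneRecord]:
    """Read genes from a TSV with columns gene_id, start, end, strand[, features]."""
    return frame_to_genes(pd.read_csv(path, sep="\t"))


def write_gene_table(genes: list[GeneRecord], path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_gff3_genes(path) -> list[GeneRecord]:
    """Extract gene-level records from a GFF3 file.

    Keeps ``gene`` features; ``rRNA``/``tRNA`` children attach the matching
    label to their parent gene when the parent is present, otherwise they are
    promoted to standalone records.
    """
    genes: dict[str, GeneRecord] = {}
    rna_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            _, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", attr.get("locus_tag", f"gene_{len(genes)}"))
                genes[gid] = GeneRecord(gid, int(start), int(end), strand)
            elif ftype in ("rRNA", "tRNA"):
                rna_rows.append((ftype, int(start), int(end), strand, attr))
    for ftype, start, end, strand, attr in rna_rows:
        parent = attr.get("Parent")
        if parent in genes:
            genes[parent].features.add(ftype)
        else:
            gid = attr.get("ID", f"{ftype}_{start}")
            genes[gid] = GeneRecord(gid, start, end, strand, {ftype})
    return sorted(genes.values(), key=lambda g: g.start)
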