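"""Plain-text format plumbing: TSV matrices, pairs tables, BED, bedGraph.

BED and bedGraph exports are 0-based half-open; internal coordinates are
1-based inclusive and bins 0-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import ContactMap

PAIRS_COLUMNS = ["chrom1", "pos1", "strand1", "frag1",
                 "chrom2", "pos2", "strand2", "frag2"]


def write_matrix_tsv(cmap: ContactMap, path) -> None:
    """Dense matrix TSV with a header row of bin start coordinates (bp)."""
    starts = np.arange(cmap.n_bins) * cmap.bin_size
    pd.DataFrame(cmap.matrix, columns=starts).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_matrix_tsv(path, state: str = "raw") -> ContactMap:
    df = pd.read_csv(path, sep="\t")
    starts = df.columns.astype(int).to_numpy()
    bin_size = int(starts[1] - starts[0]) if len(starts) > 1 else 10_000
    return ContactMap(df.to_numpy(dtype=float), bin_size=bin_size, state=state)


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    cols = [c for c in PAIRS_COLUMNS if c in pairs.columns]
    pairs.to_csv(path, sep="\t", index=False, columns=cols or None)


def read_pairs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(
    intervals: list[tuple[int, int]],
    path,
    chrom: str = "chr",
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write 1-based inclusive bp intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for k, (start, end) in enumerate(intervals):
            row = [chrom, str(start - 1), str(end)]
            row.append(names[k] if names else f"feature_{k}")
            if scores is not None:
                row.append(f"{scores[k]:.6g}")
            fh.write("\t".join(row) + "\n")


def write_bedgraph(track: np.ndarray, bin_size: int, path, chrom: str = "chr") -> None:
    """Per-bin signal as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for b, v in enumerate(track):
            fh.write(f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{v:.6g}\n")


def write_boundaries_bed(boundaries, bin_size: int, path, chrom: str = "chr") -> None:
    """Boundary bins as BED with score = min(FI_up, FI_down)."""
    with open(path, "w") as fh:
        for k, bd in enumerate(boundaries):
            lo = min(bd.bins) * bin_size
            hi = (max(bd.bins) + 1) * bin_size
            fh.write(f"{chrom}\t{lo}\t{hi}\tboundary_{k}\t{bd.score:.6g}\n")
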