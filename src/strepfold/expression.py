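"""Stranded expression normalization, antisense statistics and categories.

Sense counts are normalized with the median-of-ratios size factors used by
standard RNA-seq pipelines.  Antisense counts are never normalized directly:
the antisense fraction of each gene is measured on the raw data and applied
to the normalized sense counts, so that pervasive antisense transcription
cannot distort the size factors.  Expression levels are reported as
normalized reads per kilobase of gene length (normRPK) and discretized into
five categories CAT_0..CAT_4; a gene above 20,000 normRPK is flagged as
highly expressed (HEG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: normRPK above which a gene counts as highly expressed
HEG_THRESHOLD = 20_000.0

#: antisense-index classes
AS_VERY_LOW = 0.05
AS_HIGH = 0.5


def median_ratio_size_factors(raw: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and normalized counts.

    For each sample, the size factor is the median over genes (restricted to
    genes with positive counts in every sample) of the ratio between the
    sample's count and the gene's geometric mean across samples.  Normalized
    counts are raw counts divided by the sample's factor.
    """
    if raw.shape[1] < 2:
        raise ValueError("size-factor estimation needs >= 2 samples")
    counts = raw.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene with positive counts in all samples; "
            "consider a pseudo-reference fallback"
        )
    sub = counts[all_pos]
    geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geomean, axis=0)
    sf = pd.Series(factors, index=raw.columns, name="size_factor")
    return sf, raw / sf


def rescale_antisense(
    raw_sense: pd.DataFrame,
    raw_antisense: pd.DataFrame,
    norm_sense: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Antisense counts rescaled through the raw antisense percentage.

    ``p = raw_AS / (raw_S + raw_AS)`` per gene and sample, then
    ``norm_AS = p * norm_S``.  Entries with zero total raw signal get
    norm_AS = 0 and are flagged undefined.

    Returns (norm_antisense, undefined_mask).
    """
    s = raw_sense.to_numpy(dtype=float)
    a = raw_antisense.to_numpy(dtype=float)
    if (s < 0).any() or (a < 0).any():
        raise ValueError("negative counts")
    total = s + a
    undefined = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(undefined, 0.0, a / np.where(total == 0, 1.0, total))
    norm_as = p * norm_sense.to_numpy(dtype=float)
    return (
        pd.DataFrame(norm_as, index=raw_sense.index, columns=raw_sense.columns),
        pd.DataFrame(undefined, index=raw_sense.index, columns=raw_sense.columns),
    )


def antisense_index(
    raw_sense: pd.DataFrame,
    raw_antisense: pd.DataFrame,
    replicates: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-gene antisense index per condition, pooling replicates.

    ``AS = sum(antisense) / (sum(sense) + sum(antisense))`` over the
    replicates of a condition; NaN when no read was detected in either
    orientation in all replicates.  Classes: 'very_low' (< 0.05), 'high'
    (> 0.5), otherwise 'intermediate'.
    """
    out = {}
    for cond, samples in replicates.items():
        s = raw_sense[samples].sum(axis=1).to_numpy(dtype=float)
        a = raw_antisense[samples].sum(axis=1).to_numpy(dtype=float)
        total = s + a
        with np.errstate(invalid="ignore", divide="ignore"):
            out[cond] = np.where(total > 0, a / np.where(total == 0, 1, total), np.nan)
    return pd.DataFrame(out, index=raw_sense.index)


def classify_antisense(as_index: pd.DataFrame) -> pd.DataFrame:
    """Label antisense indices as very_low / intermediate / high (NaN kept)."""
    vals = as_index.to_numpy(dtype=float)
    labels = np.full(vals.shape, "intermediate", dtype=object)
    labels[vals < AS_VERY_LOW] = "very_low"
    labels[vals > AS_HIGH] = "high"
    labels[np.isnan(vals)] = None
    return pd.DataFrame(labels, index=as_index.index, columns=as_index.columns)


def compute_normRPK(norm_counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """normRPK = normalized count / gene length (bp) * 1000."""
    lengths = gene_lengths.reindex(norm_counts.index).to_numpy(dtype=float)
    if np.isnan(lengths).any():
        missing = norm_counts.index[np.isnan(lengths)][0]
        raise ValueError(f"missing length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return norm_counts.div(lengths, axis=0) * 1000.0


def default_cat_thresholds(normrpk: pd.DataFrame) -> list[float]:
    """CAT cut points from the distribution of expressed genes.

    CAT_0 below 1 normRPK; CAT_1..CAT_4 split at the 25/50/75% quantiles of
    normRPK >= 1 values pooled across conditions.
    """
    vals = normrpk.to_numpy(dtype=float).ravel()
    vals = vals[vals >= 1.0]
    if len(vals) == 0:
        return [1.0, 2.0, 4.0, 8.0]
    q25, q50, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
    return [1.0, float(q25), float(q50), float(q75)]


def categorize_expression(
    normrpk: pd.DataFrame,
    thresholds: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discretize normRPK into CAT_0..CAT_4 and flag highly expressed genes.

    ``thresholds`` are 4 strictly increasing cut points; CAT_k for values in
    [t_k-1, t_k), CAT_0 below the first cut, CAT_4 at or above the last.
    Returns (categories as ints 0..4, HEG flag at normRPK > 20,000).
    """
    if thresholds is None:
        thresholds = default_cat_thresholds(normrpk)
    t = np.asarray(thresholds, dtype=float)
    if len(t) != 4 or not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be 4 strictly increasing cut points")
    vals = normrpk.to_numpy(dtype=float)
    cats = np.searchsorted(t, vals, side="right")
    heg = vals > HEG_THRESHOLD
    return (
        pd.DataFrame(cats, index=normrpk.index, columns=normrpk.columns),
        pd.DataFrame(heg, index=normrpk.index, columns=normrpk.columns),
    )


def flag_switch_genes(categories: pd.DataFrame) -> pd.Series:
    """Genes switched ON: CAT_0 in some condition and >= CAT_3 in another."""
    if categories.shape[1] < 2:
        raise ValueError("switch detection needs >= 2 conditions")
    cmin = categories.min(axis=1)
    cmax = categories.max(axis=1)
    return (cmin == 0) & (cmax >= 3)


def bin_expression_profile(
    counts: pd.Series,
    gene_midpoints: pd.Series,
    chrom_length: int,
    bin_size: int = 10_000,
) -> np.ndarray:
    """Sum per-gene counts into fixed-size bins by gene midpoint.

    Bin b covers [b*bin_size + 1, (b+1)*bin_size] in 1-based coordinates;
    the track has ceil(chrom_length / bin_size) bins and conserves the total.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    n_bins = -(-chrom_length // bin_size)
    track = np.zeros(n_bins, dtype=float)
    mids = gene_midpoints.reindex(counts.index).to_numpy(dtype=float)
    if np.any(mids < 1) or np.any(mids > chrom_length):
        raise ValueError("gene outside chromosome")
    bins = ((mids - 1) // bin_size).astype(int)
    np.add.at(track, bins, counts.to_numpy(dtype=float))
    return track


@dataclass
class ExpressionSet:
    """Bundle of stranded expression data for one annotation.

    Holds raw and normalized sense/antisense matrices (gene x sample), the
    replicate structure, condition-level normRPK, categories and antisense
    indices.  Genes listed in ``excluded`` (rRNA, duplicated-TIR copies) are
    masked out of normalization and categorization.
    """

    raw_sense: pd.DataFrame
    raw_antisense: pd.DataFrame
    replicates: dict[str, list[str]]
    gene_lengths: pd.Series
    excluded: set = None

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = set()
        self._keep = [g for g in self.raw_sense.index if g not in self.excluded]

    def analyse(self, cat_thresholds: list[float] | None = None) -> dict:
        """Run the full normalization / categorization cascade.

        Returns a dict with size_factors, norm_sense, norm_antisense,
        normRPK (condition-level), categories, heg, switch, as_index.
        """
        sense = self.raw_sense.loc[self._keep]
        anti = self.raw_antisense.loc[self._keep]
        sf, norm_sense = median_ratio_size_factors(sense)
        norm_anti, undef = rescale_antisense(sense, anti, norm_sense)
        # condition level = mean of replicate normalized counts
        cond_norm = pd.DataFrame(
            {c: norm_sense[s].mean(axis=1) for c, s in self.replicates.items()}
        )
        normrpk = compute_normRPK(cond_norm, self.gene_lengths.loc[self._keep])
        cats, heg = categorize_expression(normrpk, cat_thresholds)
        switch = flag_switch_genes(cats)
        asi = antisense_index(sense, anti, self.replicates)
        return {
            "size_factors": sf,
            "norm_sense": norm_sense,
            "norm_antisense": norm_anti,
            "antisense_undefined": undef,
            "normRPK": normrpk,
            "categories": cats,
            "heg": heg,
            "switch": switch,
            "as_index": asi,
        }
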