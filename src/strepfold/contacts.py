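"""3C contact-map construction, SCN normalization, decay and dispersion.

The 3C pipeline proceeds in the canonical order: restriction digest of the
genome into a fragment map, assignment of read pairs to fragments, removal
of non-informative events (PCR duplicates, self-circularized fragments,
uncut co-linear religations), binning of the valid pairs at 10 kb, and
sequential component normalization (SCN: alternate division of columns and
rows by their Euclidean norm until convergence).  Distance-decay statistics
P(s) / var(s) and the dispersion index I(s) = var(s)/P(s) are computed per
chromosome compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

SALI_SITE = "GTCGAC"
SALI_CUT_OFFSET = 1  # SalI cuts G^TCGAC


@dataclass
class FragmentMap:
    """Restriction fragments tiling the chromosome (1-based inclusive)."""

    starts: np.ndarray  # 1-based start of each fragment
    ends: np.ndarray  # 1-based inclusive end
    site: str = SALI_SITE

    @property
    def n_fragments(self) -> int:
        return len(self.starts)

    @property
    def chrom_length(self) -> int:
        return int(self.ends[-1])

    def assign(self, positions: np.ndarray) -> np.ndarray:
        """Fragment index (0-based) of each 1-based bp position."""
        pos = np.asarray(positions)
        if np.any(pos < 1) or np.any(pos > self.chrom_length):
            raise ValueError("position outside chromosome")
        return np.searchsorted(self.starts, pos, side="right") - 1


def digest_sequence(genome: str, site: str = SALI_SITE,
                    cut_offset: int = SALI_CUT_OFFSET) -> FragmentMap:
    """In-silico restriction digest.

    The enzyme cuts ``cut_offset`` nucleotides into each occurrence of
    ``site``; fragments tile the genome exactly (their lengths sum to the
    genome length).
    """
    if not genome:
        raise ValueError("empty genome")
    site = site.upper()
    if len(site) < 4:
        raise ValueError("site must be >= 4 nt")
    if set(site) - set("ACGT"):
        raise ValueError(f"site {site!r} contains non-ACGT symbols")
    seq = genome.upper()
    cuts = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + cut_offset)  # 0-based position after which we cut
        i = seq.find(site, i + 1)
    starts = [1] + [c + 1 for c in cuts]
    ends = [c for c in cuts] + [len(seq)]
    return FragmentMap(np.asarray(starts), np.asarray(ends), site)


def classify_pairs(pairs: pd.DataFrame, fragmap: FragmentMap) -> pd.DataFrame:
    """Classify read pairs as valid / self_circle / uncut / duplicate.

    Expects columns pos1, strand1, pos2, strand2 (1-based positions, strand
    '+'/'-').  Exact duplicates (same coordinates and strands) are flagged
    first; then mates on the same fragment facing each other are
    self-circles, and mates on adjacent fragments in genomic (inward)
    orientation across the shared cut site are uncut religations.  The
    classification is exhaustive and exclusive.
    """
    df = pairs.copy()
    frag1 = fragmap.assign(df["pos1"].to_numpy())
    frag2 = fragmap.assign(df["pos2"].to_numpy())
    df["frag1"] = frag1
    df["frag2"] = frag2

    dup = df.duplicated(subset=["pos1", "strand1", "pos2", "strand2"], keep="first")
    same_frag = frag1 == frag2
    # orient by genomic position: upstream strand / downstream strand
    upstream_plus = np.where(
        df["pos1"].to_numpy() <= df["pos2"].to_numpy(),
        df["strand1"].to_numpy(), df["strand2"].to_numpy(),
    )
    downstream_strand = np.where(
        df["pos1"].to_numpy() <= df["pos2"].to_numpy(),
        df["strand2"].to_numpy(), df["strand1"].to_numpy(),
    )
    facing = (upstream_plus == "-") & (downstream_strand == "+")  # outward
    inward = (upstream_plus == "+") & (downstream_strand == "-")
    self_circle = same_frag & facing
    uncut = (np.abs(frag1 - frag2) == 1) & inward

    cls = np.full(len(df), "valid", dtype=object)
    cls[self_circle] = "self_circle"
    cls[uncut] = "uncut"
    cls[same_frag & ~self_circle] = "self_circle"  # same-fragment events are never informative
    cls[dup.to_numpy()] = "duplicate"
    df["classification"] = cls
    return df


def bin_pairs(
    pairs: pd.DataFrame,
    chrom_length: int,
    bin_size: int = 10_000,
    only_valid: bool = True,
) -> "ContactMap":
    """Bin (valid) pairs into a raw symmetric contact matrix.

    Each pair increments M[i, j] and M[j, i] (once on the diagonal when
    i = j), with i, j the 0-based bins of the two mate positions.
    """
    n_bins = -(-chrom_length // bin_size)
    mat = np.zeros((n_bins, n_bins), dtype=np.int64)
    df = pairs
    if only_valid and "classification" in pairs.columns:
        df = pairs[pairs["classification"] == "valid"]
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    if np.any(p1 < 1) or np.any(p1 > chrom_length) or np.any(p2 < 1) or np.any(
        p2 > chrom_length
    ):
        raise ValueError("position beyond chromosome")
    b1 = ((p1 - 1) // bin_size).astype(np.int64)
    b2 = ((p2 - 1) // bin_size).astype(np.int64)
    np.add.at(mat, (b1, b2), 1)
    off = b1 != b2
    np.add.at(mat, (b2[off], b1[off]), 1)
    return ContactMap(matrix=mat.astype(float), bin_size=bin_size, state="raw")


@dataclass
class ContactMap:
    """Binned symmetric contact matrix with mask and normalization state."""

    matrix: np.ndarray
    bin_size: int = 10_000
    state: str = "raw"
    masked_bins: set = field(default_factory=set)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        self.matrix = m
        self.masked_bins = set(int(b) for b in self.masked_bins)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.masked_bins)] = False
        return keep


def mask_low_coverage(cmap: ContactMap, frac_of_median: float = 0.10) -> ContactMap:
    """Mask bins whose raw marginal sum is below a fraction of the median.

    SCN diverges on (near-)empty rows; masked bins are zeroed and excluded
    from normalization and downstream statistics.
    """
    marg = cmap.matrix.sum(axis=0)
    pos = marg[marg > 0]
    cutoff = frac_of_median * (np.median(pos) if len(pos) else 0.0)
    masked = set(int(b) for b in np.flatnonzero(marg < cutoff)) | set(
        int(b) for b in np.flatnonzero(marg == 0)
    )
    mat = cmap.matrix.copy()
    idx = sorted(masked)
    mat[idx, :] = 0.0
    mat[:, idx] = 0.0
    return ContactMap(mat, cmap.bin_size, cmap.state, masked | cmap.masked_bins)


def scn_normalize(
    cmap: ContactMap,
    max_iter: int = 200,
    tol: float = 1e-9,
    norm: str = "l2",
) -> ContactMap:
    """Sequential component normalization.

    Alternately divides each column then each row by its norm (Euclidean by
    default) and symmetrizes, until every unmasked row norm is within
    ``tol`` of 1.  The output is scale-invariant in the input counts and
    idempotent up to ``tol``.
    """
    mat = cmap.matrix.astype(float).copy()
    keep = cmap.unmasked()
    if not np.any(mat[np.ix_(keep, keep)] > 0):
        raise ValueError("all-zero matrix cannot be normalized")
    ord_ = 2 if norm == "l2" else 1

    def norms(m, axis):
        if ord_ == 2:
            return np.sqrt((m * m).sum(axis=axis))
        return np.abs(m).sum(axis=axis)

    for _ in range(max_iter):
        col = norms(mat, 0)
        col[col == 0] = 1.0
        mat = mat / col[None, :]
        row = norms(mat, 1)
        row[row == 0] = 1.0
        mat = mat / row[:, None]
        mat = 0.5 * (mat + mat.T)
        dev = np.abs(norms(mat, 1)[keep] - 1.0).max()
        if dev < tol:
            break
    return ContactMap(mat, cmap.bin_size, "scn", set(cmap.masked_bins))


def smooth_for_display(
    cmap: ContactMap,
    z_threshold: float = 3.0,
    sigma: float = 1.0,
    per_diagonal: bool = False,
    pseudocount: float | None = None,
) -> np.ndarray:
    """Display transform: outliers to median, log10, Gaussian filter (sigma=1).

    Outliers are entries whose z-score — global by default, or within their
    diagonal when ``per_diagonal`` — exceeds ``z_threshold``; they are
    replaced with the matrix median before the log.  The result is for
    visualization only and is never fed into boundary calling.
    """
    mat = cmap.matrix.astype(float).copy()
    keep = cmap.unmasked()
    sub = mat[np.ix_(keep, keep)]
    med = float(np.median(sub))
    if per_diagonal:
        n = mat.shape[0]
        for s in range(n):
            diag = np.diagonal(mat, offset=s)
            sd = diag.std()
            if sd > 0:
                z = np.abs(diag - diag.mean()) / sd
                idx = np.flatnonzero(z > z_threshold)
                for i in idx:
                    mat[i, i + s] = med
                    mat[i + s, i] = med
    else:
        sd = sub.std()
        if sd > 0:
            z = np.abs(mat - sub.mean()) / sd
            mat[z > z_threshold] = med
    if pseudocount is None:
        pos = mat[mat > 0]
        pseudocount = float(pos.min()) / 10.0 if len(pos) else 1.0
    logm = np.log10(mat + pseudocount)
    return ndimage.gaussian_filter(logm, sigma=sigma)


def contact_probability(
    cmap: ContactMap, region: np.ndarray | None = None
) -> pd.DataFrame:
    """Distance-decay statistics P(s) and var(s) within a bin region.

    For each separation s >= 1 (in bins), P(s) is the mean and var(s) the
    variance (ddof=1) of M[i, i+s] over pairs with both bins inside
    ``region`` (contiguous 0-based bin indices; full map when None),
    skipping masked bins.
    """
    if region is None:
        region = np.arange(cmap.n_bins)
    region = np.asarray(region, dtype=int)
    if len(region) < 2:
        raise ValueError("region must span >= 2 bins")
    keep = cmap.unmasked()
    lo, hi = region.min(), region.max()
    rows = []
    for s in range(1, hi - lo + 1):
        i = np.arange(lo, hi - s + 1)
        j = i + s
        ok = keep[i] & keep[j]
        vals = cmap.matrix[i[ok], j[ok]]
        if len(vals) == 0:
            continue
        rows.append(
            {
                "s_bins": s,
                "s_bp": s * cmap.bin_size,
                "n": len(vals),
                "P": float(vals.mean()),
                "var": float(vals.var(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def expected_by_distance(cmap: ContactMap) -> np.ndarray:
    """P(s) over the whole map for every separation 0..n-1 (masked skipped)."""
    n = cmap.n_bins
    keep = cmap.unmasked()
    exp = np.zeros(n)
    for s in range(n):
        i = np.arange(0, n - s)
        j = i + s
        ok = keep[i] & keep[j]
        exp[s] = cmap.matrix[i[ok], j[ok]].mean() if ok.any() else 0.0
    return exp


def dispersion_index(decay: pd.DataFrame) -> pd.DataFrame:
    """Dispersion index I(s) = var(s) / P(s); undefined where P(s) = 0."""
    out = decay.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["I"] = np.where(out["P"] > 0, out["var"] / out["P"], np.nan)
    return out


def long_range_dispersion(
    cmap: ContactMap,
    regions: dict[str, np.ndarray],
    min_dist_bp: int = 100_000,
) -> dict[str, float]:
    """Mean I(s) over s > min_dist_bp, computed separately per compartment."""
    out = {}
    for name, region in regions.items():
        disp = dispersion_index(contact_probability(cmap, region))
        sel = disp[disp["s_bp"] > min_dist_bp]
        out[name] = float(np.nanmean(sel["I"])) if len(sel) else np.nan
    return out


def subsample_pairs(
    pairs: pd.DataFrame, target: int = 2_000_000, seed: int = 0
) -> pd.DataFrame:
    """Random subsample of valid pairs to a fixed depth (comparative maps)."""
    if len(pairs) <= target:
        return pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=target, replace=False)
    return pairs.iloc[np.sort(idx)]
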