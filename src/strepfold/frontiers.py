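"""Frontier-index boundary and domain calling on normalized contact maps.

The frontier index (FI) quantifies how strongly each bin behaves as the
edge of a self-interacting domain.  From an SCN-normalized map the expected
contact frequency at each distance, P(s), is subtracted to remove the
overall decay; a pseudocount of m/20 (m = maximal contact frequency) makes
all entries positive before taking the logarithm.  Directional first
differences of the log map are clipped at zero and summed over all partner
bins closer than 600 kb: a domain START produces a peak of the upstream
index FI_up, a domain END a peak of the downstream index FI_down.

Peaks are kept when they exceed median(peak heights) + 2 * 1.48 * MAD,
with the statistics computed separately in the left arm, the central
region and the right arm, whose contact statistics differ.  A boundary is
a bin — or a pair of consecutive bins, to absorb positional uncertainty —
carrying both a significant upstream and a significant downstream peak;
remaining significant peaks are orphans and are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMap, expected_by_distance
from .genome import CompartmentPartition, GeneRecord

DEFAULT_MAX_DIST_BP = 600_000
DEFAULT_PSEUDOCOUNT_FRAC = 1.0 / 20.0
DEFAULT_THRESH_MULT = 2.0
MAD_SCALE = 1.48  # robust sigma estimate: 1.48 * MAD
ENV_BINS = 2  # boundary environment: +/- 2 bins


@dataclass
class Boundary:
    """A called domain boundary: one bin or a pair of consecutive bins."""

    bins: tuple[int, ...]  # (b,) or (b, b+1)
    fi_up: float
    fi_down: float

    @property
    def position(self) -> float:
        """Delimiter coordinate in bins (midpoint for a pair)."""
        return float(np.mean(self.bins))

    @property
    def score(self) -> float:
        return min(self.fi_up, self.fi_down)


@dataclass
class FrontierResult:
    fi_up: np.ndarray
    fi_down: np.ndarray
    peaks_up: list[int]
    peaks_down: list[int]
    sig_up: set = field(default_factory=set)
    sig_down: set = field(default_factory=set)
    boundaries: list[Boundary] = field(default_factory=list)
    orphan_peaks: list[int] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def prepare_frontier_matrix(cmap: ContactMap) -> np.ndarray:
    """Expected-corrected log contact map.

    ``L[i, j] = log(M[i, j] - P(|i - j|) + c)`` with the pseudocount
    ``c = m/20`` (m the maximal contact frequency) plus whatever additional
    shift is needed to make every entry strictly positive.  Masked bins
    propagate as NaN.
    """
    keep = cmap.unmasked()
    if keep.sum() < 3:
        raise ValueError("need >= 3 unmasked bins")
    mat = cmap.matrix.astype(float)
    exp = expected_by_distance(cmap)
    n = cmap.n_bins
    idx = np.arange(n)
    corrected = mat - exp[np.abs(idx[:, None] - idx[None, :])]
    sub = corrected[np.ix_(keep, keep)]
    m = float(mat[np.ix_(keep, keep)].max())
    c = m * DEFAULT_PSEUDOCOUNT_FRAC
    low = float(sub.min())
    if low + c <= 0:
        c += -low + m * DEFAULT_PSEUDOCOUNT_FRAC  # shift into positivity
    L = np.log(corrected + c)
    L[~keep, :] = np.nan
    L[:, ~keep] = np.nan
    return L


def frontier_profiles(
    L: np.ndarray,
    bin_size: int = 10_000,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
) -> tuple[np.ndarray, np.ndarray]:
    """Upstream and downstream frontier-index profiles.

    The derivative entering FI_up at bin b compares the contacts of b with
    those of b-1 against common partners (a domain start gains contacts);
    FI_down compares b with b+1 (a domain end loses contacts to the right).
    Negative derivative values are set to zero and the remainder summed
    over partner bins at distance 1..max_dist bins on both sides.
    Derivatives across missing (NaN) bins are skipped.
    """
    n = L.shape[0]
    d = max(2, int(round(max_dist_bp / bin_size)))
    fi_up = np.zeros(n)
    fi_down = np.zeros(n)
    for b in range(n):
        j0 = max(0, b - d)
        j1 = min(n, b + d + 1)
        js = np.arange(j0, j1)
        js = js[js != b]
        if b > 0:
            dup = L[b, js] - L[b - 1, js]
            dup = dup[np.isfinite(dup)]
            fi_up[b] = np.clip(dup, 0, None).sum()
        if b < n - 1:
            ddn = L[b, js] - L[b + 1, js]
            ddn = ddn[np.isfinite(ddn)]
            fi_down[b] = np.clip(ddn, 0, None).sum()
    fi_up[~np.isfinite(L).any(axis=1)] = 0.0
    fi_down[~np.isfinite(L).any(axis=1)] = 0.0
    return fi_up, fi_down


def find_local_maxima(profile: np.ndarray) -> list[int]:
    """Strict local maxima; a flat plateau contributes its leftmost bin."""
    peaks = []
    n = len(profile)
    b = 1
    while b < n - 1:
        if profile[b] > profile[b - 1]:
            e = b
            while e + 1 < n and profile[e + 1] == profile[b]:
                e += 1
            if e + 1 < n and profile[e + 1] < profile[b]:
                peaks.append(b)
            b = e + 1
        else:
            b += 1
    return peaks


def call_peaks(
    profile: np.ndarray,
    compartment_of_bin: np.ndarray | list[str],
    thresh_mult: float = DEFAULT_THRESH_MULT,
) -> tuple[list[int], set]:
    """Significant peaks of an FI profile, per-compartment thresholds.

    Candidate peaks are strict local maxima.  Within each compartment, a
    peak is significant when its height strictly exceeds
    ``median(peak heights) + thresh_mult * 1.48 * MAD(peak heights)`` with
    both statistics taken over that compartment's candidate peaks only.  A
    compartment with fewer than 3 candidates falls back to the global
    statistics (with a warning).
    """
    comp = np.asarray(compartment_of_bin)
    candidates = find_local_maxima(profile)
    if not candidates:
        return [], set()
    heights = profile[candidates]
    global_med = float(np.median(heights))
    global_mad = float(stats.median_abs_deviation(heights))
    sig: set = set()
    for label in pd.unique(comp):
        local = [p for p in candidates if comp[p] == label]
        if len(local) < 3:
            warnings.warn(
                f"compartment {label!r}: fewer than 3 candidate peaks; "
                "falling back to global peak statistics",
                stacklevel=2,
            )
            med, mad = global_med, global_mad
        else:
            h = profile[local]
            med = float(np.median(h))
            mad = float(stats.median_abs_deviation(h))
        thr = med + thresh_mult * MAD_SCALE * mad
        sig.update(p for p in local if profile[p] > thr)
    return candidates, sig


def call_boundaries(
    sig_up: set, sig_down: set, masked_bins: set | None = None
) -> tuple[list[tuple[int, ...]], list[int]]:
    """Pair significant upstream and downstream peaks into boundaries.

    A bin carrying both a significant up and down peak is a single-bin
    boundary; two consecutive bins carrying one significant up and one
    significant down peak form a pair boundary.  Peaks consumed by no
    boundary are orphans.  Boundaries are never allocated to masked bins.
    """
    masked = masked_bins or set()
    up = {b for b in sig_up if b not in masked}
    down = {b for b in sig_down if b not in masked}
    boundaries: list[tuple[int, ...]] = []
    used_up: set = set()
    used_down: set = set()
    for b in sorted(up & down):
        boundaries.append((b,))
        used_up.add(b)
        used_down.add(b)
    for b in sorted(up):
        if b in used_up:
            continue
        for nb in (b - 1, b + 1):
            if nb in down and nb not in used_down and nb not in used_up:
                boundaries.append((min(b, nb), max(b, nb)))
                used_up.add(b)
                used_down.add(nb)
                break
    orphans = sorted((up - used_up) | (down - used_down))
    boundaries.sort()
    return boundaries, orphans


def call_frontiers(
    cmap: ContactMap,
    partition: CompartmentPartition | None = None,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
    thresh_mult: float = DEFAULT_THRESH_MULT,
) -> FrontierResult:
    """Full frontier-index pipeline on an SCN-normalized contact map."""
    L = prepare_frontier_matrix(cmap)
    fi_up, fi_down = frontier_profiles(L, cmap.bin_size, max_dist_bp)
    if partition is None:
        comp = np.asarray(["all"] * cmap.n_bins)
    else:
        comp = partition.bin_compartments(cmap.bin_size, cmap.n_bins).to_numpy()
    peaks_up, sig_up = call_peaks(fi_up, comp, thresh_mult)
    peaks_down, sig_down = call_peaks(fi_down, comp, thresh_mult)
    pairs, orphans = call_boundaries(sig_up, sig_down, cmap.masked_bins)
    boundaries = [
        Boundary(
            bins=p,
            fi_up=float(max(fi_up[b] for b in p)),
            fi_down=float(max(fi_down[b] for b in p)),
        )
        for p in pairs
    ]
    return FrontierResult(
        fi_up=fi_up,
        fi_down=fi_down,
        peaks_up=peaks_up,
        peaks_down=peaks_down,
        sig_up=sig_up,
        sig_down=sig_down,
        boundaries=boundaries,
        orphan_peaks=orphans,
        params={
            "max_dist_bp": max_dist_bp,
            "pseudocount_frac": DEFAULT_PSEUDOCOUNT_FRAC,
            "thresh_mult": thresh_mult,
            "env_bins": ENV_BINS,
        },
    )


def segment_domains(
    boundaries: list[Boundary],
    bin_size: int = 10_000,
    compartment_bins: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Domains between consecutive boundary delimiters within a compartment.

    Delimiters are the boundary positions (midpoint for paired bins).  With
    ``compartment_bins = (lo, hi)``, only boundaries inside the compartment
    are used.  Sizes are reported in kb; fewer than 2 delimiters yield an
    empty set.
    """
    pos = sorted(b.position for b in boundaries)
    if compartment_bins is not None:
        lo, hi = compartment_bins
        pos = [p for p in pos if lo <= p <= hi]
    rows = []
    for a, b in zip(pos, pos[1:]):
        rows.append(
            {
                "start_bin": a,
                "end_bin": b,
                "size_kb": (b - a) * bin_size / 1000.0,
            }
        )
    return pd.DataFrame(rows, columns=["start_bin", "end_bin", "size_kb"])


def annotate_boundaries(
    boundaries: list[Boundary],
    genes: list[GeneRecord],
    bin_size: int,
    chrom_length: int,
    normrpk: pd.Series | None = None,
    persistence: pd.Series | None = None,
    oriC_pos: int | None = None,
    env_bins: int = ENV_BINS,
) -> pd.DataFrame:
    """Annotate each boundary with the genes in its +/- 2-bin environment.

    Summarizes expression (median normRPK, highly-expressed-gene count),
    persistence, and rRNA content per boundary.  When ``oriC_pos`` is
    given, the report carries the leading-strand-orientation Fisher test
    over all boundary genes: gene strand vs replichore side relative to
    oriC (genes co-oriented with the replication fork are '+' right of
    oriC and '-' left of it on a linear chromosome).
    """
    from scipy import stats as _st

    rows = []
    table = np.zeros((2, 2), dtype=int)
    for bd in boundaries:
        lo_bin = min(bd.bins) - env_bins
        hi_bin = max(bd.bins) + env_bins
        lo_bp = max(1, lo_bin * bin_size + 1)
        hi_bp = min(chrom_length, (hi_bin + 1) * bin_size)
        if min(bd.bins) * bin_size >= chrom_length:
            raise ValueError("boundary outside annotated chromosome")
        env = [g for g in genes if lo_bp <= g.midpoint <= hi_bp]
        ids = [g.gene_id for g in env]
        rec = {
            "bins": ",".join(str(b) for b in bd.bins),
            "position_bp": bd.position * bin_size + bin_size / 2,
            "score": bd.score,
            "n_genes": len(env),
            "has_rRNA": any("rRNA" in g.features for g in env),
        }
        if normrpk is not None:
            vals = normrpk.reindex(ids).dropna()
            rec["median_normRPK"] = float(vals.median()) if len(vals) else np.nan
            rec["n_heg"] = int((vals > 20_000).sum())
        if persistence is not None:
            vals = persistence.reindex(ids).dropna()
            rec["median_persistence"] = float(vals.median()) if len(vals) else np.nan
        if oriC_pos is not None:
            for g in env:
                leading = ("+" if g.midpoint > oriC_pos else "-")
                table[0 if g.strand == leading else 1][
                    0 if g.midpoint > oriC_pos else 1
                ] += 1
        rows.append(rec)
    report = pd.DataFrame(rows)
    if oriC_pos is not None and table.sum() > 0:
        # collapse to co-oriented vs not (both replichores pooled)
        co = int(table[0].sum())
        anti = int(table[1].sum())
        report.attrs["leading_strand_table"] = table.tolist()
        report.attrs["co_oriented"] = co
        report.attrs["anti_oriented"] = anti
    return report


def leading_strand_test(
    genes: list[GeneRecord],
    boundary_gene_ids: set,
    oriC_pos: int,
) -> dict:
    """Fisher test: co-orientation with replication vs boundary membership.

    2x2 table of (gene co-oriented with the fork) x (gene in a boundary
    environment), two-sided exact test; the sample odds ratio is ad/bc.
    """
    a = b = c = d = 0
    for g in genes:
        leading = "+" if g.midpoint > oriC_pos else "-"
        co = g.strand == leading
        in_bd = g.gene_id in boundary_gene_ids
        if co and in_bd:
            a += 1
        elif co:
            b += 1
        elif in_bd:
            c += 1
        else:
            d += 1
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    sample_or = (a * d) / (b * c) if b * c else float("inf")
    return {"odds_ratio": sample_or, "p_value": float(p), "table": [[a, b], [c, d]]}
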