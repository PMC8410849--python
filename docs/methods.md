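# Methods

## The chromosome model

The object of analysis is a linear bacterial chromosome of the
*Streptomyces* type, ~6.7 Mb after trimming one terminal inverted repeat
(TIR), partitioned into three compartments by the outermost ribosomal RNA
operons: `left = [1, first_rdna_start)`, `central = [first_rdna_start,
last_rdna_end]`, `right = (last_rdna_end, chrom_length]`. The default
coordinates place the first rDNA at 1,469,670 bp and the end of the last at
5,807,629 bp, giving a 1.47-Mb left arm. Compartments are projected onto
10-kb bins by bin midpoint. All internal coordinates are 1-based inclusive;
BED/bedGraph exports are 0-based half-open; contact bins are 0-based.

## Conservation layer

**Orthologs.** Reciprocal best hits between protein sets, best hit ranked by
bit-score with deterministic tie-breaking (lower E-value, then
lexicographically smaller subject). Thresholds: ≥ 40% identity, ≥ 70%
coverage, E ≤ 1e−10, in both directions. Coverage is alignment length over
query length; since the 12-column tabular hit format carries no sequence
lengths, the coverage filter requires an explicit length table and is
otherwise skipped.

**Persistence.** `persistence(g) = N_orth(g)/N` over the N surveyed genomes;
genes above 0.95 are flagged as the conserved backbone.

**GOC.** Sliding window of 8 CDSs, step 1, against one target genome. The
denominator is the number of window genes with an ortholog; the numerator
counts genes participating in a conserved adjacency — consecutive reference
indices whose target indices differ by exactly 1. A window with a single
ortholog scores 0; NA is reserved for windows with no ortholog at all.

**Synteny blocks and islands.** A block extends while successive
ortholog-bearing genes are strictly consecutive in the reference *and* step
by ±1 in the target in a fixed direction; runs below `min_block = 2` genes
are dropped. A break between two same-direction blocks is a genomic island
when at least 15 CDSs lie inside the break in either genome; when the
reference side has < 2 CDSs (or only tRNAs) against ≥ 15 in the target it
is recorded as an insertion point instead. Islands overlapping across
pairwise comparisons are fused (the fusion is order-independent; insertion
points never fuse with true islands). Strict consecutiveness means any
ortholog absence interrupts a block; this is what lets a reference-specific
insertion appear as a break with 0 target CDSs.

**Enrichment.** Two-sided Fisher's exact test on the 2×2 table of feature
membership × compartment membership (gene midpoint); the reported odds ratio
is the sample `ad/bc` (∞ at zero cells), the p-value the exact
hypergeometric sum.

## Expression layer

**Size factors.** Median-of-ratios: for genes positive in every sample, the
factor of a sample is the median of count / per-gene geometric mean. The
median is taken on the linear ratios, which makes the median ratio of
normalized counts to the raw pseudo-reference exactly 1 (a log-space median
differs for even gene counts). Genes on the duplicated TIR copy and rRNAs
are excluded via a mask before normalization.

**Antisense rescaling.** Antisense counts never enter the size factors: the
raw antisense percentage `p = AS/(S+AS)` per gene and sample is applied to
the normalized sense counts. A gene with zero total raw signal gets 0 and an
undefined flag; a gene with only antisense reads gets `p = 1` applied to a
zero normalized sense count (0, but defined). The antisense index per
condition pools replicates, `ΣAS/(ΣS+ΣAS)`, and is undefined only when all
replicates are silent in both orientations; classes are very low (< 0.05)
and high (> 0.5).

**Categories.** `normRPK = normalized count / gene length × 1000`, averaged
over replicates per condition. CAT_0 below 1 normRPK; CAT_1–CAT_4 split at
the 25/50/75% quantiles of the pooled normRPK ≥ 1 distribution (cut points
fully configurable; pooling across conditions keeps categories comparable
between conditions). Genes above 20,000 normRPK are flagged highly
expressed. Switch-ON genes have CAT_0 in at least one condition and ≥ CAT_3
in another.

## Contact-map layer

**Digestion and event filtering.** SalI (`GTCGAC`) cut 1 nt into the site
(`G^TCGAC`). Exact duplicate pairs are removed first; all same-fragment
events are discarded (self-circles and their kin are never informative);
pairs on adjacent fragments in inward genomic orientation across the shared
cut site are discarded as uncut religations; the remainder are valid and
binned at 10 kb (both matrix orders, once on the diagonal).

**Masking and SCN.** Bins whose raw marginal is below 10% of the median
positive marginal are masked (SCN diverges on empty rows). SCN alternates
column and row division by the Euclidean norm with symmetrization until the
maximal deviation of unmasked row norms from 1 is below `tol = 1e−9`
(≤ 200 iterations). The output is invariant to rescaling the input and
idempotent to within `tol`.

**Display smoothing.** For visualization only: entries with |z| > 3 (global
by default; a per-diagonal mode is available because the printed outlier
rule does not say whether z-scores were distance-stratified) are replaced by
the matrix median, then log10 with a pseudocount, then a Gaussian filter
with σ = 1 bin (the printed "H = 1" is read as σ). Never fed to boundary
calling.

**Decay and dispersion.** For each separation s ≥ 1 (bins), `P(s)` and
`var(s)` are the mean and variance (ddof = 1) of `M[i, i+s]` over pairs
inside a region, skipping masked bins; `I(s) = var(s)/P(s)` where
`P(s) > 0`. The long-range summary is the mean of `I(s)` over s > 100 kb,
computed per compartment. On Poisson-sampled maps `I(s) → 1`, which
calibrates the index; multiplicative intensity noise of variance v adds
≈ `λ·v` to it.

## Frontier index

From the SCN map: `L[i,j] = log(M[i,j] − P(|i−j|) + c)` with the
pseudocount `c = m/20` (m the maximal contact frequency), augmented by the
minimal extra shift when the expected-corrected map still has non-positive
entries. The upstream profile at bin b sums `max(0, L[b,j] − L[b−1,j])`
over partners j within 600 kb on both sides (a domain start gains contacts
relative to its left neighbour); the downstream profile uses
`L[b,j] − L[b+1,j]`. This orientation is pinned by the two-block contract:
an ideal two-domain matrix puts the downstream maximum on the last bin of
the first domain and the upstream maximum on the first bin of the second.
The 600-kb cap is symmetric around each bin (a one-sided variant was
considered and rejected: the symmetric sum is what makes the mirror-symmetry
property hold exactly). Derivatives across masked bins are skipped.

**Peaks and boundaries.** Candidate peaks are strict local maxima (plateaus
take the leftmost bin). Within each compartment with ≥ 3 candidates, peaks
above `median(heights) + 2·1.48·MAD(heights)` are significant; smaller
compartments fall back to global statistics with a warning. A bin carrying
both significant peaks is a boundary; two consecutive bins carrying one
significant upstream and one significant downstream peak (either order —
the pair rule absorbs ±1-bin positional jitter of either peak) form a pair
boundary whose delimiter is their midpoint; remaining significant peaks are
orphans and are discarded. Boundaries are never allocated to masked bins.
Domains are the intervals between consecutive delimiters within a
compartment, reported in kb.

**Boundary annotation.** The environment of a boundary is ±2 bins; the
report summarizes gene content, median normRPK, highly-expressed-gene count,
median persistence and rRNA presence, and a Fisher test of leading-strand
co-orientation (gene strand vs replichore side relative to oriC) against
boundary membership.

## Synthetic generators

The generators emulate the statistical structure the analysis assumes, not
sequence-level data (no FASTQ, no mapping):

* **Genome**: ~2,000 genes of ~1 kb tiling 6.7 Mb; core genes at 80%
  probability in the center vs 15% in arms, SMBGC 25% in arms vs 2%, GI
  15% vs 1% — strong, unambiguous compartment contrast for enrichment
  tests.
* **Orthologs**: presence Bernoulli with compartment persistence (0.92
  central, 0.35 arms); target order co-linear, with planted reference-side
  island gaps and target-side insertions.
* **Counts**: negative-binomial totals (gamma-Poisson, squared CV 0.1) with
  phase×compartment means — arms 0.5 reads in exponential phase vs 200 in
  stationary (quiescent early, induced late), center ~300 throughout — and
  a binomial antisense split (arms 0.35 exponential → 0.10 stationary,
  center 0.03), reproducing the decreasing arm antisense index.
* **Contact maps**: intensity `(s+1)^−α` with α = 1 (primary diagonal
  visible to ~1 Mb), intra-domain enrichment by the boundary strength,
  optional tilted secondary anti-diagonal with Gaussian cross-section,
  multiplicative gamma noise of variance `arm_noise_mult − 1` on arm×arm
  entries, then Poisson sampling scaled to `n_pairs` (default 2 × 10⁶
  valid pairs, the depth used for comparative maps). Poisson (rather than
  negative-binomial) sampling keeps sampling noise separate from the
  planted biological variability, which is exactly the decomposition the
  dispersion index reads out.

What passing on synthetic data does **not** show: robustness to mapping
artefacts, copy-number and replication-associated coverage gradients,
restriction-site density bias (the generator plants uniform bins), or real
inter-replicate variability. The Tier of results that depends on the real
deposited data (exact boundary counts and domain sizes on the reference
chromosome) is out of desk-scale scope and is expected to be sensitive to
mapping and masking choices.

## Problem sizes and determinism

Validation runs use 670-bin maps (the 10-kb binning of the TIR-trimmed
chromosome) at 2 × 10⁶ pairs, 10 seeds for recovery and 20 for the null;
oracle comparisons use ≤ 30-gene toys and ≤ 20 margins, where exhaustive
enumeration is exact. All generators take explicit seeds; a pipeline run
writes its configuration next to its outputs and reruns byte-identically.

## Known limitations

* The null boundary rate of the caller on boundary-free Poisson maps is of
  the order of one boundary per 670-bin map — the median + 2·1.48·MAD peak
  rule combined with the consecutive-pair rule occasionally pairs two noise
  peaks. Real analyses should treat isolated weak boundaries with the
  orphan-peak caution the method itself applies.
* GOC counts adjacencies broken by any missing ortholog; panels of very
  distant genomes therefore depress GOC globally rather than locally.
* Island bp coordinates span from the end of the last upstream-block gene
  to the start of the first downstream-block gene; nested or overlapping
  rearrangements are fused rather than resolved.
* `annotate_boundaries` assumes a single linear chromosome and bins genes
  by midpoint; genes straddling bin edges are not split.
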