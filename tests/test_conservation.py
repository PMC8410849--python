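"""Orthology, persistence, GOC, synteny-break and enrichment statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strepfold.conservation import (
    BLAST_COLUMNS,
    call_genomic_islands,
    compute_goc_profile,
    compute_persistence,
    detect_synteny_blocks,
    fisher_enrichment,
    reciprocal_best_hits,
)
from strepfold.genome import GeneRecord

from conftest import make_ortholog_table


def hits_frame(rows):
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def hit(q, s, pident=80.0, evalue=1e-50, bitscore=200.0, length=300):
    return [q, s, pident, length, 0, 0, 1, length, 1, length, evalue, bitscore]


class TestReciprocalBestHits:
    def test_pair_passing_thresholds_in_both_directions_is_retained(self):
        fwd = hits_frame([hit("A", "X", pident=45.0)])
        rev = hits_frame([hit("X", "A", pident=45.0)])
        assert reciprocal_best_hits(fwd, rev) == [("A", "X")]

    def test_identity_thresholds_reject_weak_hits(self):
        fwd = hits_frame([hit("A", "X", pident=39.9)])
        rev = hits_frame([hit("X", "A", pident=80.0)])
        assert reciprocal_best_hits(fwd, rev) == []
        fwd = hits_frame([hit("A", "X", evalue=1e-9)])
        rev = hits_frame([hit("X", "A")])
        assert reciprocal_best_hits(fwd, rev) == []

    def test_coverage_filter_uses_query_length(self):
        fwd = hits_frame([hit("A", "X", length=300)])
        rev = hits_frame([hit("X", "A", length=300)])
        # 300/500 = 60% coverage < 70%
        assert reciprocal_best_hits(fwd, rev, query_lengths={"A": 500},
                                    subject_lengths={"X": 500}) == []
        assert reciprocal_best_hits(fwd, rev, query_lengths={"A": 400},
                                    subject_lengths={"X": 400}) == [("A", "X")]

    def test_self_comparison_maps_every_gene_to_itself(self):
        genes = ["A", "B", "C"]
        fwd = hits_frame([hit(g, g, bitscore=500) for g in genes]
                         + [hit("A", "B", bitscore=100)])
        pairs = reciprocal_best_hits(fwd, fwd)
        assert pairs == [(g, g) for g in genes]

    def test_non_reciprocal_best_hit_dropped(self):
        # A<->X mutual best; B's best is Y but Y's best is C
        fwd = hits_frame([hit("A", "X", bitscore=300), hit("B", "Y", bitscore=300)])
        rev = hits_frame([hit("X", "A", bitscore=300), hit("Y", "C", bitscore=400),
                          hit("Y", "B", bitscore=100)])
        assert reciprocal_best_hits(fwd, rev) == [("A", "X")]

    def test_ties_resolved_deterministically(self):
        # equal bitscore: lower evalue wins, then lexicographic subject
        fwd = hits_frame([hit("A", "X2", evalue=1e-50), hit("A", "X1", evalue=1e-50)])
        rev = hits_frame([hit("X1", "A"), hit("X2", "A")])
        assert reciprocal_best_hits(fwd, rev) == [("A", "X1")]

    def test_malformed_row_rejected_with_row_number(self):
        fwd = hits_frame([hit("A", "X")]).astype({"evalue": object})
        fwd.loc[0, "evalue"] = "oops"
        with pytest.raises(ValueError, match="row 0"):
            reciprocal_best_hits(fwd, hits_frame([hit("X", "A")]))


class TestPersistence:
    def test_fraction_of_genomes_with_ortholog(self):
        table = make_ortholog_table(
            {f"t{k}": ({0: 0, 1: 1} if k < 2 else {0: 0}) for k in range(4)}, 2
        )
        pers = compute_persistence(table)
        assert pers.loc[0, "persistence"] == 1.0
        assert pers.loc[1, "persistence"] == 0.5
        assert bool(pers.loc[0, "persistent_95"]) is True
        assert bool(pers.loc[1, "persistent_95"]) is False

    def test_absent_gene_has_zero_persistence(self):
        table = make_ortholog_table({"t": {0: 0}}, 2)
        assert compute_persistence(table).loc[1, "persistence"] == 0.0

    def test_no_genomes_is_an_error(self):
        table = make_ortholog_table({}, 3)
        with pytest.raises(ValueError):
            compute_persistence(table)


def goc_oracle(pres, tidx, window):
    """Brute-force GOC: explicit enumeration of conserved adjacencies."""
    g = len(pres)
    out = []
    for s in range(g - window + 1):
        idx = list(range(s, s + window))
        orth = [i for i in idx if pres[i]]
        if not orth:
            out.append(np.nan)
            continue
        contiguous = set()
        for i in idx:
            for j in idx:
                if j == i + 1 and pres[i] and pres[j] and abs(tidx[j] - tidx[i]) == 1:
                    contiguous.update((i, j))
        out.append(len(contiguous) / len(orth))
    return out


class TestGOC:
    def test_colinear_window_scores_one(self, colinear_table):
        goc = compute_goc_profile(colinear_table, "t", window=8)
        assert np.allclose(goc["goc"], 1.0)

    def test_window_without_orthologs_is_na(self):
        table = make_ortholog_table({"t": {0: 0, 1: 1}}, 12)
        goc = compute_goc_profile(table, "t", window=4)
        assert np.isnan(goc["goc"].iloc[-1])

    def test_one_conserved_pair_two_scattered(self):
        # 4 orthologs in the window: pair (0,1) adjacent in both, 2 scattered
        table = make_ortholog_table({"t": {0: 0, 1: 1, 3: 10, 5: 20}}, 8)
        goc = compute_goc_profile(table, "t", window=8)
        assert goc["goc"].iloc[0] == pytest.approx(0.5)

    def test_single_ortholog_scores_zero_not_na(self):
        table = make_ortholog_table({"t": {0: 0}}, 4)
        goc = compute_goc_profile(table, "t", window=4)
        assert goc["goc"].iloc[0] == 0.0

    def test_window_larger_than_genome_errors(self, colinear_table):
        with pytest.raises(ValueError):
            compute_goc_profile(colinear_table, "t", window=11)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(5, 30),
        window=st.integers(2, 8),
        seed=st.integers(0, 10_000),
    )
    def test_matches_bruteforce_oracle_on_random_permutations(self, n, window, seed):
        rng = np.random.default_rng(seed)
        pres = rng.random(n) < 0.7
        perm = rng.permutation(n)
        mapping = {int(i): int(perm[i]) for i in np.flatnonzero(pres)}
        table = make_ortholog_table({"t": mapping}, n)
        window = min(window, n)
        goc = compute_goc_profile(table, "t", window=window)["goc"].to_numpy()
        tidx = np.full(n, -1)
        for i, t in mapping.items():
            tidx[i] = t
        expect = goc_oracle(pres, tidx, window)
        assert np.allclose(goc, expect, equal_nan=True)

    def test_shuffled_target_order_drives_mean_goc_to_zero(self, rng):
        n = 200
        perm = rng.permutation(n)
        table = make_ortholog_table({"t": {i: int(perm[i]) for i in range(n)}}, n)
        goc = compute_goc_profile(table, "t", window=8)["goc"]
        assert goc.mean() < 0.15


class TestSyntenyBlocks:
    def test_colinear_genomes_give_single_block(self, colinear_table):
        blocks = detect_synteny_blocks(colinear_table, "t")
        assert len(blocks) == 1
        assert (blocks[0].ref_start, blocks[0].ref_end) == (0, 9)
        assert blocks[0].direction == "same"

    def test_hand_enumerated_breakpoints(self):
        # genes 1..5 (0-based 0..4) map to 1,2,7,8,3 -> blocks {0,1},{2,3}
        table = make_ortholog_table({"t": {0: 0, 1: 1, 2: 6, 3: 7, 4: 2}}, 5)
        blocks = detect_synteny_blocks(table, "t", min_block=2)
        spans = [(b.ref_start, b.ref_end) for b in blocks]
        assert spans == [(0, 1), (2, 3)]

    def test_inverted_segment_gets_inverted_direction(self):
        table = make_ortholog_table({"t": {0: 5, 1: 4, 2: 3}}, 3)
        blocks = detect_synteny_blocks(table, "t")
        assert len(blocks) == 1 and blocks[0].direction == "inverted"

    def test_no_orthologs_gives_empty_list(self):
        table = make_ortholog_table({"t": {}}, 5)
        assert detect_synteny_blocks(table, "t") == []


def _island_genes(n, trna=()):
    return [
        GeneRecord(f"g{i}", 1000 * i + 1, 1000 * i + 900, "+",
                   {"tRNA"} if i in trna else set())
        for i in range(n)
    ]


def _gapped_table(n, gap_lo, gap_hi, name="t"):
    """Co-linear mapping with reference genes [gap_lo, gap_hi] absent."""
    present = [i for i in range(n) if not gap_lo <= i <= gap_hi]
    return make_ortholog_table(
        {name: {i: rank for rank, i in enumerate(present)}}, n
    )


class TestGenomicIslands:
    def test_break_below_threshold_is_not_an_island(self):
        n = 40
        table = _gapped_table(n, 10, 23)  # 14-CDS reference gap
        genes = _island_genes(n)
        blocks = {"t": detect_synteny_blocks(table, "t")}
        assert call_genomic_islands(blocks, genes, table) == []

    def test_fifteen_cds_in_reference_only_is_an_island(self):
        n = 45
        table = _gapped_table(n, 10, 24)  # 15-CDS reference gap, 0 in target
        genes = _island_genes(n)
        blocks = {"t": detect_synteny_blocks(table, "t")}
        islands = call_genomic_islands(blocks, genes, table)
        assert len(islands) == 1
        isl = islands[0]
        assert not isl.is_insertion_point
        assert (isl.ref_gene_start, isl.ref_gene_end) == (10, 24)
        assert isl.cds_counts["t"] == (15, 0)

    def test_target_insertion_with_bare_reference_is_insertion_point(self):
        # target has 20 extra genes between reference neighbours 9 and 10
        n = 20
        mapping = {i: i for i in range(10)}
        mapping.update({i: i + 20 for i in range(10, n)})
        table = make_ortholog_table({"t": mapping}, n)
        genes = _island_genes(n)
        blocks = {"t": detect_synteny_blocks(table, "t")}
        islands = call_genomic_islands(blocks, genes, table)
        assert len(islands) == 1
        assert islands[0].is_insertion_point
        assert islands[0].cds_counts["t"] == (0, 20)

    def test_opposite_direction_flanking_blocks_are_skipped(self):
        n = 40
        mapping = {i: i for i in range(10)}
        # inverted downstream block after a 16-gene gap
        mapping.update({i: 60 - i for i in range(26, 36)})
        table = make_ortholog_table({"t": mapping}, n)
        genes = _island_genes(n)
        blocks = {"t": detect_synteny_blocks(table, "t")}
        assert call_genomic_islands(blocks, genes, table) == []

    def test_fusion_is_order_independent(self):
        n = 60
        t1 = _gapped_table(n, 10, 27, "a")
        t2 = _gapped_table(n, 20, 37, "b")
        genes = _island_genes(n)
        b1 = detect_synteny_blocks(t1, "a")
        b2 = detect_synteny_blocks(t2, "b")
        table = make_ortholog_table({}, n)
        table.presence.update({**t1.presence, **t2.presence})
        table.target_index.update({**t1.target_index, **t2.target_index})
        fwd = call_genomic_islands({"a": b1, "b": b2}, genes, table)
        rev = call_genomic_islands({"b": b2, "a": b1}, genes, table)
        assert len(fwd) == 1  # overlapping islands fused
        assert [(i.start_bp, i.end_bp) for i in fwd] == [
            (i.start_bp, i.end_bp) for i in rev
        ]
        assert sorted(fwd[0].supporting) == ["a", "b"]


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric two-sided p over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherEnrichment:
    def _genes(self, table):
        """Build genes realizing the 2x2 table (feature 'GI' x left arm)."""
        (a, b), (c, d) = table
        genes = []
        k = 0
        for count, feats, left in (
            (a, {"GI"}, True), (b, {"GI"}, False), (c, set(), True), (d, set(), False)
        ):
            for _ in range(count):
                pos = 1000 + k * 10 if left else 2_000_000 + k * 10
                genes.append(GeneRecord(f"f{k}", pos, pos + 5, "+", feats))
                k += 1
        return genes

    def test_balanced_table_gives_unit_odds_and_p(self, printed_partition):
        res = fisher_enrichment("GI", printed_partition,
                                self._genes([[10, 10], [10, 10]]),
                                compartments=("left",))
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_sample_odds_ratio_is_ad_over_bc(self, printed_partition):
        res = fisher_enrichment("GI", printed_partition,
                                self._genes([[5, 1], [2, 8]]),
                                compartments=("left",))
        assert res["odds_ratio"] == pytest.approx(20.0)
        assert res["table"] == [[5, 1], [2, 8]]

    def test_p_matches_exhaustive_enumeration(self, printed_partition):
        for table in ([[5, 1], [2, 8]], [[3, 7], [6, 2]], [[1, 9], [9, 1]],
                      [[4, 4], [4, 4]], [[0, 5], [5, 0]]):
            res = fisher_enrichment("GI", printed_partition, self._genes(table),
                                    compartments=("left",))
            expect = fisher_two_sided_oracle(*table[0], *table[1])
            assert res["p_value"] == pytest.approx(expect, rel=1e-9)

    def test_empty_gene_list_errors(self, printed_partition):
        with pytest.raises(ValueError):
            fisher_enrichment("GI", printed_partition, [])
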