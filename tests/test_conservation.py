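"""Chain lifting against a per-base oracle; six-category classification."""

import numpy as np
import pytest

from circpipe import simulate as sim
from circpipe.conservation import (
    CATEGORIES,
    LiftResult,
    classify_conservation,
    conserve,
    conserve_all,
    lift_interval,
    summarize_categories,
)
from circpipe.types import Chain, ChainBlock, ChainSet, CircDbRecord, GenomicInterval


def identity_chain(length=1000, name="chr1", target="hchr1"):
    return ChainSet([Chain(100.0, name, length, "+", 0, length,
                           target, length, "+", 0, length,
                           [ChainBlock(length)], 1)])


# -- independent per-base oracle ------------------------------------------

def oracle_map_base(chain, pos):
    """Map a single source base through a chain by walking its blocks."""
    s, t = chain.source_start, chain.target_start
    for b in chain.blocks:
        if s <= pos < s + b.size:
            tf = t + (pos - s)
            return chain.target_size - 1 - tf if chain.target_strand == "-" else tf
        s += b.size + b.source_gap
        t += b.size + b.target_gap
    return None


def oracle_lift(chains, query, min_ratio=0.95):
    cands = [c for c in chains
             if c.source_name == query.chrom
             and c.source_start < query.end and query.start < c.source_end]
    if not cands:
        return None
    best = max(c.score for c in cands)
    chain = min((c for c in cands if c.score == best), key=lambda c: c.chain_id)
    hits = [oracle_map_base(chain, p) for p in range(query.start, query.end)]
    hits = [h for h in hits if h is not None]
    if not hits or len(hits) / len(query) < min_ratio:
        return None
    return (chain.target_name, min(hits), max(hits) + 1)


class TestLiftInterval:
    def test_identity_chain_maps_to_itself(self):
        res = lift_interval(identity_chain(), GenomicInterval("chr1", 10, 20))
        assert res.mapped and res.remap_ratio == 1.0
        assert (res.target.chrom, res.target.start, res.target.end) == ("hchr1", 10, 20)

    def test_target_gap_shifts_downstream_coordinates(self):
        # 50-base block, 10-base target gap, 50-base block
        chain = ChainSet([Chain(100.0, "chr1", 1000, "+", 0, 100,
                                "hchr1", 1000, "+", 0, 110,
                                [ChainBlock(50, 0, 10), ChainBlock(50)], 1)])
        res = lift_interval(chain, GenomicInterval("chr1", 60, 70))
        assert res.mapped
        assert (res.target.start, res.target.end) == (70, 80)

    def test_query_inside_source_gap_is_unmapped(self):
        chain = ChainSet([Chain(100.0, "chr1", 1000, "+", 0, 110,
                                "hchr1", 1000, "+", 0, 100,
                                [ChainBlock(50, 10, 0), ChainBlock(50)], 1)])
        res = lift_interval(chain, GenomicInterval("chr1", 52, 58))
        assert not res.mapped

    def test_unknown_chromosome_unmapped(self):
        assert not lift_interval(identity_chain(), GenomicInterval("chrX", 5, 6)).mapped

    def test_min_ratio_boundary(self):
        # 95 of 100 bases in blocks: ratio exactly 0.95 -> mapped (inclusive)
        chain = ChainSet([Chain(100.0, "chr1", 1000, "+", 0, 100,
                                "hchr1", 1000, "+", 0, 95,
                                [ChainBlock(50, 5, 0), ChainBlock(45)], 1)])
        assert lift_interval(chain, GenomicInterval("chr1", 0, 100)).mapped
        # 94 of 100 -> unmapped
        chain2 = ChainSet([Chain(100.0, "chr1", 1000, "+", 0, 100,
                                 "hchr1", 1000, "+", 0, 94,
                                 [ChainBlock(50, 6, 0), ChainBlock(44)], 1)])
        assert not lift_interval(chain2, GenomicInterval("chr1", 0, 100)).mapped

    def test_inverting_chain_flips_strand_and_coordinates(self):
        L = 100
        chain = ChainSet([Chain(100.0, "chr1", L, "+", 0, L,
                                "hchr1", L, "-", 0, L, [ChainBlock(L)], 1)])
        res = lift_interval(chain, GenomicInterval("chr1", 10, 20, "+"))
        assert res.mapped and res.target.strand == "-"
        assert (res.target.start, res.target.end) == (L - 20, L - 10)

    def test_full_interval_mode_uses_lifted_interval_ends(self):
        from circpipe.conservation import lift_circ_ends

        chain = ChainSet([Chain(100.0, "chr1", 1000, "+", 0, 100,
                                "hchr1", 1000, "+", 0, 110,
                                [ChainBlock(50, 0, 10), ChainBlock(50)], 1)])
        l5, l3 = lift_circ_ends(chain, GenomicInterval("chr1", 10, 90, "+"),
                                full_interval=True)
        assert l5.mapped and l3.mapped
        assert l5.target.start == 10
        assert l3.target.start == 99  # last base of [10, 100) on the target
        # a gap inside the body fails the 0.95 ratio in full-interval mode
        gappy = ChainSet([Chain(100.0, "chr1", 1000, "+", 0, 110,
                                "hchr1", 1000, "+", 0, 100,
                                [ChainBlock(50, 10, 0), ChainBlock(50)], 1)])
        g5, g3 = lift_circ_ends(gappy, GenomicInterval("chr1", 10, 100, "+"),
                                full_interval=True)
        assert not g5.mapped and not g3.mapped
        # whereas the 1-base flank mode lifts both ends fine
        f5, f3 = lift_circ_ends(gappy, GenomicInterval("chr1", 10, 100, "+"))
        assert f5.mapped and f3.mapped

    def test_equal_score_tie_breaks_to_lowest_chain_id(self):
        c1 = Chain(100.0, "chr1", 1000, "+", 0, 100, "hchrA", 1000, "+", 0, 100,
                   [ChainBlock(100)], 2)
        c2 = Chain(100.0, "chr1", 1000, "+", 0, 100, "hchrB", 1000, "+", 500, 600,
                   [ChainBlock(100)], 1)
        res = lift_interval(ChainSet([c1, c2]), GenomicInterval("chr1", 10, 11))
        assert res.target.chrom == "hchrB"

    def test_agrees_with_per_base_oracle_on_random_chains(self):
        """Block-walking lift equals the brute-force per-base map."""
        rng = np.random.default_rng(0)
        checked = 0
        for rep in range(300):
            chains = sim.gen_chain(int(rng.integers(2**31)), source_length=500,
                                   n_blocks=int(rng.integers(1, 8)),
                                   gap_model=(0, 15),
                                   inversion_prob=0.3)
            for _ in range(4):
                start = int(rng.integers(0, 490))
                length = int(rng.integers(1, 10))
                q = GenomicInterval("chr1", start, start + length)
                got = lift_interval(chains, q, min_ratio=0.95)
                exp = oracle_lift(chains, q, min_ratio=0.95)
                if exp is None:
                    assert not got.mapped
                else:
                    assert got.mapped
                    assert (got.target.chrom, got.target.start, got.target.end) == exp
                checked += 1
        assert checked >= 1000


# -- classification --------------------------------------------------------

def mapped(chrom, pos):
    return LiftResult("mapped", GenomicInterval(chrom, pos, pos + 1, "+"), 1.0)


DB = [CircDbRecord("R1", GenomicInterval("hchr1", 1000, 2000, "."))]


class TestClassify:
    def test_exact_ends_are_homologous(self):
        call = classify_conservation("c", mapped("hchr1", 1000), mapped("hchr1", 1999), DB)
        assert call.category == "homologous" and call.matched_db_ids == ["R1"]

    def test_plus_two_offset_still_matches(self):
        call = classify_conservation("c", mapped("hchr1", 1002), mapped("hchr1", 1997), DB)
        assert call.category == "homologous"

    def test_plus_three_offset_does_not_match(self):
        call = classify_conservation("c", mapped("hchr1", 1003), mapped("hchr1", 5000), DB)
        assert call.category == "no_homologous"

    def test_five_prime_only(self):
        call = classify_conservation("c", mapped("hchr1", 1002), mapped("hchr1", 5000), DB)
        assert call.category == "five_prime_utilized"

    def test_three_prime_only(self):
        call = classify_conservation("c", mapped("hchr1", 5000), mapped("hchr1", 2001), DB)
        assert call.category == "three_prime_utilized"

    def test_both_sites_by_different_records(self):
        db = [CircDbRecord("R1", GenomicInterval("hchr1", 1000, 1500, ".")),
              CircDbRecord("R2", GenomicInterval("hchr1", 1800, 2400, "."))]
        call = classify_conservation("c", mapped("hchr1", 1000), mapped("hchr1", 2399), db)
        assert call.category == "both_sites_utilized"
        assert call.matched_db_ids == ["R1", "R2"]

    def test_unlifted_end_is_not_aligned(self):
        call = classify_conservation("c", LiftResult("unmapped"), mapped("hchr1", 1999), DB)
        assert call.category == "not_aligned"

    def test_wrong_chromosome_no_match(self):
        call = classify_conservation("c", mapped("hchr2", 1000), mapped("hchr2", 1999), DB)
        assert call.category == "no_homologous"

    def test_tolerance_monotonicity(self):
        """Raising the tolerance never demotes a circRNA's category."""
        rank = {c: i for i, c in enumerate(CATEGORIES)}
        rng = np.random.default_rng(5)
        for _ in range(200):
            p5 = int(rng.integers(990, 1010))
            p3 = int(rng.integers(1990, 2010))
            prev = -1
            for tol in (0, 1, 2, 4, 8):
                cat = classify_conservation(
                    "c", mapped("hchr1", p5), mapped("hchr1", p3), DB, tolerance_nt=tol
                ).category
                assert rank[cat] >= prev
                prev = rank[cat]


class TestPlantedCategories:
    def test_planted_recovery_is_exact(self, truth, chains, circ_db):
        calls = conserve_all(
            [(f"c{i}", tc.interval) for i, tc in enumerate(truth.true_circs)],
            chains, circ_db,
        )
        for call, tc in zip(calls, truth.true_circs):
            assert call.category == tc.category

    def test_category_partition(self, truth, chains, circ_db):
        calls = conserve_all(
            [(f"c{i}", tc.interval) for i, tc in enumerate(truth.true_circs)],
            chains, circ_db,
        )
        table = summarize_categories(calls)
        assert table["count"].sum() == len(calls)
        assert abs(table["percent"].sum() - 100.0) < 1e-9


class TestSummary:
    def test_single_homologous_circ_is_100_percent(self):
        call = classify_conservation("c", mapped("hchr1", 1000), mapped("hchr1", 1999), DB)
        table = summarize_categories([call])
        row = table.set_index("category")
        assert row.loc["homologous", "percent"] == 100.0

    def test_denominator_includes_unlifted(self):
        calls = [classify_conservation("a", mapped("hchr1", 1000), mapped("hchr1", 1999), DB),
                 classify_conservation("b", LiftResult("unmapped"), LiftResult("unmapped"), DB)]
        table = summarize_categories(calls).set_index("category")
        assert table.loc["homologous", "percent"] == 50.0
        assert table.loc["not_aligned", "percent"] == 50.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_categories([])
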