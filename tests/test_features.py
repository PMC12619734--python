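"""Length gate, DTR detection, synteny links and block chaining."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from jumboclade import features
from jumboclade.features import SyntenyLink
from jumboclade.records import GenomeRecord

from oracle import largest_terminal_repeat


def _genome(gid, length):
    rng = random.Random(hash(gid) % 2**31)
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    return GenomeRecord(gid, seq)


class TestLengthGate:
    def test_boundary_is_strict(self):
        # a contig of exactly 200,000 bp is not "> 200 kbp"
        kept = features.length_gate([_genome("edge", 200_000)])
        assert kept == []

    def test_smallest_retained_jumbo_length_passes(self):
        kept = features.length_gate([_genome("small_jumbo", 200_148)])
        assert len(kept) == 1

    def test_empty_input(self):
        assert features.length_gate([]) == []


class TestDetectDTR:
    def test_constructed_repeat_exact(self):
        rng = random.Random(0)
        x = "".join(rng.choice("ACGT") for _ in range(50))
        y = "".join(rng.choice("ACGT") for _ in range(5000))
        res = features.detect_dtr(x + y + x)
        assert res.repeat_len == 50
        assert res.complete
        assert res.repeat_seq == x

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.integers(60, 400), st.integers(0, 2**31))
    def test_repeat_at_least_planted_length(self, xlen, ylen, seed):
        rng = random.Random(seed)
        x = "".join(rng.choice("ACGT") for _ in range(xlen))
        y = "".join(rng.choice("ACGT") for _ in range(ylen))
        res = features.detect_dtr(x + y + x, min_dtr_len=1)
        assert res.repeat_len >= xlen

    def test_matches_upward_scan_oracle_on_random_sequence(self):
        rng = random.Random(7)
        for _ in range(10):
            seq = "".join(rng.choice("ACGT") for _ in range(2000))
            res = features.detect_dtr(seq)
            assert res.repeat_len == largest_terminal_repeat(seq)
            assert not res.complete  # chance 21-mer repeat is ~1e-7

    def test_homopolymer_capped_and_flagged(self):
        res = features.detect_dtr("A" * 1000)
        assert res.repeat_len == 500  # floor(n/2) cap
        assert res.low_complexity_flag

    def test_two_letter_repeat_flagged(self):
        res = features.detect_dtr("AT" * 20 + "GGCC" * 300 + "AT" * 20)
        assert res.repeat_len >= 40
        assert res.low_complexity_flag

    def test_too_short_sequence_warns(self, caplog):
        with caplog.at_level("WARNING"):
            res = features.detect_dtr("ACGTACGT", min_dtr_len=21)
        assert res.repeat_len == 0
        assert not res.complete

    def test_planted_dtrs_recovered_in_simulation(self, small_clade):
        for g in small_clade.genomes:
            res = features.detect_dtr(g)
            planted = small_clade.truth.dtr_len[g.genome_id]
            if planted > 0:
                assert res.repeat_len == planted
            else:
                assert not res.complete


def _links(pairs):
    """Build links from (a_index, b_index); bp coords 1000 per gene."""
    return [
        SyntenyLink(gene_a=f"a{ai}", gene_b=f"b{bi}", a_index=ai, b_index=bi,
                    a_start=ai * 1000 + 1, a_end=ai * 1000 + 900,
                    b_start=bi * 1000 + 1, b_end=bi * 1000 + 900,
                    pct_identity=90.0)
        for ai, bi in pairs
    ]


class TestChainBlocks:
    def test_colinear_single_forward_block(self):
        links = _links([(i, i) for i in range(12)])
        blocks = features.chain_blocks(links)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert len(blocks[0].links) == 12

    def test_no_links_no_blocks(self):
        assert features.chain_blocks([]) == []

    def test_single_inversion_recovered_with_flanks(self):
        # genes 4..9 inverted in genome b
        order = list(range(4)) + list(range(9, 3, -1)) + list(range(10, 16))
        links = _links(list(enumerate(order)))
        blocks = features.chain_blocks(links)
        orientations = [b.orientation for b in blocks]
        assert orientations == ["forward", "inverted", "forward"]
        inv = blocks[1]
        assert [l.b_index for l in inv.links] == [9, 8, 7, 6, 5, 4]

    def test_minimum_length_inversion_recovered(self):
        # a 3-gene inversion whose junction step equals the gap limit
        order = [0, 1, 2, 3, 6, 5, 4, 7, 8, 9]
        blocks = features.chain_blocks(_links(list(enumerate(order))))
        inv = [b for b in blocks if b.orientation == "inverted"]
        assert len(inv) == 1
        assert [l.b_index for l in inv[0].links] == [6, 5, 4]

    def test_blocks_are_link_disjoint_and_monotone(self):
        rng = random.Random(11)
        order = list(range(40))
        # a few local shuffles and one inversion
        order[10:16] = order[15:9:-1]
        order[25], order[27] = order[27], order[25]
        blocks = features.chain_blocks(_links(list(enumerate(order))))
        seen = set()
        for b in blocks:
            bids = [l.b_index for l in b.links]
            steps = [y - x for x, y in zip(bids, bids[1:])]
            if b.orientation == "forward":
                assert all(s > 0 for s in steps)
            else:
                assert all(s < 0 for s in steps)
            for l in b.links:
                assert (l.gene_a, l.gene_b) not in seen
                seen.add((l.gene_a, l.gene_b))

    def test_shuffled_order_yields_only_fragmentary_blocks(self):
        rng = random.Random(13)
        n = 30
        for _ in range(20):
            order = list(range(n))
            rng.shuffle(order)
            blocks = features.chain_blocks(_links(list(enumerate(order))))
            assert all(len(b.links) < n // 2 for b in blocks)


class TestSyntenyLinks:
    def test_identical_genomes_link_diagonally(self, sibling_pair):
        from jumboclade import homology
        ga = sibling_pair.genes["sim00"]
        hits = homology.best_hits({g.gene_id: g.protein for g in ga},
                                  {g.gene_id: g.protein for g in ga})
        links = features.synteny_links(ga, ga, hits)
        assert len(links) == len(ga)
        assert all(l.a_index == l.b_index for l in links)

    def test_no_homology_no_links(self, sibling_pair):
        ga = sibling_pair.genes["sim00"]
        links = features.synteny_links(ga, ga, [])
        assert links == []
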