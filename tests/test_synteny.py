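"""Anchor construction, block chaining, homology classification, depth."""

import numpy as np
import pytest

from helpers import best_chain_oracle, block_from_ranks, make_table, pairs_between

from karyoforge.synteny import (
    ChainParams,
    build_anchors,
    chain_anchors,
    classify_chromosome_homology,
    coverage,
    filter_blocks,
    syntenic_depth,
)


def _chain(mapping_a_b, max_gap=25, min_pairs=5, sizes=(40, 40)):
    ta = make_table("A", {"c1": sizes[0]})
    tb = make_table("B", {"d1": sizes[1]})
    pairs = pairs_between(ta, tb, [("c1", ra, "d1", rb) for ra, rb in mapping_a_b])
    anchors = build_anchors(ta, tb, pairs)
    return chain_anchors(anchors, ChainParams(max_gap=max_gap, min_pairs=min_pairs), "A", "B")


def test_perfect_collinear_run_is_one_plus_block():
    blocks = _chain([(i, i) for i in range(10)])
    assert len(blocks) == 1
    b = blocks[0]
    assert b.n_pairs == 10 and b.orientation == "+"
    assert b.span_a == (0, 9) and b.span_b == (0, 9)


def test_reversed_run_is_minus_block():
    blocks = _chain([(i, 20 - i) for i in range(10)])
    assert len(blocks) == 1
    assert blocks[0].orientation == "-" and blocks[0].n_pairs == 10


def test_gap_larger_than_max_gap_splits_blocks():
    mapping = [(i, i) for i in range(6)] + [(i, i) for i in range(20, 26)]
    blocks = _chain(mapping, max_gap=5, min_pairs=5)
    assert len(blocks) == 2
    assert sorted(b.n_pairs for b in blocks) == [6, 6]


def test_min_pairs_filters_short_chains():
    blocks = _chain([(i, i) for i in range(4)], min_pairs=5)
    assert blocks == []


def test_anchors_conserved_and_strictly_monotone():
    rng = np.random.default_rng(0)
    mapping = sorted({(int(a), int(b)) for a, b in rng.integers(0, 40, size=(60, 2))})
    blocks = _chain(mapping, max_gap=10, min_pairs=3)
    assert blocks
    input_pairs = set(mapping)
    for b in blocks:
        ra = [a.rank_a for a in b.anchors]
        rb = [a.rank_b for a in b.anchors]
        assert all((x, y) in input_pairs for x, y in zip(ra, rb))
        assert all(0 < ra[i + 1] - ra[i] <= 10 for i in range(len(ra) - 1))
        step = 1 if b.orientation == "+" else -1
        assert all(0 < step * (rb[i + 1] - rb[i]) <= 10 for i in range(len(rb) - 1))


def test_orientation_flip_symmetry():
    mapping = [(i, i) for i in range(8)]
    fwd = _chain(mapping)
    rev = _chain([(a, 39 - b) for a, b in mapping])
    assert len(fwd) == len(rev) == 1
    assert fwd[0].n_pairs == rev[0].n_pairs
    assert fwd[0].orientation == "+" and rev[0].orientation == "-"


def test_chaining_deterministic():
    rng = np.random.default_rng(1)
    mapping = sorted({(int(a), int(b)) for a, b in rng.integers(0, 40, size=(80, 2))})
    b1 = _chain(mapping, max_gap=8, min_pairs=3)
    b2 = _chain(mapping, max_gap=8, min_pairs=3)
    assert b1 == b2


def test_chain_matches_oracle_small():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(1, 13))
        pts = sorted({(int(a), int(b)) for a, b in rng.integers(0, 25, size=(n, 2))})
        gap = int(rng.integers(3, 9))
        blocks = _chain(pts, max_gap=gap, min_pairs=2)
        got = max((b.n_pairs for b in blocks), default=1)
        ra = [p[0] for p in pts]
        rb = [p[1] for p in pts]
        want = best_chain_oracle(ra, rb, gap)
        if want >= 2:
            assert got == want
        else:
            assert blocks == []


def test_build_anchors_skips_unknown_genes():
    from karyoforge.io import HomologyPair

    ta = make_table("A", {"c1": 3})
    tb = make_table("B", {"d1": 3})
    pairs = pairs_between(ta, tb, [("c1", 0, "d1", 0)]) + [HomologyPair("ghost", "phantom", 1e-20, 100.0)]
    anchors = build_anchors(ta, tb, pairs)
    assert len(anchors) == 1
    assert build_anchors.last_skipped == 1


def test_self_mode_drops_identity_diagonal():
    t = make_table("A", {"c1": 20})
    mapping = [("c1", i, "c1", i) for i in range(20)]
    pairs = pairs_between(t, t, mapping)
    anchors = build_anchors(t, t, pairs)
    params = ChainParams(max_gap=25, min_pairs=5, self_mode=True)
    blocks = filter_blocks(chain_anchors(anchors, params, "A", "A"), params)
    assert blocks == []


def test_coverage_fraction_exact():
    t = make_table("A", {"c1": 20})
    b = block_from_ranks("x", "A", "B", "c1", "d1", [(2, 0), (6, 4)])
    cov = coverage([b], t, side="a")
    assert cov[("c1", "d1")] == pytest.approx(5 / 20)


def test_classify_whole_vs_segmental():
    ta = make_table("A", {"c1": 30})
    tb = make_table("B", {"d1": 30, "d2": 30})
    whole = block_from_ranks("w", "A", "B", "c1", "d1", [(i, i) for i in range(0, 30, 1)])
    seg = block_from_ranks("s", "A", "B", "c1", "d2", [(i, i) for i in range(5)])
    rel = classify_chromosome_homology([whole, seg], ta, tb, theta_whole=0.6)
    assert rel[("c1", "d1")] == "whole"
    assert rel[("c1", "d2")] == "segmental"


def test_classify_whole_requires_mutual_top_partner():
    ta = make_table("A", {"c1": 30})
    tb = make_table("B", {"d1": 30, "d2": 30})
    b1 = block_from_ranks("b1", "A", "B", "c1", "d1", [(i, i) for i in range(20)])
    # d2 covers c1 better, so c1's top partner is d2 and (c1, d1) cannot be whole
    b2 = block_from_ranks("b2", "A", "B", "c1", "d2", [(i, i) for i in range(25)])
    rel = classify_chromosome_homology([b1, b2], ta, tb, theta_whole=0.6)
    assert rel[("c1", "d1")] == "segmental"


def test_classify_arm_relation():
    ta = make_table("A", {"c1": 40})
    tb = make_table("B", {"d1": 20})
    # d1 maps entirely into the left arm of c1 (centromere at rank 20)
    b = block_from_ranks("b", "A", "B", "c1", "d1", [(i, i) for i in range(18)])
    rel = classify_chromosome_homology(
        [b], ta, tb, theta_whole=0.9, theta_arm=0.6,
        centromeres={("A", "c1"): 20}, classify_arms=True,
    )
    assert rel[("c1", "d1")] == "arm"


def test_syntenic_depth_counts_overlapping_spans():
    ref = make_table("R", {"c1": 10})
    b1 = block_from_ranks("b1", "R", "T", "c1", "t1", [(0, 0), (5, 5)])
    b2 = block_from_ranks("b2", "R", "T", "c1", "t2", [(3, 0), (8, 5)])
    prof = syntenic_depth([b1, b2], ref)
    d = prof.depths["c1"]
    assert list(d) == [1, 1, 1, 2, 2, 2, 1, 1, 1, 0]
    assert prof.modal_ratio == "1:1" and not prof.no_signal


def test_syntenic_depth_no_signal():
    ref = make_table("R", {"c1": 5})
    prof = syntenic_depth([], ref)
    assert prof.no_signal and prof.modal_ratio == "0:1"


def test_chain_params_validation():
    with pytest.raises(ValueError):
        ChainParams(max_gap=0)
    with pytest.raises(ValueError):
        ChainParams(min_pairs=1)
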