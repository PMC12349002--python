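"""Two-round reconstruction, representative selection, painting, arm mapping."""

import pytest

from helpers import block_from_ranks, make_table

from karyoforge.ancestor import (
    ArmTable,
    BlockIndex,
    Painting,
    Segment,
    assign_round2,
    karyotype_from_genome,
    map_blocks_to_arms,
    project_karyotype,
    seed_round1,
    select_representatives,
    ProtoBuild,
)


# -- round 1 ----------------------------------------------------------------


def _tables(sizes_by_species):
    return {sp: make_table(sp, sizes) for sp, sizes in sizes_by_species.items()}


def test_seed_round1_transitive_unification():
    tables = _tables({"A": {"c1": 10}, "B": {"d1": 10}, "C": {"e1": 10}})
    relations = {
        ("A", "B"): {("c1", "d1"): "whole"},
        ("B", "C"): {("d1", "e1"): "whole"},
        ("A", "C"): {},
    }
    seeds = seed_round1(relations, ["A", "B", "C"], tables)
    assert len(seeds) == 1
    assert seeds[0].members == {("A", "c1"), ("B", "d1"), ("C", "e1")}
    assert seeds[0].round1


def test_seed_round1_two_copies_allowed_for_wgd():
    tables = _tables({"A": {"c1": 10}, "B": {"d1": 10, "d2": 10}})
    relations = {("A", "B"): {("c1", "d1"): "whole", ("c1", "d2"): "whole"}}
    seeds = seed_round1(relations, ["A", "B"], tables)
    assert len(seeds) == 1
    assert seeds[0].members == {("A", "c1"), ("B", "d1"), ("B", "d2")}


def test_seed_round1_three_copies_is_conflict():
    tables = _tables({"A": {"c1": 10}, "B": {"d1": 10, "d2": 10, "d3": 10}})
    relations = {
        ("A", "B"): {("c1", "d1"): "whole", ("c1", "d2"): "whole", ("c1", "d3"): "whole"}
    }
    with pytest.raises(ValueError, match="conflicting seed unification"):
        seed_round1(relations, ["A", "B"], tables)


# -- round 2 ----------------------------------------------------------------


def _diag(n, off_a=0, off_b=0):
    return [(off_a + i, off_b + i) for i in range(n)]


def test_assign_round2_requires_min_species():
    tables = _tables({"A": {"c1": 20}, "B": {"d1": 20}, "C": {"e1": 20}, "D": {"f1": 20}})
    proto = ProtoBuild(round1=True)
    proto.candidates = [Segment("A", "c1", 0, 19), Segment("B", "d1", 0, 19)]
    proto.members = {("A", "c1"), ("B", "d1")}
    # C's residual links to A only -> supporters {A} + itself = 2 < 3
    weak = {("C", "A"): [block_from_ranks("w", "C", "A", "e1", "c1", _diag(8))]}
    assigned, unassigned = assign_round2([("C", "e1")], [proto], BlockIndex(weak), tables, min_species=3)
    assert assigned == []
    assert unassigned[0]["reason"] == "insufficient support"
    # linking to both A and B meets the threshold (2 supporters + itself)
    strong = {
        ("C", "A"): [block_from_ranks("x", "C", "A", "e1", "c1", _diag(8))],
        ("C", "B"): [block_from_ranks("y", "C", "B", "e1", "d1", _diag(8))],
    }
    proto2 = ProtoBuild(round1=True)
    proto2.candidates = list(proto.candidates)
    proto2.members = set(proto.members)
    assigned, _ = assign_round2([("C", "e1")], [proto2], BlockIndex(strong), tables, min_species=3)
    assert len(assigned) == 1
    seg = assigned[0]["segment"]
    assert (seg.species, seg.chromosome, seg.rank_lo, seg.rank_hi) == ("C", "e1", 0, 7)


# -- representative selection ----------------------------------------------


def test_representative_prefers_intact_chromosome_over_dense_fragment():
    """A short, fully anchored fragment must not outrank an intact chromosome
    carrying far more of the region (regression for the coverage-vs-density
    scoring defect)."""
    tables = _tables({"A": {"c1": 100}, "B": {"d1": 100}, "C": {"e1": 100, "e9": 10}})
    proto = ProtoBuild(round1=True)
    proto.candidates = [
        Segment("A", "c1", 0, 99),
        Segment("B", "d1", 0, 99),
        Segment("C", "e9", 0, 4),  # translocated 5-gene fragment, fully anchored
    ]
    proto.members = {(s.species, s.chromosome) for s in proto.candidates}
    blocks = {
        ("A", "B"): [block_from_ranks("ab", "A", "B", "c1", "d1", _diag(90))],
        ("A", "C"): [block_from_ranks("ac", "A", "C", "c1", "e9", _diag(5, off_a=40))],
        ("B", "C"): [block_from_ranks("bc", "B", "C", "d1", "e9", _diag(5, off_a=40))],
    }
    karyotype = select_representatives([proto], BlockIndex(blocks), tables, ["A", "B", "C"])
    reps = karyotype.protos[0].segments
    assert len(reps) == 1
    assert (reps[0].species, reps[0].chromosome) == ("A", "c1")
    # trimmed to the anchor hull of the region
    assert reps[0].rank_lo == 0 and reps[0].rank_hi == 89


def test_representative_trims_fusion_to_homologous_part():
    """A fusion chromosome winning a region contributes only its anchored span."""
    tables = _tables({"A": {"c1": 200}, "B": {"d1": 80}, "C": {"e1": 80}})
    proto = ProtoBuild(round1=True)
    proto.candidates = [Segment("A", "c1", 0, 199), Segment("B", "d1", 0, 79), Segment("C", "e1", 0, 79)]
    proto.members = {(s.species, s.chromosome) for s in proto.candidates}
    # only the first 80 ranks of c1 belong to this region; d1 and e1 each carry
    # less of it, so c1 wins on coverage but must be trimmed to its anchor hull
    blocks = {
        ("A", "B"): [block_from_ranks("ab", "A", "B", "c1", "d1", _diag(70))],
        ("A", "C"): [block_from_ranks("ac", "A", "C", "c1", "e1", _diag(75, off_a=5, off_b=5))],
    }
    karyotype = select_representatives([proto], BlockIndex(blocks), tables, ["A", "B", "C"])
    reps = karyotype.protos[0].segments
    assert (reps[0].species, reps[0].chromosome, reps[0].rank_lo, reps[0].rank_hi) == ("A", "c1", 0, 79)


def test_karyotype_from_genome_orders_by_size():
    t = make_table("sp", {"small": 5, "big": 9})
    k = karyotype_from_genome(t)
    assert k.proto_ids() == ["AGK1", "AGK2"]
    assert k.protos[0].segments[0].chromosome == "big"
    assert k.protos[0].gene_count == 9


# -- painting ---------------------------------------------------------------


def test_project_largest_block_wins_overlap():
    agk = make_table("AGK", {"AGK1": 30, "AGK2": 30})
    target = make_table("T", {"t1": 30})
    big = block_from_ranks("big", "AGK", "T", "AGK1", "t1", _diag(20))
    small = block_from_ranks("small", "AGK", "T", "AGK2", "t1", _diag(6, off_b=10), "+")
    painting = project_karyotype(agk, target, [big, small])
    lab = painting.labels["t1"]
    assert all(x == "AGK1" for x in lab[:20])
    assert all(x is None for x in lab[20:])


def test_project_smoothing_absorbs_short_discordant_run():
    agk = make_table("AGK", {"AGK1": 40, "AGK2": 40})
    target = make_table("T", {"t1": 40})
    left = block_from_ranks("l", "AGK", "T", "AGK1", "t1", _diag(15))
    island = block_from_ranks("i", "AGK", "T", "AGK2", "t1", _diag(2, off_b=15))
    right = block_from_ranks("r", "AGK", "T", "AGK1", "t1", _diag(15, off_b=17))
    painting = project_karyotype(agk, target, [left, island, right], smooth_window=30)
    lab = painting.labels["t1"]
    assert all(x == "AGK1" for x in lab[:32])
    # pre-smoothing assignment retained as support
    assert painting.support["t1"][15] == "AGK2"


def test_project_unpainted_stays_na():
    agk = make_table("AGK", {"AGK1": 10})
    target = make_table("T", {"t1": 10})
    painting = project_karyotype(agk, target, [])
    assert painting.painted_fraction() == 0.0


def test_painting_segments_round_trip_semantics():
    p = Painting("sp", {"c": ["A", "A", None, "B", "B", "B"]})
    segs = p.segments
    assert [(s.start_rank, s.end_rank, s.proto_id) for s in segs] == [
        (0, 1, "A"), (2, 2, None), (3, 5, "B")
    ]
    assert Painting.from_segments("sp", segs).labels == p.labels


# -- arms -------------------------------------------------------------------


def test_arm_table_validation():
    with pytest.raises(ValueError, match="outside"):
        ArmTable.from_centromeres({"AGK1": 10}, {"AGK1": 10})
    arms = ArmTable.from_centromeres({"AGK1": 4}, {"AGK1": 10})
    assert arms.arm_lengths["AGK1"] == (4, 6)
    assert arms.arms() == ["AGK1L", "AGK1R"]


def test_map_blocks_to_arms_ties_go_left():
    arms = ArmTable.from_centromeres({"AGK1": 5}, {"AGK1": 10})
    left = block_from_ranks("l", "AGK", "T", "AGK1", "t", _diag(4))            # ranks 0-3: L
    tie = block_from_ranks("t", "AGK", "T", "AGK1", "t", [(3, 0), (6, 3)])     # 2 ranks each side
    right = block_from_ranks("r", "AGK", "T", "AGK1", "t", _diag(3, off_a=6))  # ranks 6-8: R
    counts, labels = map_blocks_to_arms([left, tie, right], arms)
    assert counts == {"AGK1L": 2, "AGK1R": 1}
    assert dict(labels)["t"] == "AGK1L"
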