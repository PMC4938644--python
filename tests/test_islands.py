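import numpy as np
import pytest

from conftest import random_seq
from exonpatch.islands import (
    BoundarySignal,
    detect_boundaries,
    grow_island,
    islands_for_template,
    local_align_reads,
)
from exonpatch.seqio import ReadSet, revcomp


def tile_reads(rng, genome, read_len=100, depth=30.0, error=0.0, prefix="g"):
    n = int(round(depth * len(genome) / read_len))
    reads = []
    for i in range(n):
        s = int(rng.integers(0, len(genome) - read_len + 1))
        seq = genome[s : s + read_len]
        if error > 0:
            seq = "".join(
                ("ACGT"[(("ACGT".index(b)) + int(rng.integers(1, 4))) % 4]
                 if rng.random() < error else b)
                for b in seq
            )
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"{prefix}{i}", seq, None))
    return ReadSet(reads, read_length=read_len)


@pytest.fixture(scope="module")
def two_segment_case():
    """Genome with two segments E1,E2 far apart; template = E1+E2."""
    rng = np.random.default_rng(0)
    e1, e2 = random_seq(rng, 300), random_seq(rng, 300)
    genome = random_seq(rng, 400) + e1 + random_seq(rng, 600) + e2 + random_seq(rng, 400)
    template = e1 + e2
    reads = tile_reads(np.random.default_rng(1), genome, depth=40)
    return genome, template, reads


def test_local_alignment_full_containment():
    rng = np.random.default_rng(2)
    template = random_seq(rng, 400)
    reads = ReadSet([("r0", template[40:140], None)], read_length=100)
    (a,) = local_align_reads(reads, template)
    assert (a.t_start, a.t_end) == (40, 140)
    assert a.strand == "+" and a.mismatches == 0


def test_local_alignment_partial_with_foreign_tail():
    rng = np.random.default_rng(3)
    template = random_seq(rng, 300)
    read = template[240:300] + random_seq(rng, 40)
    reads = ReadSet([("r0", read, None)], read_length=100)
    (a,) = local_align_reads(reads, template)
    # aligned part is the leading 60 nt (give or take chance extension)
    assert a.t_end == 300
    assert abs(a.t_start - 240) <= 3


def test_short_match_not_reported():
    rng = np.random.default_rng(4)
    template = random_seq(rng, 300)
    read = template[100:115] + random_seq(rng, 85)  # only 15 nt of identity
    reads = ReadSet([("r0", read, None)], read_length=100)
    assert local_align_reads(reads, template, min_local_length=20) == []


def test_minus_strand_read_aligned():
    rng = np.random.default_rng(5)
    template = random_seq(rng, 300)
    reads = ReadSet([("r0", revcomp(template[50:150]), None)], read_length=100)
    (a,) = local_align_reads(reads, template)
    assert a.strand == "-" and (a.t_start, a.t_end) == (50, 150)
    assert a.oriented_seq == template[50:150]


def test_boundary_signature_at_segment_join(two_segment_case):
    _, template, reads = two_segment_case
    als = local_align_reads(reads, template)
    signals = detect_boundaries(als, len(template))
    starts = [s for s in signals if s.side == "start"]
    finishes = [s for s in signals if s.side == "finish"]
    # one start pileup and one finish pileup at/near the join at 300
    assert any(abs(s.position - 300) <= 2 for s in starts)
    assert any(abs(s.position - 300) <= 2 for s in finishes)
    for s in signals:
        assert s.enrichment >= 10


def test_contiguous_template_has_no_internal_signal():
    rng = np.random.default_rng(6)
    genome = random_seq(rng, 2000)
    template = genome[500:1100]  # contiguous: reads tile straight through
    reads = tile_reads(np.random.default_rng(7), genome, depth=40)
    als = local_align_reads(reads, template)
    signals = detect_boundaries(als, len(template))
    assert [s for s in signals if 30 < s.position < len(template) - 30] == []


def test_island_growth_recovers_segment_with_tails(two_segment_case):
    _, template, reads = two_segment_case
    als = local_align_reads(reads, template)
    signals = detect_boundaries(als, len(template))
    seed = next(s for s in signals if s.side == "start" and abs(s.position - 300) <= 2)
    island = grow_island(seed, als, template)
    assert abs(island.core_start - 300) <= 2
    assert abs(island.core_end - 600) <= 2
    # tails of roughly read length minus the minimum local alignment length
    assert 60 <= island.left_tail_len <= 85
    assert 60 <= island.right_tail_len <= 85
    # the island core consensus reproduces the template segment
    core = island.slice_at(island.core_start, island.core_end)
    assert core == template[island.core_start : island.core_end]


def test_island_tails_match_true_genome(two_segment_case):
    genome, template, reads = two_segment_case
    als = local_align_reads(reads, template)
    islands = islands_for_template(reads, template, alignments=als)
    # E2 occupies genome[1300:1600]; its left tail continues the true genome
    e2 = next(i for i in islands if abs(i.core_start - 300) <= 2)
    lt = e2.slice_at(e2.core_start - e2.left_tail_len, e2.core_start)
    g_start = 1300 - (300 - e2.core_start)
    assert lt == genome[g_start - e2.left_tail_len : g_start]
    # and the tail does not align back to the template at >= 20 nt
    tail_reads = ReadSet([("t", lt, None)], read_length=len(lt))
    assert local_align_reads(tail_reads, template, min_local_length=20) == []


def test_repeat_only_reads_are_discarded():
    """Reads sharing only a short repeat with the template are excluded."""
    rng = np.random.default_rng(8)
    repeat = random_seq(rng, 25)
    seg = random_seq(rng, 140) + repeat + random_seq(rng, 135)
    genome = random_seq(rng, 300) + seg + random_seq(rng, 300)
    template = seg
    reads = list(tile_reads(np.random.default_rng(9), genome, depth=40))
    # foreign reads from an unrelated locus carrying the same repeat
    foreign = [
        (f"x{i}", random_seq(rng, 40) + repeat + random_seq(rng, 35), None)
        for i in range(4)
    ]
    rs = ReadSet(reads + foreign, read_length=100)
    als = local_align_reads(rs, template)
    islands = islands_for_template(rs, template, alignments=als)
    big = max(islands, key=lambda i: i.n_reads)
    assert not any(r.startswith("x") for r in big.read_ids)


def test_three_segment_template_gives_three_islands():
    rng = np.random.default_rng(10)
    segs = [random_seq(rng, 300) for _ in range(3)]
    genome = "".join(
        random_seq(rng, 500) + s for s in segs
    ) + random_seq(rng, 500)
    template = "".join(segs)
    reads = tile_reads(np.random.default_rng(11), genome, depth=40)
    islands = islands_for_template(reads, template)
    assert len(islands) == 3
    for k, isl in enumerate(islands):
        assert abs(isl.core_start - 300 * k) <= 2
        assert abs(isl.core_end - 300 * (k + 1)) <= 2


def test_zero_depth_seed_gives_empty_island():
    rng = np.random.default_rng(12)
    template = random_seq(rng, 200)
    seed = BoundarySignal(100, 0, 0, float("inf"), "start")
    island = grow_island(seed, [], template)
    assert island.is_empty


def test_thin_depth_islands_flagged_low_confidence():
    rng = np.random.default_rng(13)
    genome = random_seq(rng, 1500)
    template = genome[400:700]
    reads = tile_reads(np.random.default_rng(14), genome, depth=1.2, error=0.01)
    als = local_align_reads(reads, template)
    if als:
        islands = islands_for_template(reads, template, alignments=als)
        assert all(i.low_confidence or i.n_reads >= 4 for i in islands)
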