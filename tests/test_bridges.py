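import numpy as np
import pytest

from conftest import random_seq
from exonpatch.bridges import (
    AlignParams,
    Hsp,
    aggregate_junction_table,
    classify_junctions,
    junction_summary,
    recompute_score,
    ungapped_local_align,
)
from exonpatch.seqio import GenomeAssembly, TranscriptModel, revcomp


# --------------------------------------------------------------------------
# independent brute-force oracle: every match-run start on every diagonal is
# a seed; two-sided x-drop extension; same dedup/overlap-resolution rules
# --------------------------------------------------------------------------

def _oracle_strand(q, s, params):
    m, mm, x = params.match_score, params.mismatch_score, params.x_drop
    found = {}
    for diag in range(-(len(s) - 1), len(q)):
        qi0 = max(0, diag)
        si0 = qi0 - diag
        length = min(len(q) - qi0, len(s) - si0)
        if length <= 0:
            continue
        col = [
            m if q[qi0 + k] == s[si0 + k] and q[qi0 + k] != "N" else mm
            for k in range(length)
        ]
        for k in range(length):
            if col[k] != m or (k > 0 and col[k - 1] == m):
                continue  # seed only at match-run starts
            # two-sided x-drop from the single column k
            best_r, run, jr = 0, 0, k + 1
            j = k + 1
            while j < length:
                run += col[j]
                j += 1
                if run > best_r:
                    best_r, jr = run, j
                elif best_r - run > x:
                    break
            best_l, run, jl = 0, 0, k
            j = k
            while j > 0:
                j -= 1
                run += col[j]
                if run > best_l:
                    best_l, jl = run, j
                elif best_l - run > x:
                    break
            score = col[k] + best_l + best_r
            if score >= params.min_hsp_score:
                key = (qi0 + jl, qi0 + jr, si0 + jl, si0 + jr)
                found[key] = max(found.get(key, -1), score)
    by_diag = {}
    for (qa, qb, sa, sb), score in found.items():
        by_diag.setdefault(qa - sa, []).append((qa, qb, sa, sb, score))
    out = []
    for items in by_diag.values():
        items.sort(key=lambda t: (-t[4], t[1] - t[0], t[0]))
        kept = []
        for it in items:
            if all(it[1] <= k[0] or it[0] >= k[1] for k in kept):
                kept.append(it)
        out.extend(kept)
    return out


def oracle_hsps(query, subject, params):
    res = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for qa, qb, sa, sb, score in _oracle_strand(q, subject, params):
            if strand == "+":
                res.add((qa, qb, sa, sb, strand, score))
            else:
                res.add((len(query) - qb, len(query) - qa, sa, sb, strand, score))
    return res


def as_set(hsps):
    return {(h.q_start, h.q_end, h.s_start, h.s_end, h.strand, h.score) for h in hsps}


def test_identity_alignment():
    rng = np.random.default_rng(0)
    q = random_seq(rng, 50)
    (h,) = ungapped_local_align(q, q)
    assert (h.q_start, h.q_end, h.s_start, h.s_end) == (0, 50, 0, 50)
    assert h.score == 50 and h.strand == "+" and h.identity == 1.0


def test_reverse_complement_strand():
    rng = np.random.default_rng(1)
    s = random_seq(rng, 60)
    hs = ungapped_local_align(revcomp(s), s)
    assert hs[0].strand == "-"
    assert (hs[0].s_start, hs[0].s_end) == (0, 60)


def test_insert_splits_into_two_hsps():
    # expected intervals frozen from the brute-force oracle on this instance
    rng = np.random.default_rng(42)
    A, B, X = random_seq(rng, 60), random_seq(rng, 60), random_seq(rng, 30)
    query, subject = A + X + B, A + B
    hs = ungapped_local_align(query, subject)
    assert as_set(hs) == oracle_hsps(query, subject, AlignParams())
    plus = sorted(
        [h for h in hs if h.strand == "+"], key=lambda h: h.s_start
    )
    assert len(plus) == 2
    # first HSP covers A (chance extension into X may add a couple of nt)
    assert plus[0].q_start == 0 and plus[0].s_start == 0
    assert abs(plus[0].q_end - 60) <= 3
    # second HSP covers B
    assert plus[1].q_end == 150 and plus[1].s_end == 120
    assert abs(plus[1].q_start - 90) <= 3


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_random_instances(seed):
    rng = np.random.default_rng(seed)
    subject = random_seq(rng, int(rng.integers(100, 200)))
    # plant 1-2 exact blocks of the subject inside a random query
    query = random_seq(rng, int(rng.integers(100, 200)))
    for _ in range(int(rng.integers(1, 3))):
        ln = int(rng.integers(25, 60))
        if ln >= len(subject) or ln >= len(query):
            continue
        ss = int(rng.integers(0, len(subject) - ln))
        qs = int(rng.integers(0, len(query) - ln))
        block = subject[ss : ss + ln]
        if rng.random() < 0.3:
            block = revcomp(block)
        query = query[:qs] + block + query[qs + ln :]
    params = AlignParams()
    assert as_set(ungapped_local_align(query, subject, params)) == oracle_hsps(
        query, subject, params
    )


def test_score_recomputation_property():
    rng = np.random.default_rng(7)
    subject = random_seq(rng, 150)
    query = random_seq(rng, 40) + subject[30:110] + random_seq(rng, 40)
    params = AlignParams()
    for h in ungapped_local_align(query, subject, params):
        assert recompute_score(h, query, subject, params) == h.score


# --------------------------------------------------------------------------
# junction classification
# --------------------------------------------------------------------------

def _two_exon_model(rng, e1=150, e2=150, intron=200):
    g = random_seq(rng, e1) + random_seq(rng, intron) + random_seq(rng, e2)
    genome = GenomeAssembly({"c": g})
    m = TranscriptModel("t", "c", "+", [(0, e1), (e1 + intron, e1 + intron + e2)])
    m.compute_derived(genome)
    return m


def test_covered_junction():
    rng = np.random.default_rng(3)
    m = _two_exon_model(rng)
    obj = m.spliced_sequence  # continuous across the junction
    hs = ungapped_local_align(obj, m.spliced_sequence, query_id="o", subject_id="t")
    calls = classify_junctions(hs, m, {"o": obj})
    assert [c.status for c in calls] == ["covered"]


def test_bridged_junction_with_insert():
    rng = np.random.default_rng(4)
    m = _two_exon_model(rng)
    m.n_island_flags = [True]
    insert = random_seq(rng, 45)
    pos = m.junctions[0][2]
    obj = m.spliced_sequence[:pos] + insert + m.spliced_sequence[pos:]
    hs = ungapped_local_align(obj, m.spliced_sequence, query_id="o", subject_id="t")
    calls = classify_junctions(hs, m, {"o": obj})
    c = calls[0]
    assert c.status == "bridged"
    assert c.insert_length == 45
    lo, hi = c.insert_query_interval
    assert (lo, hi) == (pos, pos + 45)
    assert c.insert_sequence == insert


def test_bridged_junction_on_minus_strand_object():
    rng = np.random.default_rng(5)
    m = _two_exon_model(rng)
    m.n_island_flags = [True]
    insert = random_seq(rng, 33)
    pos = m.junctions[0][2]
    obj = revcomp(m.spliced_sequence[:pos] + insert + m.spliced_sequence[pos:])
    hs = ungapped_local_align(obj, m.spliced_sequence, query_id="o", subject_id="t")
    calls = classify_junctions(hs, m, {"o": obj})
    c = calls[0]
    assert c.status == "bridged" and c.strand == "-"
    assert c.insert_sequence == insert  # reported in subject orientation


def test_half_bridge_requires_long_tail_near_island():
    rng = np.random.default_rng(6)
    m = _two_exon_model(rng, e1=150, e2=150)
    m.n_island_flags = [True]
    pos = m.junctions[0][2]
    # object: 120 nt matching the left exon end + 280 nt of foreign sequence
    obj = m.spliced_sequence[pos - 120 : pos] + random_seq(rng, 280)
    hs = ungapped_local_align(obj, m.spliced_sequence, query_id="o", subject_id="t")
    calls = classify_junctions(hs, m, {"o": obj})
    assert calls[0].status == "half_bridged"
    # same object at an unflagged junction stays no_information
    m.n_island_flags = [False]
    calls = classify_junctions(hs, m, {"o": obj})
    assert calls[0].status == "no_information"


def test_half_bridge_tail_fraction_threshold():
    rng = np.random.default_rng(8)
    m = _two_exon_model(rng)
    m.n_island_flags = [True]
    pos = m.junctions[0][2]
    # tail is only 40% of the object: below the 60% requirement
    obj = m.spliced_sequence[pos - 120 : pos] + random_seq(rng, 80)
    hs = ungapped_local_align(obj, m.spliced_sequence, query_id="o", subject_id="t")
    calls = classify_junctions(hs, m, {"o": obj})
    assert calls[0].status == "no_information"


def test_aggregation_precedence_and_summary():
    rng = np.random.default_rng(9)
    m = _two_exon_model(rng)
    m.n_island_flags = [True]
    pos = m.junctions[0][2]
    covered_obj = m.spliced_sequence
    insert = random_seq(rng, 50)
    bridged_obj = m.spliced_sequence[:pos] + insert + m.spliced_sequence[pos:]
    objs = {"cov": covered_obj, "bri": bridged_obj}
    hs = []
    for oid, oseq in objs.items():
        hs.extend(ungapped_local_align(oseq, m.spliced_sequence, query_id=oid,
                                       subject_id="t"))
    calls = classify_junctions(hs, m, objs)
    assert calls[0].status == "bridged"  # bridged > covered
    assert calls[0].object_id == "bri"
    table = aggregate_junction_table(calls)
    summary = junction_summary(table)
    assert summary.loc[0, "count"] == 1 and summary.loc[0, "status"] == "bridged"


def test_no_hsps_means_no_information():
    rng = np.random.default_rng(10)
    m = _two_exon_model(rng)
    obj = random_seq(rng, 300)  # unrelated
    hs = ungapped_local_align(obj, m.spliced_sequence, query_id="o", subject_id="t")
    calls = classify_junctions(hs, m, {"o": obj})
    assert calls[0].status == "no_information"


def test_perfect_input_recovery_all_covered(small_truth):
    """Error-free objects cover every junction not involving an N-island."""
    for isl_free in [m for m in small_truth.models_masked]:
        obj_id = f"obj_{isl_free.transcript_id}"
        obj = small_truth.objects[obj_id]
        hs = ungapped_local_align(
            obj, isl_free.spliced_sequence, query_id=obj_id,
            subject_id=isl_free.transcript_id,
        )
        calls = classify_junctions(hs, isl_free, {obj_id: obj})
        for c in calls:
            if not c.n_flag:
                assert c.status == "covered"
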