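import numpy as np
import pytest

from conftest import planted_exon_intervals, random_seq
from exonpatch.bridges import classify_junctions, ungapped_local_align
from exonpatch.islands import islands_for_template, local_align_reads
from exonpatch.junctions import (
    build_connected_islands,
    call_splice,
    find_join_offsets,
    resolve_hidden_exons,
)
from exonpatch.pipeline import RunParams, analyze_object
from exonpatch.seqio import revcomp
from test_islands import tile_reads


def _spliced_case(rng, pwm, n_segs=2, seg_len=300, intron_len=400, repeat=""):
    """Genome with n segments separated by introns carrying real splice
    sites drawn as perfect consensus; template = spliced segments."""
    w = pwm.windows
    donor_best = "".join(
        "ACGT"[int(np.argmax(p * ic)) if ic > 0.05 else int(np.argmax(p))]
        for p, ic in zip(pwm.donor_probs[w.donor_exonic :],
                         pwm.donor_ic[w.donor_exonic :])
    )
    acc_best = "".join(
        "ACGT"[int(np.argmax(p * ic)) if ic > 0.05 else int(np.argmax(p))]
        for p, ic in zip(pwm.acceptor_probs[: w.acceptor_intronic],
                         pwm.acceptor_ic[: w.acceptor_intronic])
    )
    segs = []
    genome_parts = [random_seq(rng, 300)]
    for k in range(n_segs):
        seg = random_seq(rng, seg_len)
        if repeat and k > 0:
            seg = repeat + seg[len(repeat):]
        if repeat and k < n_segs - 1:
            seg = seg[: -len(repeat)] + repeat if False else seg
        segs.append(seg)
        genome_parts.append(seg)
        if k < n_segs - 1:
            mid = random_seq(rng, intron_len - len(donor_best) - len(acc_best))
            genome_parts.append(donor_best + mid + acc_best)
    genome_parts.append(random_seq(rng, 300))
    return "".join(genome_parts), "".join(segs), segs


@pytest.fixture(scope="module")
def consensus_case(small_pwm):
    rng = np.random.default_rng(20)
    genome, template, segs = _spliced_case(rng, small_pwm)
    reads = tile_reads(np.random.default_rng(21), genome, depth=40)
    islands = islands_for_template(reads, template)
    return genome, template, segs, islands


def test_unique_join_without_repeat(consensus_case, small_pwm):
    _, template, segs, islands = consensus_case
    assert len(islands) == 2
    cand = find_join_offsets(islands[0], islands[1], template)
    assert cand.offsets == [len(segs[0])]
    assert cand.ambiguity == 1 and cand.direct_repeat_len == 0


def test_planted_consensus_called_high_confidence(consensus_case, small_pwm):
    _, template, segs, islands = consensus_case
    cand = find_join_offsets(islands[0], islands[1], template)
    calls = call_splice(cand, islands[0], islands[1], template, small_pwm)
    best = max(calls, key=lambda c: (c.high_confidence, c.score))
    assert best.strand == "+" and best.high_confidence
    assert best.offset == len(segs[0])
    assert best.score >= small_pwm.score_cutoff


def test_direct_repeat_widens_join(small_pwm):
    """A k-nt repeat across the junction admits k+1 offsets."""
    rng = np.random.default_rng(22)
    w = small_pwm.windows
    donor_best = "GT" + "A" * (w.donor_intronic - 2)
    acc_best = "T" * (w.acceptor_intronic - 2) + "AG"
    rep = "AG"
    # pin the bases flanking the repeat so no *chance* repeat extends it
    e1 = random_seq(rng, 299) + "C"
    e2 = rep + "A" + random_seq(rng, 297)
    # the intron starts with the same 2 nt the next exon starts with
    intron = rep + "C" + donor_best + random_seq(rng, 300) + acc_best
    genome = random_seq(rng, 300) + e1 + intron + e2 + random_seq(rng, 300)
    template = e1 + e2
    reads = tile_reads(np.random.default_rng(23), genome, depth=50)
    islands = islands_for_template(reads, template)
    assert len(islands) == 2
    cand = find_join_offsets(islands[0], islands[1], template)
    assert cand.ambiguity == len(rep) + 1
    assert cand.offsets == [300, 301, 302]


def test_minus_strand_consensus_detected(small_pwm, consensus_case):
    genome, template, segs, _ = consensus_case
    # the same locus observed in the opposite orientation: reads align to the
    # reverse-complemented template, the splice reads GT..AG on '-' only
    rc_template = revcomp(template)
    rc_genome = revcomp(genome)
    reads = tile_reads(np.random.default_rng(24), rc_genome, depth=40)
    islands = islands_for_template(reads, rc_template)
    assert len(islands) == 2
    cand = find_join_offsets(islands[0], islands[1], rc_template)
    calls = call_splice(cand, islands[0], islands[1], rc_template, small_pwm)
    best = max(calls, key=lambda c: (c.high_confidence, c.score))
    assert best.strand == "-" and best.high_confidence


def test_connected_islands_and_fusion_flag(small_truth, small_reads, small_pwm):
    _, genomic = small_reads
    params = RunParams()
    # a clean full-length object forms one connected island spanning all
    clean = next(
        oid for oid, reg in small_truth.object_registry.items()
        if reg["type"] == "full" and reg["genes"][0] == "t4"
    )
    ana = analyze_object(clean, small_truth.objects[clean], genomic, small_pwm, params)
    assert ana.diagnostics["splice_consistent"]
    # every fusion object yields >= 2 connected islands
    for oid, reg in small_truth.object_registry.items():
        if reg["type"] != "fusion":
            continue
        ana = analyze_object(oid, small_truth.objects[oid], genomic, small_pwm, params)
        assert ana.diagnostics["fusion_suspected"], oid
        if reg["strand_flip"]:
            assert ana.diagnostics["strand_flip"]


def test_no_high_confidence_without_dinucleotides(small_truth, small_reads, small_pwm):
    _, genomic = small_reads
    params = RunParams()
    w = small_pwm.windows
    for oid in list(small_truth.objects)[:3]:
        ana = analyze_object(oid, small_truth.objects[oid], genomic, small_pwm, params)
        for calls in ana.junction_calls:
            for c in calls:
                if c.high_confidence:
                    gt = c.donor_window[w.donor_exonic : w.donor_exonic + 2]
                    ag = c.acceptor_window[w.acceptor_intronic - 2 : w.acceptor_intronic]
                    assert gt == "GT" and ag == "AG"


def test_resolve_hidden_exons_exact_boundaries(small_truth, small_reads, small_pwm):
    _, genomic = small_reads
    params = RunParams()
    planted = planted_exon_intervals(small_truth)
    (tid, jidx) = next(k for k in planted if len(planted[k]) == 2)
    obj_id = f"obj_{tid}"
    obj = small_truth.objects[obj_id]
    model = next(m for m in small_truth.models_masked if m.transcript_id == tid)
    hsps = ungapped_local_align(obj, model.spliced_sequence, query_id=obj_id,
                                subject_id=tid)
    calls = classify_junctions(hsps, model, {obj_id: obj})
    bridge = next(c for c in calls if c.junction_index == jidx)
    assert bridge.status == "bridged"
    ana = analyze_object(obj_id, obj, genomic, small_pwm, params)
    res = resolve_hidden_exons(
        bridge, ana.islands, ana.connected,
        [c if c else [] for c in ana.junction_calls], obj,
    )
    assert res["status"] == "hidden_exons"
    got = [(e["start"], e["end"]) for e in res["exons"]]
    assert got == planted[(tid, jidx)]
    for e in res["exons"]:
        assert e["left_splice"].high_confidence
        assert e["right_splice"].high_confidence


def test_reference_concordance_of_computed_splices(small_truth, small_reads, small_pwm):
    """Computed join offsets line up with the generating model's junctions."""
    _, genomic = small_reads
    params = RunParams()
    total, hits = 0, 0
    for m in small_truth.models_true[:5]:
        obj_id = f"obj_{m.transcript_id}"
        obj = small_truth.objects[obj_id]
        flip = small_truth.object_registry[obj_id]["flipped"]
        bounds = list(np.cumsum([e - s for s, e in m.transcript_exons()])[:-1])
        if flip:
            bounds = sorted(len(obj) - b for b in bounds)
        ana = analyze_object(obj_id, obj, genomic, small_pwm, params)
        offsets = []
        for calls in ana.junction_calls:
            hc = [c for c in calls if c.high_confidence]
            if hc:
                offsets.append(max(hc, key=lambda c: c.score).offset)
        for b in bounds:
            total += 1
            hits += b in offsets
    assert total > 10
    assert hits / total >= 0.9
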