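"""Splice tests at island junctions and connected-island assembly.

Two sequential consensus islands share no sequence, yet each aligns to
adjacent segments of the transcript object: the position where their cores
meet is an obligatory, single-nucleotide join (widened to k+1 candidate
offsets by a k-nt terminal direct repeat).  Because nearly all nucleotides
of the splice consensus are intronic, finding donor/acceptor consensus in
the islands' genomic *tails* exactly at the constrained join is independent
evidence the join is a real splice.  Chains of islands connected by
same-strand high-confidence splices ("connected islands") certify a
transcript object as producible by splicing; multiple connected islands on
one object flag an in-silico fusion (track-crossing) artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bridges import JunctionCall
from .islands import ConsensusIsland
from .seqio import TranscriptModel, revcomp
from .splice import SplicePwm, has_terminal_dinucleotides, score_junction


@dataclass
class JoinCandidate:
    left_index: int
    right_index: int
    offsets: list[int]
    truncated: bool = False

    @property
    def ambiguity(self) -> int:
        return len(self.offsets)

    @property
    def direct_repeat_len(self) -> int:
        return len(self.offsets) - 1


@dataclass
class SpliceCall:
    offset: int
    strand: str
    donor_window: str
    acceptor_window: str
    score: float
    high_confidence: bool


@dataclass
class ConnectedIsland:
    member_indices: list[int]
    calls: list[SpliceCall] = field(default_factory=list)
    strand: str | None = None
    spans_whole_template: bool = False


def find_join_offsets(
    left: ConsensusIsland,
    right: ConsensusIsland,
    template: str,
    max_ambiguity: int = 20,
) -> JoinCandidate:
    """Candidate join positions between two adjacent islands.

    With no terminal direct repeat the cores abut at one position and the
    join is unique.  A k-nt terminal direct repeat widens the join to k+1
    candidate offsets.  The core overlap only bounds the window: because all
    boundary reads share the same genomic continuation, an x-drop extension
    can hop a mismatch in lock-step and overstate the core by a few nt, so
    each offset is verified against the sequence itself — the join at ``o``
    is valid only when the left island's consensus reproduces the template
    on [window_start, o) and the right island's on [o, window_end).
    """
    if right.core_start > left.core_end:
        raise ValueError(
            f"islands not adjacent: gap [{left.core_end},{right.core_start})"
        )
    lo, hi = right.core_start, left.core_end
    truncated = False
    if hi - lo > max_ambiguity:
        hi = lo + max_ambiguity
        truncated = True
    # longest prefix of [lo, hi) where the left consensus matches the template
    pre = 0
    while lo + pre < hi and 0 <= lo + pre < len(template) \
            and left.base_at(lo + pre) == template[lo + pre]:
        pre += 1
    # longest suffix where the right consensus matches the template
    suf = 0
    while hi - 1 - suf >= lo and 0 <= hi - 1 - suf < len(template) \
            and right.base_at(hi - 1 - suf) == template[hi - 1 - suf]:
        suf += 1
    o_min, o_max = max(lo, hi - suf), min(hi, lo + pre)
    if o_min > o_max:  # inconsistent overlap: best-effort single offset
        return JoinCandidate(-1, -1, [min(hi, lo + pre)], True)
    return JoinCandidate(-1, -1, list(range(o_min, o_max + 1)), truncated)


def _tpl_slice(template: str, lo: int, hi: int) -> str:
    """Template slice, N-padded outside [0, len)."""
    out = []
    for p in range(lo, hi):
        out.append(template[p] if 0 <= p < len(template) else "N")
    return "".join(out)


def splice_windows_at(
    offset: int,
    strand: str,
    left: ConsensusIsland,
    right: ConsensusIsland,
    template: str,
    pwm: SplicePwm,
) -> tuple[str, str]:
    """Donor/acceptor windows for a join at ``offset`` on either strand.

    On '+' the donor's intronic side continues the left island's genomic
    sequence past the join, and the acceptor's intronic side is the right
    island's genomic sequence approaching it; exonic sides come from the
    template.  On '-' the two sides swap roles and are reverse-complemented.
    Positions without consensus coverage are N (scoring 0).
    """
    w = pwm.windows
    o = offset
    left_side = _tpl_slice(template, o - w.donor_exonic, o)  # exonic, donor
    left_intron = left.slice_at(o, o + w.donor_intronic)
    right_intron = right.slice_at(o - w.acceptor_intronic, o)
    right_side = _tpl_slice(template, o, o + w.acceptor_exonic)
    if strand == "+":
        return left_side + left_intron, right_intron + right_side
    # '-': donor reads rightward sequence in reverse, acceptor the leftward
    d_int = right.slice_at(o - w.donor_intronic, o)
    d_ex = _tpl_slice(template, o, o + w.donor_exonic)
    a_ex = _tpl_slice(template, o - w.acceptor_exonic, o)
    a_int = left.slice_at(o, o + w.acceptor_intronic)
    return revcomp(d_int + d_ex), revcomp(a_ex + a_int)


def call_splice(
    candidate: JoinCandidate,
    left: ConsensusIsland,
    right: ConsensusIsland,
    template: str,
    pwm: SplicePwm,
) -> list[SpliceCall]:
    """Best-scoring splice call per strand over the candidate offsets.

    Ties break toward the smallest offset.  High confidence follows the
    two-step rule: literal GT...AG at the chosen offset plus score >= the
    model cutoff; a call can never be high-confidence without the
    dinucleotides.
    """
    best: dict[str, SpliceCall] = {}
    for strand in ("+", "-"):
        for o in candidate.offsets:
            dw, aw = splice_windows_at(o, strand, left, right, template, pwm)
            score = float(score_junction(dw, aw, pwm))
            has_dinuc = has_terminal_dinucleotides(dw, aw, pwm.windows)
            hc = bool(has_dinuc and score >= pwm.score_cutoff)
            if hc:
                assert has_dinuc, "high-confidence call without GT...AG"
            call = SpliceCall(o, strand, dw, aw, score, hc)
            cur = best.get(strand)
            if (
                cur is None
                or (call.high_confidence, call.score) > (cur.high_confidence, cur.score)
            ):
                best[strand] = call
    return [best["+"], best["-"]]


def build_connected_islands(
    islands: list[ConsensusIsland],
    junction_calls: list[list[SpliceCall]],
) -> tuple[list[ConnectedIsland], dict]:
    """Maximal runs of islands joined by same-strand high-confidence splices.

    Diagnostics: a single run spanning the template means the object is
    splice-consistent; multiple runs suggest a fused (track-crossing)
    object; a strand flip between adjacent runs marks a strand-switching
    fusion; junctions callable on both strands are flagged ambiguous.
    """
    n = len(islands)
    assert len(junction_calls) == max(n - 1, 0)
    runs: list[ConnectedIsland] = []
    cur = ConnectedIsland([0]) if n else None
    cur_strand: str | None = None
    ambiguous = []
    failed = []
    for j, calls in enumerate(junction_calls):
        hc = {c.strand: c for c in calls if c.high_confidence}
        if len(hc) == 2:
            ambiguous.append(j)
        take = None
        if hc:
            if cur_strand is None:
                take = hc.get("+") if "+" in hc else hc.get("-")
                if len(hc) == 1:
                    cur_strand = take.strand
            elif cur_strand in hc:
                take = hc[cur_strand]
        if take is not None:
            cur.member_indices.append(j + 1)
            cur.calls.append(take)
        else:
            if not hc:
                failed.append(j)
            cur.strand = cur_strand
            runs.append(cur)
            cur = ConnectedIsland([j + 1])
            cur_strand = next(iter(hc)) if len(hc) == 1 else None
    if cur is not None:
        cur.strand = cur_strand
        runs.append(cur)
    for r in runs:
        if r.strand is None and r.calls:
            r.strand = r.calls[0].strand
        r.spans_whole_template = len(r.member_indices) == n and n > 0
    strands = [r.strand for r in runs if r.strand]
    diagnostics = {
        "n_connected": len(runs),
        "splice_consistent": len(runs) == 1 and (runs[0].spans_whole_template if runs else False),
        "fusion_suspected": len(runs) > 1,
        "strand_flip": any(a != b for a, b in zip(strands, strands[1:])),
        "ambiguous_junctions": ambiguous,
        "failed_junctions": failed,
    }
    return runs, diagnostics


def resolve_hidden_exons(
    bridge: JunctionCall,
    islands: list[ConsensusIsland],
    connected: list[ConnectedIsland],
    junction_calls: list[list[SpliceCall]],
    template: str,
    model: TranscriptModel | None = None,
    tolerance: int = 5,
) -> dict:
    """Turn a bridged junction's insert islands into hidden-exon calls.

    Islands whose cores lie within the insert's query interval are candidate
    exons; they pass the splicing test only if one connected island contains
    them *and* the flanking reference-matching islands.  Exon boundaries are
    the chosen join offsets, so a passing exon has literal splice-site
    support on both sides.
    """
    if bridge.status != "bridged" or bridge.insert_query_interval is None:
        raise ValueError("resolve_hidden_exons requires a bridged junction call")
    lo, hi = bridge.insert_query_interval
    interior = [
        i for i, isl in enumerate(islands)
        if isl.core_start >= lo - tolerance and isl.core_end <= hi + tolerance
    ]
    base = {
        "transcript_id": bridge.transcript_id,
        "junction_index": bridge.junction_index,
        "object_id": bridge.object_id,
        "insert_interval": (lo, hi),
    }
    if not interior:
        return {**base, "status": "unresolved_no_island", "exons": []}
    first, last = interior[0], interior[-1]
    if first == 0 or last == len(islands) - 1:
        return {**base, "status": "unresolved_terminal", "exons": []}
    needed = set(range(first - 1, last + 2))
    home = next(
        (r for r in connected if needed.issubset(set(r.member_indices))), None
    )
    if home is None:
        return {**base, "status": "failed_splice_test", "exons": []}
    exons = []
    for k, i in enumerate(interior):
        left_call = _call_for(junction_calls[i - 1], home)
        right_call = _call_for(junction_calls[i], home)
        o_l, o_r = left_call.offset, right_call.offset
        exons.append(
            {
                "index": k,
                "start": o_l,
                "end": o_r,
                "sequence": template[o_l:o_r],
                "strand": home.strand,
                "left_splice": left_call,
                "right_splice": right_call,
                "left_tail": islands[i].left_tail_len,
                "right_tail": islands[i].right_tail_len,
            }
        )
    return {**base, "status": "hidden_exons", "exons": exons, "strand": home.strand}


def _call_for(calls: list[SpliceCall], run: ConnectedIsland) -> SpliceCall:
    hc = [c for c in calls if c.high_confidence]
    for c in hc:
        if c.strand == run.strand:
            return c
    return hc[0] if hc else max(calls, key=lambda c: c.score)
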