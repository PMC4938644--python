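"""Ungapped local alignment of transcript objects to reference transcripts
and the separated-HSP junction test.

The aligner is BLASTN-like restricted to ungapped extension: exact word
seeding on each diagonal followed by two-sided x-drop extension, with each
extension trimmed back to its maximum-scoring point.  Forcing ungapped HSPs
makes an inserted exon show up as *two* separate HSPs with transcript-object
sequence in between, instead of being absorbed as a gap — that separation is
the detection signal for sequence hidden in an assembly gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .seqio import TranscriptModel, revcomp


@dataclass(frozen=True)
class AlignParams:
    match_score: int = 1
    mismatch_score: int = -2
    word_size: int = 11
    x_drop: int = 10
    min_hsp_score: int = 22

    def __post_init__(self) -> None:
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("require match > 0 > mismatch")
        if self.word_size < 4:
            raise ValueError("word size must be >= 4")


@dataclass(frozen=True)
class Hsp:
    """One ungapped high-scoring pair.

    ``q_start/q_end`` are 0-based half-open on the *original* query; for
    strand ``-`` the reverse complement of ``query[q_start:q_end]`` aligns to
    ``subject[s_start:s_end]``.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    identity: float

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def hsp_columns(hsp: Hsp, query: str, subject: str) -> list[tuple[str, str]]:
    """Aligned columns (query base, subject base) for score recomputation."""
    q = query[hsp.q_start : hsp.q_end]
    if hsp.strand == "-":
        q = revcomp(q)
    s = subject[hsp.s_start : hsp.s_end]
    return list(zip(q, s))


def recompute_score(hsp: Hsp, query: str, subject: str, params: AlignParams) -> int:
    return sum(
        params.match_score if a == b and a != "N" else params.mismatch_score
        for a, b in hsp_columns(hsp, query, subject)
    )


def _extend_xdrop(q: str, s: str, qi: int, si: int, qj: int, sj: int,
                  params: AlignParams):
    """Two-sided ungapped x-drop extension of seed q[qi:qj] ~ s[si:sj].

    Returns (q_start, q_end, s_start, s_end, score).  Each direction is
    extended until the running score falls more than ``x_drop`` below the
    best seen, then trimmed back to the best point.
    """
    m, mm, x = params.match_score, params.mismatch_score, params.x_drop
    seed_score = sum(
        m if q[qi + k] == s[si + k] and q[qi + k] != "N" else mm
        for k in range(qj - qi)
    )
    # right extension
    best_r, run = 0, 0
    br_q, br_s = qj, sj
    a, b = qj, sj
    while a < len(q) and b < len(s):
        run += m if q[a] == s[b] and q[a] != "N" else mm
        a += 1
        b += 1
        if run > best_r:
            best_r, br_q, br_s = run, a, b
        elif best_r - run > x:
            break
    # left extension
    best_l, run = 0, 0
    bl_q, bl_s = qi, si
    a, b = qi, si
    while a > 0 and b > 0:
        a -= 1
        b -= 1
        run += m if q[a] == s[b] and q[a] != "N" else mm
        if run > best_l:
            best_l, bl_q, bl_s = run, a, b
        elif best_l - run > x:
            break
    return bl_q, br_q, bl_s, br_s, seed_score + best_l + best_r


def _scan_strand(q: str, s: str, query_id: str, subject_id: str, strand: str,
                 q_len: int, params: AlignParams) -> list[Hsp]:
    w = params.word_size
    if len(q) < w or len(s) < w:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(s) - w + 1):
        word = s[i : i + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    # per-diagonal rightmost query end already reached, to skip redundant seeds
    reached: dict[int, int] = {}
    found: dict[tuple[int, int, int, int], int] = {}
    for qi in range(len(q) - w + 1):
        word = q[qi : qi + w]
        hits = index.get(word)
        if not hits:
            continue
        for si in hits:
            diag = qi - si
            if reached.get(diag, -1) >= qi + w:
                continue
            qa, qb, sa, sb, score = _extend_xdrop(q, s, qi, si, qi + w, si + w, params)
            reached[diag] = max(reached.get(diag, -1), qb)
            if score >= params.min_hsp_score:
                key = (qa, qb, sa, sb)
                if found.get(key, -1) < score:
                    found[key] = score
    # resolve overlaps per diagonal: keep best-scoring interval
    by_diag: dict[int, list[tuple[int, int, int, int, int]]] = {}
    for (qa, qb, sa, sb), score in found.items():
        by_diag.setdefault(qa - sa, []).append((qa, qb, sa, sb, score))
    hsps = []
    for diag, items in by_diag.items():
        # equal scores: prefer the tighter interval (trimmed to its maximum)
        items.sort(key=lambda t: (-t[4], t[1] - t[0], t[0]))
        kept: list[tuple[int, int, int, int, int]] = []
        for it in items:
            if all(it[1] <= k[0] or it[0] >= k[1] for k in kept):
                kept.append(it)
        for qa, qb, sa, sb, score in kept:
            n_match = sum(
                1 for a, b in zip(q[qa:qb], s[sa:sb]) if a == b and a != "N"
            )
            if strand == "+":
                oqa, oqb = qa, qb
            else:  # q is revcomp(query): map back to original coordinates
                oqa, oqb = q_len - qb, q_len - qa
            hsps.append(
                Hsp(query_id, subject_id, oqa, oqb, sa, sb, strand, score,
                    n_match / (qb - qa))
            )
    return hsps


def ungapped_local_align(
    query: str,
    subject: str,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[Hsp]:
    """All maximal ungapped HSPs (score >= min_hsp_score), both query strands.

    Identical intervals are reported once; overlapping candidates on the same
    diagonal collapse to the highest-scoring one.  Sorted by score descending.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    hsps = _scan_strand(query, subject, query_id, subject_id, "+", len(query), params)
    hsps += _scan_strand(
        revcomp(query), subject, query_id, subject_id, "-", len(query), params
    )
    hsps.sort(key=lambda h: (-h.score, h.s_start, h.q_start, h.strand))
    return hsps


# ---------------------------------------------------------------------------
# Junction classification (covered / bridged / half-bridged / no-information)
# ---------------------------------------------------------------------------

STATUS_PRECEDENCE = {"bridged": 3, "covered": 2, "half_bridged": 1, "no_information": 0}


@dataclass
class JunctionCall:
    transcript_id: str
    junction_index: int
    status: str
    n_flag: bool
    object_id: str | None = None
    hsps: list[Hsp] = field(default_factory=list)
    insert_sequence: str | None = None
    insert_query_interval: tuple[int, int] | None = None
    strand: str | None = None

    @property
    def insert_length(self) -> int:
        return len(self.insert_sequence) if self.insert_sequence else 0


def _clip_hsp_to_junction(h: Hsp, pos: int, side: str, max_clip: int = 10) -> Hsp | None:
    """Clip an HSP so its subject interval stays on one side of ``pos``.

    ``side='left'`` keeps subject <= pos; ``'right'`` keeps subject >= pos.
    Chance few-base extensions across a junction are trimmed here (up to
    ``max_clip`` nt) rather than rejecting the pair; HSPs reaching further
    across are genuinely on the wrong side and yield None.  Query coordinates
    shrink by the same amount on the junction-facing end, respecting strand.
    The score is reduced by one match per clipped column (upper bound on the
    clipped contribution; used only for pair ranking).
    """
    if side == "left":
        over = h.s_end - pos
        if over <= 0:
            return h
        if over > max_clip or h.s_end - over <= h.s_start:
            return None
        if h.strand == "+":
            return replace(h, s_end=pos, q_end=h.q_end - over, score=h.score - over)
        return replace(h, s_end=pos, q_start=h.q_start + over, score=h.score - over)
    over = pos - h.s_start
    if over <= 0:
        return h
    if over > max_clip or h.s_start + over >= h.s_end:
        return None
    if h.strand == "+":
        return replace(h, s_start=pos, q_start=h.q_start + over, score=h.score - over)
    return replace(h, s_start=pos, q_end=h.q_end - over, score=h.score - over)


def classify_junctions(
    hsps: list[Hsp],
    model: TranscriptModel,
    object_sequences: dict[str, str],
    half_bridge_max_gap: int = 50,
    half_bridge_min_tail_frac: float = 0.6,
    bridge_max_gap: int = 50,
    trim_overlap: bool = True,
    min_cover_overhang: int = 4,
) -> list[JunctionCall]:
    """Classify every junction of ``model`` from object-vs-transcript HSPs.

    Per transcript object a junction is *covered* when one HSP spans its
    spliced position with >= 1 aligned nt each side; *bridged* when two HSPs
    flank it with extra object sequence strictly between them (the hidden-exon
    signature); *half_bridged* (N-flagged junctions only) when a single HSP
    ends within ``half_bridge_max_gap`` of the junction with an unaligned
    object tail > ``half_bridge_min_tail_frac`` of the object pointing at it.
    Calls are aggregated across objects with precedence
    bridged > covered > half_bridged > no_information.
    """
    calls: list[JunctionCall] = []
    by_object: dict[str, list[Hsp]] = {}
    for h in hsps:
        if h.subject_id == model.transcript_id:
            by_object.setdefault(h.query_id, []).append(h)

    for j, (_, _, pos) in enumerate(model.junctions):
        n_flag = model.n_island_flags[j] if model.n_island_flags else False
        best = JunctionCall(model.transcript_id, j, "no_information", n_flag)
        best_key = (-1, -1.0)
        for obj_id, obj_hsps in by_object.items():
            obj_seq = object_sequences[obj_id]
            call = _classify_one_object(
                obj_id, obj_seq, obj_hsps, j, pos, n_flag,
                half_bridge_max_gap, half_bridge_min_tail_frac,
                bridge_max_gap, trim_overlap, min_cover_overhang,
            )
            if call is None:
                continue
            call.transcript_id = model.transcript_id
            # among equal statuses the object with the highest summed HSP
            # score wins (alternates are recoverable from the raw HSPs)
            key = (STATUS_PRECEDENCE[call.status], sum(h.score for h in call.hsps))
            if key > best_key:
                best, best_key = call, key
        calls.append(best)
    return calls


def _classify_one_object(
    obj_id: str, obj_seq: str, obj_hsps: list[Hsp], j: int, pos: int,
    n_flag: bool, hb_gap: int, hb_tail: float, bridge_gap: int, trim: bool,
    cover_overhang: int = 4,
) -> JunctionCall | None:
    # objects are non-stranded: keep the best orientation (by summed score)
    strands = {"+": 0, "-": 0}
    for h in obj_hsps:
        strands[h.strand] += h.score
    strand = "+" if strands["+"] >= strands["-"] else "-"
    hs = [h for h in obj_hsps if h.strand == strand]

    # covered: one HSP continuing across the junction with a few aligned nt
    # on each side (chance x-drop extensions reach 1-3 nt, genuine coverage
    # far more, so a small overhang floor separates the two)
    covered = [
        h for h in hs
        if h.s_start + cover_overhang <= pos <= h.s_end - cover_overhang
    ]

    # bridged: pair (A left of junction, B right), non-overlapping, insert >= 1
    best_pair = None
    for a in hs:
        for b in hs:
            if a is b:
                continue
            if trim:
                ac = _clip_hsp_to_junction(a, pos, "left")
                bc = _clip_hsp_to_junction(b, pos, "right")
            else:
                ac = a if a.s_end <= pos else None
                bc = b if b.s_start >= pos else None
            if ac is None or bc is None:
                continue
            if not (ac.s_end <= pos <= bc.s_start):
                continue
            if pos - ac.s_end > bridge_gap or bc.s_start - pos > bridge_gap:
                continue
            if bc.s_start < ac.s_end:  # subject overlap (after optional clip)
                continue
            # query order follows strand; insert is object sequence between them
            if strand == "+":
                lo, hi = ac.q_end, bc.q_start
            else:
                lo, hi = bc.q_end, ac.q_start
            if hi - lo < 1:
                continue  # direct-repeat guard: no extra object sequence
            score = ac.score + bc.score
            insert_len = hi - lo
            key = (score, -insert_len)
            if best_pair is None or key > best_pair[0]:
                best_pair = (key, ac, bc, lo, hi)

    if best_pair is not None:
        _, ac, bc, lo, hi = best_pair
        insert = obj_seq[lo:hi]
        if strand == "-":
            insert = revcomp(insert)
        return JunctionCall(
            "", j, "bridged", n_flag, obj_id, [ac, bc], insert, (lo, hi), strand
        )
    if covered:
        h = max(covered, key=lambda h: h.score)
        return JunctionCall("", j, "covered", n_flag, obj_id, [h], strand=strand)
    if n_flag:
        L = len(obj_seq)
        for h in hs:
            # HSP left of the junction, tail hanging toward it
            if 0 <= pos - h.s_end <= hb_gap:
                tail = (L - h.q_end) if strand == "+" else h.q_start
                if tail / L > hb_tail:
                    return JunctionCall(
                        "", j, "half_bridged", n_flag, obj_id, [h], strand=strand
                    )
            if 0 <= h.s_start - pos <= hb_gap:
                tail = h.q_start if strand == "+" else (L - h.q_end)
                if tail / L > hb_tail:
                    return JunctionCall(
                        "", j, "half_bridged", n_flag, obj_id, [h], strand=strand
                    )
    return None


def aggregate_junction_table(calls: list[JunctionCall]) -> pd.DataFrame:
    """One row per junction with final status and best supporting object."""
    rows = []
    for c in calls:
        h = c.hsps[0] if c.hsps else None
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "junction_index": c.junction_index,
                "n_flag": c.n_flag,
                "status": c.status,
                "object_id": c.object_id,
                "insert_len": c.insert_length,
                "q_start": h.q_start if h else None,
                "q_end": h.q_end if h else None,
                "s_start": h.s_start if h else None,
                "s_end": h.s_end if h else None,
            }
        )
    return pd.DataFrame(rows)


def junction_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts by (n_flag x status)."""
    return (
        table.groupby(["n_flag", "status"]).size().rename("count").reset_index()
    )
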