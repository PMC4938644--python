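"""Consensus islands: genomic reads aligned locally to a transcript object.

A transcript object transcribed from discontiguous genomic segments (exons)
shows a sharp signature when genomic reads are aligned to it locally: read
alignment *starts* pile up at the template position where each segment
begins and *finishes* pile up where it ends, because a read crossing the
segment boundary in the genome can only align its within-segment part.
Those pileups seed iterative majority-consensus growth: each segment
re-assembles from its reads into an island whose core matches the template
and whose tails (the unaligned read overhangs, up to read length minus the
minimum local alignment length, typically ~80 nt) extend into flanking
genomic — intronic — sequence the template does not contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bridges import AlignParams, _extend_xdrop
from .seqio import ReadSet, revcomp

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class LocalReadAlignment:
    read_id: str
    template_id: str
    t_start: int
    t_end: int
    r_start: int  # on the oriented read
    r_end: int
    strand: str
    mismatches: int
    oriented_seq: str
    codes: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = encode(self.oriented_seq)

    @property
    def length(self) -> int:
        return self.t_end - self.t_start

    @property
    def offset(self) -> int:
        """Template-axis coordinate of oriented-read base 0."""
        return self.t_start - self.r_start

    @property
    def span(self) -> tuple[int, int]:
        """Template-axis interval covered by the whole read (incl. overhangs)."""
        return self.offset, self.offset + len(self.oriented_seq)


def local_align_reads(
    reads: ReadSet,
    template: str,
    min_local_length: int = 20,
    max_mismatch_frac: float = 0.05,
    template_id: str = "template",
    word_size: int = 11,
) -> list[LocalReadAlignment]:
    """Best ungapped local alignment of each read (both strands) to a template.

    Word seeding at a stride that guarantees any exact block of
    ``min_local_length`` contains a probed word, x-drop extension trimmed to
    the maximal-scoring segment.  Alignments shorter than
    ``min_local_length`` or with more than ``max_mismatch_frac`` mismatching
    columns are not reported.
    """
    if not template:
        raise ValueError("empty template")
    w = word_size
    params = AlignParams(word_size=w)
    index: dict[str, list[int]] = {}
    for i in range(len(template) - w + 1):
        word = template[i : i + w]
        if "N" not in word:
            index.setdefault(word, []).append(i)
    stride = max(1, min_local_length - w + 1)
    out = []
    for rid, seq, _ in reads:
        best = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            probes = list(range(0, len(oriented) - w + 1, stride))
            if probes and probes[-1] != len(oriented) - w:
                probes.append(len(oriented) - w)
            seen_diags: set[int] = set()
            for p in probes:
                hits = index.get(oriented[p : p + w])
                if not hits:
                    continue
                for si in hits:
                    diag = p - si
                    if diag in seen_diags:
                        continue
                    seen_diags.add(diag)
                    qa, qb, sa, sb, score = _extend_xdrop(
                        oriented, template, p, si, p + w, si + w, params
                    )
                    if qb - qa < min_local_length:
                        continue
                    mism = sum(
                        1
                        for a, b in zip(oriented[qa:qb], template[sa:sb])
                        if a != b or a == "N"
                    )
                    if mism > max_mismatch_frac * (qb - qa):
                        continue
                    cand = (score, -sa, strand, qa, qb, sa, sb, mism, oriented)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        if best is not None:
            score, _, strand, qa, qb, sa, sb, mism, oriented = best
            out.append(
                LocalReadAlignment(
                    rid, template_id, sa, sb, qa, qb, strand, mism, oriented
                )
            )
    return out


@dataclass
class BoundarySignal:
    position: int
    start_count: int
    finish_count: int
    enrichment: float
    side: str  # start | finish


def detect_boundaries(
    alignments: list[LocalReadAlignment],
    template_length: int,
    seed_enrichment_threshold: float = 10.0,
    min_seed_count: int = 4,
) -> list[BoundarySignal]:
    """Positions whose start/finish pileup exceeds the interior mean.

    Template termini are excluded from the interior mean (and are implicit
    seeds downstream).  ``min_seed_count`` suppresses Poisson noise at thin
    depth; a true boundary at usable depth exceeds it by an order of
    magnitude.
    """
    if not alignments:
        raise ValueError("no alignments")
    L = template_length
    starts = np.zeros(L + 1, dtype=int)
    finishes = np.zeros(L + 1, dtype=int)
    for a in alignments:
        starts[a.t_start] += 1
        finishes[a.t_end] += 1
    interior = slice(1, L)
    mean_start = max(float(starts[interior].mean()), 1e-9)
    mean_finish = max(float(finishes[interior].mean()), 1e-9)
    signals = []
    for pos in range(1, L):
        if starts[pos] >= min_seed_count and starts[pos] >= seed_enrichment_threshold * mean_start:
            signals.append(
                BoundarySignal(pos, int(starts[pos]), int(finishes[pos]),
                               starts[pos] / mean_start, "start")
            )
        if finishes[pos] >= min_seed_count and finishes[pos] >= seed_enrichment_threshold * mean_finish:
            signals.append(
                BoundarySignal(pos, int(starts[pos]), int(finishes[pos]),
                               finishes[pos] / mean_finish, "finish")
            )
    signals.sort(key=lambda s: (s.position, s.side))
    return signals


@dataclass
class ConsensusIsland:
    template_id: str
    core_start: int
    core_end: int
    consensus: str  # left tail + core + right tail
    consensus_start: int  # template-axis coordinate of consensus[0]
    n_reads: int
    depth: np.ndarray = field(repr=False, default=None)
    agreement: np.ndarray = field(repr=False, default=None)
    read_ids: list[str] = field(default_factory=list, repr=False)
    low_confidence: bool = False

    @property
    def left_tail_len(self) -> int:
        return self.core_start - self.consensus_start

    @property
    def right_tail_len(self) -> int:
        return self.consensus_start + len(self.consensus) - self.core_end

    @property
    def is_empty(self) -> bool:
        return self.n_reads == 0

    def base_at(self, axis_pos: int) -> str:
        """Consensus base at a template-axis coordinate ('N' if uncovered)."""
        i = axis_pos - self.consensus_start
        if 0 <= i < len(self.consensus):
            return self.consensus[i]
        return "N"

    def slice_at(self, lo: int, hi: int) -> str:
        return "".join(self.base_at(p) for p in range(lo, hi))


def _consensus_from(
    members: list[LocalReadAlignment],
    template_codes: np.ndarray,
    consensus_majority: float,
):
    """Majority-vote consensus of placed reads on the template axis.

    Returns (call codes, depth, agreement, axis_lo).  Ties break toward the
    template base where the template covers the position, else toward the
    alphabetically first base.
    """
    lo = min(a.span[0] for a in members)
    hi = max(a.span[1] for a in members)
    counts = np.zeros((hi - lo, 4), dtype=np.int32)
    for a in members:
        off = a.offset - lo
        codes = a.codes
        idx = np.nonzero(codes < 4)[0]
        counts[off + idx, codes[idx]] += 1
    depth = counts.sum(axis=1)
    maxc = counts.max(axis=1)
    call = np.argmax(counts, axis=1).astype(np.uint8)  # lowest index on ties
    # tie toward template inside template range
    t_lo = max(lo, 0)
    t_hi = min(hi, len(template_codes))
    if t_hi > t_lo:
        seg = slice(t_lo - lo, t_hi - lo)
        tmpl = template_codes[t_lo:t_hi]
        tied_with_template = (
            counts[np.arange(t_lo - lo, t_hi - lo), tmpl] == maxc[seg]
        )
        call[seg] = np.where(tied_with_template, tmpl, call[seg])
    call[depth == 0] = 4
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(depth > 0, maxc / np.maximum(depth, 1), 0.0)
    del consensus_majority  # recorded per position via agreement
    return call, depth, agreement, lo


def _core_bounds(members: list[LocalReadAlignment]) -> tuple[int, int]:
    """Core interval from the members' *aligned* coverage.

    Chance single-base extensions of boundary reads smear a minority of
    aligned ends a few nt past the true segment edge; requiring a quarter of
    the island's typical aligned depth (>= 2 reads) trims that smear while
    keeping true terminal direct repeats, which every boundary read crosses.
    """
    lo = min(a.t_start for a in members)
    hi = max(a.t_end for a in members)
    depth = np.zeros(hi - lo, dtype=np.int32)
    for a in members:
        depth[a.t_start - lo : a.t_end - lo] += 1
    covered = depth[depth > 0]
    thr = max(2, int(np.ceil(0.25 * float(np.median(covered)))))
    ok = np.nonzero(depth >= thr)[0]
    if len(ok) == 0:
        ok = np.nonzero(depth > 0)[0]
    return lo + int(ok[0]), lo + int(ok[-1]) + 1


def _member_ok(
    a: LocalReadAlignment,
    call: np.ndarray,
    depth: np.ndarray,
    lo: int,
    min_agree_overlap: int,
    max_mismatch_frac: float,
) -> bool:
    s, e = a.span
    cs, ce = max(s, lo), min(e, lo + len(call))
    if ce - cs <= 0:
        return False
    codes = a.codes[cs - a.offset : ce - a.offset]
    cons = call[cs - lo : ce - lo]
    cov = (depth[cs - lo : ce - lo] > 0) & (cons < 4) & (codes < 4)
    n = int(cov.sum())
    if n < min_agree_overlap:
        return False
    mism = int((codes[cov] != cons[cov]).sum())
    return mism <= max_mismatch_frac * n


def grow_island(
    seed: BoundarySignal,
    alignments: list[LocalReadAlignment],
    template: str,
    consensus_majority: float = 0.75,
    min_agree_overlap: int = 20,
    max_mismatch_frac: float = 0.05,
    max_rounds: int = 50,
    template_id: str = "template",
) -> ConsensusIsland:
    """Grow one consensus island from a boundary seed.

    Starts from the reads whose alignment starts (or finishes) exactly at
    the seed position, then iterates: majority consensus over the recruited
    set; membership re-evaluated for *every* template-aligned read by
    agreement with the consensus over >= ``min_agree_overlap`` positions at
    <= ``max_mismatch_frac`` disagreement.  Reads aligned only through an
    internal repeat disagree with the consensus outside the repeat and are
    discarded.  Terminates at a fixed point or after ``max_rounds``.
    """
    tmpl_codes = encode(template)
    if seed.side == "start":
        members = [a for a in alignments if a.t_start == seed.position]
    else:
        members = [a for a in alignments if a.t_end == seed.position]
    if not members:
        return ConsensusIsland(template_id, seed.position, seed.position, "",
                               seed.position, 0, np.zeros(0, int),
                               np.zeros(0), [], True)
    seen: set[frozenset] = set()
    for _ in range(max_rounds):
        call, depth, agreement, lo = _consensus_from(
            members, tmpl_codes, consensus_majority
        )
        new_members = [
            a for a in alignments
            if _member_ok(a, call, depth, lo, min_agree_overlap, max_mismatch_frac)
        ]
        if not new_members:
            break
        key = frozenset(id(a) for a in new_members)
        if key in seen:
            members = new_members
            break
        seen.add(key)
        members = new_members
    call, depth, agreement, lo = _consensus_from(members, tmpl_codes, consensus_majority)
    covered = np.nonzero(depth > 0)[0]
    a0, a1 = int(covered[0]), int(covered[-1]) + 1
    core_start, core_end = _core_bounds(members)
    consensus = _BASES[call[a0:a1]].tobytes().decode()
    return ConsensusIsland(
        template_id,
        core_start,
        core_end,
        consensus,
        lo + a0,
        len(members),
        depth[a0:a1],
        agreement[a0:a1],
        [a.read_id for a in members],
        low_confidence=len(members) < 4,
    )


def _merge_group(
    group: list[tuple[ConsensusIsland, list[LocalReadAlignment]]],
    template: str,
    template_id: str,
    consensus_majority: float,
    min_agree_overlap: int = 20,
    max_mismatch_frac: float = 0.05,
) -> ConsensusIsland:
    by_id: dict[int, LocalReadAlignment] = {}
    for _, mem in group:
        for a in mem:
            by_id[id(a)] = a
    members = list(by_id.values())
    tmpl_codes = encode(template)
    # one membership pass against the union consensus: reads recruited into a
    # repeat-seeded duplicate island but disagreeing with the majority here
    # (e.g. repeat-only foreign reads) are dropped before the final call
    call, depth, agreement, lo = _consensus_from(
        members, tmpl_codes, consensus_majority
    )
    filtered = [
        a for a in members
        if _member_ok(a, call, depth, lo, min_agree_overlap, max_mismatch_frac)
    ]
    if filtered:
        members = filtered
    call, depth, agreement, lo = _consensus_from(
        members, tmpl_codes, consensus_majority
    )
    covered = np.nonzero(depth > 0)[0]
    a0, a1 = int(covered[0]), int(covered[-1]) + 1
    core_start, core_end = _core_bounds(members)
    return ConsensusIsland(
        template_id,
        core_start,
        core_end,
        _BASES[call[a0:a1]].tobytes().decode(),
        lo + a0,
        len(members),
        depth[a0:a1],
        agreement[a0:a1],
        [a.read_id for a in members],
        low_confidence=len(members) < 4,
    )


def islands_for_template(
    reads: ReadSet,
    template: str,
    template_id: str = "template",
    min_local_length: int = 20,
    max_mismatch_frac: float = 0.05,
    seed_enrichment_threshold: float = 10.0,
    consensus_majority: float = 0.75,
    min_agree_overlap: int = 20,
    max_rounds: int = 50,
    merge_overlap: int = 10,
    alignments: list[LocalReadAlignment] | None = None,
) -> list[ConsensusIsland]:
    """Boundary detection + growth + merge for one transcript object.

    Template termini act as implicit seeds so terminal segments also produce
    islands; islands whose cores overlap by more than ``merge_overlap`` nt
    are duplicates of the same genomic segment and are merged (read sets
    united, consensus recomputed).  Small core overlaps are *kept* separate:
    a k-nt terminal direct repeat makes two genuinely distinct islands
    overlap by k.  Returned islands are ordered by core start.
    """
    if alignments is None:
        alignments = local_align_reads(
            reads, template, min_local_length, max_mismatch_frac, template_id
        )
    if not alignments:
        return []
    L = len(template)
    signals = detect_boundaries(alignments, L, seed_enrichment_threshold)
    seeds = [BoundarySignal(0, 0, 0, float("inf"), "start"),
             BoundarySignal(L, 0, 0, float("inf"), "finish")] + signals
    grown: list[tuple[ConsensusIsland, list[LocalReadAlignment]]] = []
    for seed in seeds:
        isl = grow_island(
            seed, alignments, template, consensus_majority,
            min_agree_overlap, max_mismatch_frac, max_rounds, template_id
        )
        if isl.is_empty:
            continue
        ids = set(isl.read_ids)
        mem = [a for a in alignments if a.read_id in ids]
        grown.append((isl, mem))
    # merge islands with overlapping cores
    grown.sort(key=lambda t: (t[0].core_start, t[0].core_end))
    merged: list[ConsensusIsland] = []
    group: list[tuple[ConsensusIsland, list[LocalReadAlignment]]] = []
    group_end = -1
    for isl, mem in grown:
        if group and isl.core_start < group_end - merge_overlap:
            group.append((isl, mem))
            group_end = max(group_end, isl.core_end)
        else:
            if group:
                merged.append(
                    _merge_group(group, template, template_id, consensus_majority,
                                 min_agree_overlap, max_mismatch_frac)
                )
            group = [(isl, mem)]
            group_end = isl.core_end
    if group:
        merged.append(_merge_group(group, template, template_id, consensus_majority,
                                   min_agree_overlap, max_mismatch_frac))
    merged.sort(key=lambda i: (i.core_start, i.core_end))
    return merged
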