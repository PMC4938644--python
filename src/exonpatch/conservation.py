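"""Translated-alignment conservation test with scrambled-insert control.

A bridge insert (the transcript-object sequence sitting between the two
HSPs flanking an N-island junction) is genuine coding sequence only if
adding it back between the flanks *improves* a translated alignment against
a pre-selected homologous peptide.  The control replaces the insert by a
random permutation of its nucleotides, the null model for an untranslated
in-silico artifact; an improvement that survives the real insert but never
the scrambled one is evidence of conservation.  The score
increase considered significant defaults to 10, above what scrambled
controls ever reach at these parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import revcomp

_MATRICES: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


@dataclass(frozen=True)
class ProteinAlignParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11  # cost of a gap of length 1 is gap_open + gap_extend
    gap_extend: int = 1
    min_anchor_score: float = 40.0
    # x-drop for the constrained insert crossing, raw score units.  Translated
    # search tools prune gapped extensions whose running score falls ~15 bits
    # (~40 raw BLOSUM62 units) below the best point reached; a junk insert
    # crossing between two anchors dips below that almost surely and never
    # "bridges", which is what bounds the scrambled control near zero.
    crossing_x_drop: float = 40.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


def _aligner(params: ProteinAlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _matrix(params.matrix)
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -float(params.gap_extend)
    return al


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame; +1..+3 forward, -1..-3 on the reverse complement.

    Stop codons become '*', which BLOSUM62 scores at the matrix minimum
    against every residue; codons containing N become 'X'.
    """
    if frame > 0:
        seq = nt[frame - 1 :]
    else:
        seq = revcomp(nt)[-frame - 1 :]
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return ""
    return str(Seq(seq).translate())


def translated_best_score(
    query_nt: str,
    subject_pep: str,
    params: ProteinAlignParams = ProteinAlignParams(),
) -> tuple[float, int | None, tuple[int, int] | None]:
    """Best local protein alignment score over all six reading frames.

    Returns (score, frame, subject interval of the best alignment); frame is
    None when no frame yields a positive-scoring alignment.
    """
    if len(query_nt) < 3:
        raise ValueError("query shorter than one codon")
    if not subject_pep:
        raise ValueError("empty subject peptide")
    al = _aligner(params)
    best: tuple[float, int | None, tuple[int, int] | None] = (0.0, None, None)
    for frame in (1, 2, 3, -1, -2, -3):
        pep = translate_frame(query_nt, frame)
        if not pep:
            continue
        try:
            alns = al.align(pep, subject_pep)
            score = alns.score
        except (ValueError, OverflowError):
            continue
        if score > best[0]:
            interval = None
            try:
                a = alns[0]
                sub = a.aligned[1]
                if len(sub):
                    interval = (int(sub[0][0]), int(sub[-1][1]))
            except Exception:
                interval = None
            best = (float(score), frame, interval)
    return best


def best_subject(
    query_nt: str, proteome: dict[str, str], params: ProteinAlignParams = ProteinAlignParams()
) -> tuple[str | None, float]:
    """Highest-scoring peptide in a proteome for a nucleotide query."""
    best_id, best_score = None, 0.0
    for pid, pep in proteome.items():
        score, _, _ = translated_best_score(query_nt, pep, params)
        if score > best_score:
            best_id, best_score = pid, score
    return best_id, best_score


@dataclass
class ImprovementResult:
    object_id: str
    subject_id: str
    score_extended: float  # S1
    score_flanks_only: float  # S2
    scrambled_scores: list[float]  # S3 replicates
    verdict: str  # conserved | not_conserved | no_common_subject
    improvement_threshold: float = 10.0

    @property
    def delta(self) -> float:
        return self.score_extended - self.score_flanks_only

    @property
    def max_scrambled_delta(self) -> float:
        if not self.scrambled_scores:
            return float("-inf")
        return max(self.scrambled_scores) - self.score_flanks_only


def scramble_insert(
    insert: str,
    lead_phase: int,
    rng: np.random.Generator,
    level: str = "nucleotide",
) -> str:
    """Randomly permute the intervening sequence.

    ``level='nucleotide'`` (default) permutes every base of the insert,
    destroying both reading frame and codon structure — the null model for
    "this insert is not translated in vivo".  ``level='codon'`` permutes
    whole codons in the frame continuous with the left flank (``lead_phase``
    bases complete the flank's partial codon and stay fixed), which permutes
    the amino-acid sequence while preserving each residue's codon.  The
    codon mode preserves amino-acid composition exactly, which leaves a
    heavier-tailed chance-alignment null (see methods note).
    """
    if level == "nucleotide":
        perm = rng.permutation(len(insert))
        return "".join(insert[i] for i in perm)
    if level != "codon":
        raise ValueError(f"unknown scramble level {level!r}")
    lead = insert[:lead_phase]
    body = insert[lead_phase:]
    tail_len = len(body) % 3
    tail = body[len(body) - tail_len :] if tail_len else ""
    codons = [body[i : i + 3] for i in range(0, len(body) - tail_len, 3)]
    perm = rng.permutation(len(codons))
    return lead + "".join(codons[i] for i in perm) + tail


def _xdrop_global_score(a: str, b: str, params: ProteinAlignParams) -> float | None:
    """End-anchored affine-gap alignment score of peptides a vs b with x-drop.

    The path must run from (0,0) to (len(a), len(b)); any cell whose best
    path score falls more than ``crossing_x_drop`` below the best score seen
    so far is pruned.  Returns None when no path survives pruning.
    """
    mat = _matrix(params.matrix)
    alpha = str(mat.alphabet)
    idx = {c: alpha.index(c) for c in set(a + b) if c in alpha}
    open_cost = params.gap_open + params.gap_extend
    ext = params.gap_extend
    x = params.crossing_x_drop
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [0.0] + [NEG] * m
    # first row: leading gap in b
    for j in range(1, m + 1):
        H[j] = -(params.gap_open + ext * j)
        if H[j] < -x:
            H[j] = NEG
    best = 0.0
    Fcol = [NEG] * (m + 1)
    for i in range(1, n + 1):
        ai = idx.get(a[i - 1])
        prev_diag = H[0]
        H0 = -(params.gap_open + ext * i)
        H[0] = H0 if H0 >= best - x else NEG
        E_run = NEG
        row_best = H[0]
        for j in range(1, m + 1):
            bj = idx.get(b[j - 1])
            s = float(mat[ai, bj]) if ai is not None and bj is not None else 0.0
            diag = prev_diag + s if prev_diag > NEG else NEG
            E_run = max(
                E_run - ext if E_run > NEG else NEG,
                H[j - 1] - open_cost if H[j - 1] > NEG else NEG,
            )
            Fcol[j] = max(
                Fcol[j] - ext if Fcol[j] > NEG else NEG,
                H[j] - open_cost if H[j] > NEG else NEG,
            )
            prev_diag = H[j]
            val = max(diag, E_run, Fcol[j])
            H[j] = val if val >= best - x else NEG
            if H[j] > row_best:
                row_best = H[j]
        if row_best > best:
            best = row_best
        if row_best == NEG:
            return None
    return None if H[m] == NEG else H[m]


def insert_gain(
    insert_nt: str,
    lead_phase: int,
    gap_pep: str,
    params: ProteinAlignParams = ProteinAlignParams(),
) -> float:
    """Positionally constrained score contribution of a bridge insert.

    The insert sits at an exactly known place between the two flank anchors,
    so its translation must explain the subject's *inter-anchor* segment
    end-to-end: the gain is the end-anchored affine-gap alignment score of
    the insert's in-frame translation against that segment, floored at 0,
    with x-drop pruning.  A free-floating local alignment is deliberately not
    used here — a junk insert of matching composition can always scrape
    together a small positive local score somewhere — and the x-drop stops a
    junk crossing from "bridging" the anchors at all, which is what keeps
    the scrambled control near zero.
    """
    body = insert_nt[lead_phase:]
    pep = translate_frame(body, 1) if len(body) >= 3 else ""
    if not pep or not gap_pep:
        return 0.0
    score = _xdrop_global_score(pep, gap_pep, params)
    if score is None:
        return 0.0
    return max(0.0, float(score))


def improvement_test(
    flank_left_nt: str,
    flank_right_nt: str,
    insert_nt: str,
    subject_pep: str,
    params: ProteinAlignParams = ProteinAlignParams(),
    n_scrambles: int = 20,
    improvement_threshold: float = 10.0,
    rng_seed: int = 0,
    scramble_level: str = "nucleotide",
    object_id: str = "object",
    subject_id: str = "subject",
) -> ImprovementResult:
    """Score the extended query (flanks + insert) against flanks alone.

    Inputs are expected in mRNA-sense orientation.  S2 is the sum of the two
    flank anchors, each aligned locally to the subject on its own (the two
    HSPs a translated search reports for the flanks-only query — the subject
    segment between them is not charged as a deletion).  S1 adds the
    insert's positionally constrained gain against the subject segment
    between the anchors; S3 replicates do the same with codon-permuted
    inserts.  Verdict is *conserved* iff the flanks anchor the subject
    (S2 >= min_anchor_score), S1 - S2 exceeds the threshold, and no
    scrambled replicate's increase does.
    """
    if not insert_nt:
        raise ValueError("empty insert")
    rng = np.random.default_rng(rng_seed)
    f1, fr1, iv1 = (
        translated_best_score(flank_left_nt, subject_pep, params)
        if len(flank_left_nt) >= 3
        else (0.0, None, None)
    )
    f2, fr2, iv2 = (
        translated_best_score(flank_right_nt, subject_pep, params)
        if len(flank_right_nt) >= 3
        else (0.0, None, None)
    )
    s2 = f1 + f2
    # subject segment strictly between the two anchors, when they are
    # collinear on the same strand sense; otherwise no constrained slot
    gap_pep = ""
    if iv1 is not None and iv2 is not None and iv2[0] >= iv1[1]:
        if fr1 is not None and fr2 is not None and (fr1 > 0) == (fr2 > 0):
            gap_pep = subject_pep[iv1[1] : iv2[0]]
    lead_phase = (3 - len(flank_left_nt) % 3) % 3
    s1 = s2 + insert_gain(insert_nt, lead_phase, gap_pep, params)
    s3s = []
    for _ in range(n_scrambles):
        scr = scramble_insert(insert_nt, lead_phase, rng, level=scramble_level)
        s3s.append(s2 + insert_gain(scr, lead_phase, gap_pep, params))
    if s2 < params.min_anchor_score:
        verdict = "no_common_subject"
    elif (s1 - s2) > improvement_threshold and (
        not s3s or max(s3s) - s2 <= improvement_threshold
    ):
        verdict = "conserved"
    else:
        verdict = "not_conserved"
    return ImprovementResult(
        object_id, subject_id, float(s1), float(s2), s3s, verdict,
        improvement_threshold,
    )
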