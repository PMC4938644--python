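"""Donor/acceptor splice-site position-weight model.

The model is trained on annotated junctions and scores a candidate junction
in bits using the letter-height convention: each position contributes
``p_i(b) * IC_i`` where ``p_i(b)`` is the training frequency of the observed
nucleotide ``b`` and ``IC_i = 2 - H_i`` is the position's information
content (Shannon entropy over the four nucleotides, in bits).  Under this
convention four invariant intron-terminal dinucleotide positions (GT...AG)
contribute exactly 8 bits, and a fully conserved site scores the model's
maximum possible score — the readings consistent with a realistic splice
consensus totalling ~15 bits.

A candidate is called *high confidence* by a two-step test: the literal
GT/AG dinucleotides must be present, and the summed score must reach the
cutoff (default 11 bits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seqio import GenomeAssembly, TranscriptModel, revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SpliceWindows:
    """Window extents around the two intron ends.

    The donor window covers the exon/intron boundary: ``donor_exonic`` bases
    of exon then ``donor_intronic`` bases of intron (which include the GT).
    The acceptor window covers ``acceptor_intronic`` bases of intron (which
    include the AG) then ``acceptor_exonic`` bases of exon.
    """

    donor_exonic: int = 3
    donor_intronic: int = 10
    acceptor_intronic: int = 12
    acceptor_exonic: int = 3

    def __post_init__(self) -> None:
        if self.donor_intronic < 2 or self.acceptor_intronic < 2:
            raise ValueError("intronic sides must include the terminal dinucleotide")

    @property
    def donor_len(self) -> int:
        return self.donor_exonic + self.donor_intronic

    @property
    def acceptor_len(self) -> int:
        return self.acceptor_intronic + self.acceptor_exonic


@dataclass
class SplicePwm:
    windows: SpliceWindows
    donor_probs: np.ndarray  # (donor_len, 4)
    acceptor_probs: np.ndarray  # (acceptor_len, 4)
    donor_ic: np.ndarray = field(init=False)
    acceptor_ic: np.ndarray = field(init=False)
    training_count: int = 0
    pseudocount: float = 0.0
    score_cutoff: float = 11.0

    def __post_init__(self) -> None:
        for probs in (self.donor_probs, self.acceptor_probs):
            sums = probs.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("per-position probabilities must sum to 1")
        self.donor_ic = _information_content(self.donor_probs)
        self.acceptor_ic = _information_content(self.acceptor_probs)

    @property
    def max_possible_score(self) -> float:
        return float(
            (self.donor_probs.max(axis=1) * self.donor_ic).sum()
            + (self.acceptor_probs.max(axis=1) * self.acceptor_ic).sum()
        )

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str, extra_meta: dict | None = None) -> None:
        data = {
            "windows": {
                "donor_exonic": self.windows.donor_exonic,
                "donor_intronic": self.windows.donor_intronic,
                "acceptor_intronic": self.windows.acceptor_intronic,
                "acceptor_exonic": self.windows.acceptor_exonic,
            },
            "donor_probs": self.donor_probs.tolist(),
            "acceptor_probs": self.acceptor_probs.tolist(),
            "donor_ic": self.donor_ic.tolist(),
            "acceptor_ic": self.acceptor_ic.tolist(),
            "training_count": self.training_count,
            "pseudocount": self.pseudocount,
            "score_cutoff": self.score_cutoff,
            "max_possible_score": self.max_possible_score,
            "note": "window extents and pseudocount are package defaults",
        }
        if extra_meta:
            data.update(extra_meta)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SplicePwm":
        with open(path) as fh:
            d = json.load(fh)
        w = SpliceWindows(**d["windows"])
        return cls(
            w,
            np.array(d["donor_probs"]),
            np.array(d["acceptor_probs"]),
            training_count=d.get("training_count", 0),
            pseudocount=d.get("pseudocount", 0.0),
            score_cutoff=d.get("score_cutoff", 11.0),
        )

    def to_tsv(self, path: str) -> None:
        """Plain matrix export (for external logo plotting)."""
        with open(path, "w") as fh:
            fh.write("site\tposition\tA\tC\tG\tT\tic\n")
            for name, probs, ic in (
                ("donor", self.donor_probs, self.donor_ic),
                ("acceptor", self.acceptor_probs, self.acceptor_ic),
            ):
                for i in range(probs.shape[0]):
                    vals = "\t".join(f"{v:.6g}" for v in probs[i])
                    fh.write(f"{name}\t{i}\t{vals}\t{ic[i]:.6g}\n")


def _information_content(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    return 2.0 + plogp.sum(axis=1)


def extract_training_junctions(
    models: list[TranscriptModel],
    genome: GenomeAssembly,
    windows: SpliceWindows = SpliceWindows(),
    exclude_n_flagged: bool = True,
) -> tuple[list[str], list[str], int]:
    """Strand-oriented donor/acceptor window sequences from annotated introns.

    Returns (donor_seqs, acceptor_seqs, n_skipped).  Sites whose window
    contains N, falls outside the contig, or whose intron is shorter than the
    two intronic sides are skipped and counted.
    """
    donors, acceptors, skipped = [], [], 0
    for m in models:
        contig = genome.sequences[m.contig]
        for j in range(len(m.junctions)):
            if exclude_n_flagged and m.n_island_flags and m.n_island_flags[j]:
                continue
            istart, iend = m.junction_intron(j)
            if iend - istart < windows.donor_intronic + windows.acceptor_intronic:
                skipped += 1
                continue
            d, a = junction_windows_from_genome(contig, istart, iend, m.strand, windows)
            if d is None or "N" in d or "N" in a:
                skipped += 1
                continue
            donors.append(d)
            acceptors.append(a)
    return donors, acceptors, skipped


def junction_windows_from_genome(
    contig: str, istart: int, iend: int, strand: str, windows: SpliceWindows
) -> tuple[str | None, str | None]:
    """Donor/acceptor window sequences for an intron at [istart, iend)."""
    w = windows
    if strand == "+":
        d_lo, d_hi = istart - w.donor_exonic, istart + w.donor_intronic
        a_lo, a_hi = iend - w.acceptor_intronic, iend + w.acceptor_exonic
        if d_lo < 0 or a_hi > len(contig):
            return None, None
        return contig[d_lo:d_hi], contig[a_lo:a_hi]
    d_lo, d_hi = iend - w.donor_intronic, iend + w.donor_exonic
    a_lo, a_hi = istart - w.acceptor_exonic, istart + w.acceptor_intronic
    if a_lo < 0 or d_hi > len(contig):
        return None, None
    return revcomp(contig[d_lo:d_hi]), revcomp(contig[a_lo:a_hi])


def _freqs(seqs: list[str], length: int, pseudocount: float) -> np.ndarray:
    counts = np.full((length, 4), pseudocount, dtype=float)
    for s in seqs:
        if len(s) != length:
            raise ValueError(f"window length {len(s)} != expected {length}")
        for i, b in enumerate(s):
            if b in BASE_INDEX:
                counts[i, BASE_INDEX[b]] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("position with zero observations and zero pseudocount")
    return counts / totals


def build_pwm(
    donor_seqs: list[str],
    acceptor_seqs: list[str],
    windows: SpliceWindows = SpliceWindows(),
    pseudocount: float = 0.0,
    score_cutoff: float = 11.0,
    min_sites: int = 10,
) -> SplicePwm:
    if len(donor_seqs) < min_sites or len(acceptor_seqs) < min_sites:
        raise ValueError(
            f"need >= {min_sites} training sites, got "
            f"{len(donor_seqs)}/{len(acceptor_seqs)}"
        )
    return SplicePwm(
        windows,
        _freqs(donor_seqs, windows.donor_len, pseudocount),
        _freqs(acceptor_seqs, windows.acceptor_len, pseudocount),
        training_count=min(len(donor_seqs), len(acceptor_seqs)),
        pseudocount=pseudocount,
        score_cutoff=score_cutoff,
    )


def _window_score(seq: str, probs: np.ndarray, ic: np.ndarray) -> float:
    total = 0.0
    for i, b in enumerate(seq):
        k = BASE_INDEX.get(b)
        if k is not None:  # N contributes 0
            total += probs[i, k] * ic[i]
    return total


def score_junction(donor_seq: str, acceptor_seq: str, pwm: SplicePwm) -> float:
    """Summed letter-height score (bits) of a candidate junction."""
    w = pwm.windows
    if len(donor_seq) != w.donor_len or len(acceptor_seq) != w.acceptor_len:
        raise ValueError(
            f"window length mismatch: got {len(donor_seq)}/{len(acceptor_seq)}, "
            f"expected {w.donor_len}/{w.acceptor_len}"
        )
    return _window_score(donor_seq, pwm.donor_probs, pwm.donor_ic) + _window_score(
        acceptor_seq, pwm.acceptor_probs, pwm.acceptor_ic
    )


def has_terminal_dinucleotides(donor_seq: str, acceptor_seq: str, w: SpliceWindows) -> bool:
    gt = donor_seq[w.donor_exonic : w.donor_exonic + 2]
    ag = acceptor_seq[w.acceptor_intronic - 2 : w.acceptor_intronic]
    return gt == "GT" and ag == "AG"


def high_confidence(donor_seq: str, acceptor_seq: str, pwm: SplicePwm) -> bool:
    """Two-step test: literal GT...AG plus score >= cutoff."""
    return has_terminal_dinucleotides(donor_seq, acceptor_seq, pwm.windows) and (
        score_junction(donor_seq, acceptor_seq, pwm) >= pwm.score_cutoff
    )
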