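"""Readers/writers and the shared coordinate model.

All internal coordinates are 0-based half-open on the forward strand of a
contig.  GFF3 input/output converts to and from the standard 1-based
inclusive dialect.  Sequences are upper-case strings over ``ACGTN``;
soft-masking in input files is folded away.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import reverse_complement as _rc

VALID_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    pass


class SequenceValidationError(ValueError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return _rc(seq)


@dataclass
class GenomeAssembly:
    """A genome (or draft assembly): contig id -> ACGTN sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq:
                raise SequenceValidationError(f"contig {cid!r} is empty")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                off = min(i for i, b in enumerate(seq) if b in bad)
                raise SequenceValidationError(
                    f"contig {cid!r}: non-ACGTN residue {seq[off]!r} at offset {off}"
                )

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.sequences[contig][start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences


@dataclass
class NIsland:
    """A maximal run of N in an assembly contig, with its genomic context."""

    contig: str
    start: int
    end: int
    context: str = "intergenic"  # intronic | exonic | flanking | intergenic
    host_transcript: str | None = None
    host_intron_index: int | None = None
    boundary_tie: bool = False  # island abuts an annotated exon boundary exactly

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A reference transcript: ordered exons on a contig plus derived fields.

    ``exons`` are genomic intervals sorted by coordinate.  ``junctions`` are
    ordered along the *transcript* (strand-oriented): junction ``j`` sits at
    spliced position equal to the cumulative exon length through the j-th
    transcript exon.  ``n_island_flags[j]`` is True when at least one N-island
    lies strictly between the junction's flanking exons.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    spliced_sequence: str = ""
    junctions: list[tuple[int, int, int]] = field(default_factory=list)
    n_island_flags: list[bool] = field(default_factory=list)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceValidationError(
                f"{self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        if not self.exons:
            raise SequenceValidationError(f"{self.transcript_id}: no exons")
        ex = sorted(self.exons)
        if ex != self.exons:
            self.exons = ex
        for (s, e) in self.exons:
            if e - s < 1:
                raise SequenceValidationError(
                    f"{self.transcript_id}: empty exon [{s},{e})"
                )
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise SequenceValidationError(
                    f"{self.transcript_id}: overlapping exons at {e0}/{s1}"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def transcript_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[tuple[int, int]]:
        """Introns in genomic order."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    def compute_derived(self, genome: GenomeAssembly) -> None:
        """Fill spliced sequence and junction list from the genome."""
        parts = [genome.fetch(self.contig, s, e) for s, e in self.exons]
        seq = "".join(parts)
        self.spliced_sequence = seq if self.strand == "+" else revcomp(seq)
        tex = self.transcript_exons()
        self.junctions = []
        pos = 0
        for j in range(len(tex) - 1):
            pos += tex[j][1] - tex[j][0]
            self.junctions.append((j, j + 1, pos))
        if not self.n_island_flags:
            self.n_island_flags = [False] * len(self.junctions)

    def junction_intron(self, j: int) -> tuple[int, int]:
        """Genomic intron interval spliced at transcript junction ``j``."""
        tex = self.transcript_exons()
        a, b = tex[j], tex[j + 1]
        return (a[1], b[0]) if self.strand == "+" else (b[1], a[0])

    def flag_n_islands(self, islands: list[NIsland]) -> None:
        self.n_island_flags = []
        for j in range(len(self.junctions)):
            istart, iend = self.junction_intron(j)
            hit = any(
                isl.contig == self.contig and isl.start >= istart and isl.end <= iend
                for isl in islands
            )
            self.n_island_flags.append(hit)


@dataclass
class ReadSet:
    """Short reads: (id, sequence, optional quality)."""

    reads: list[tuple[str, str, str | None]]
    read_length: int = 100

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def load_genome(path: str) -> GenomeAssembly:
    """Load a FASTA file as a GenomeAssembly (case-folded, validated)."""
    seqs: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except Exception as exc:  # Bio raises ValueError with position info
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        if rec.id in seqs:
            raise SequenceValidationError(f"{path}: duplicate contig id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeAssembly(seqs)


def load_fasta_dict(path: str) -> dict[str, str]:
    """Plain FASTA -> {id: upper-case sequence} preserving order."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise SequenceValidationError(f"{path}: duplicate id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_reads(path: str) -> ReadSet:
    """Load FASTQ (or FASTA) reads; qualities kept but ignored downstream."""
    fmt = "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    reads = []
    lengths: dict[int, int] = {}
    for rec in SeqIO.parse(path, fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        seq = str(rec.seq).upper()
        reads.append((rec.id, seq, qual))
        lengths[len(seq)] = lengths.get(len(seq), 0) + 1
    rl = max(lengths, key=lengths.get) if lengths else 0
    return ReadSet(reads, read_length=rl)


def write_fastq(reads: ReadSet, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# N-islands
# ---------------------------------------------------------------------------

def _n_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    i = seq.find("N")
    while i != -1:
        j = i
        while j < len(seq) and seq[j] == "N":
            j += 1
        runs.append((i, j))
        i = seq.find("N", j)
    return runs


def find_n_islands(
    genome: GenomeAssembly,
    models: list[TranscriptModel] | None = None,
    flank_distance: int = 100,
    min_island_len: int = 1,
) -> list[NIsland]:
    """One NIsland per maximal N-run, labelled by genomic context.

    Context precedence: intronic (inside an annotated intron) > exonic
    (overlapping an exon) > flanking (starting within ``flank_distance`` of a
    model boundary, outside the model) > intergenic.  An island that exactly
    abuts an exon boundary is classified by the intron interval and flagged
    ``boundary_tie``.
    """
    models = models or []
    by_contig: dict[str, list[TranscriptModel]] = {}
    for m in models:
        if m.contig not in genome:
            raise SequenceValidationError(f"{m.transcript_id}: unknown contig {m.contig}")
        if m.end > len(genome.sequences[m.contig]):
            raise SequenceValidationError(
                f"{m.transcript_id}: exon beyond contig end"
            )
        by_contig.setdefault(m.contig, []).append(m)

    islands: list[NIsland] = []
    for contig, seq in genome.sequences.items():
        for (s, e) in _n_runs(seq):
            if e - s < min_island_len:
                continue
            isl = NIsland(contig, s, e)
            for m in by_contig.get(contig, []):
                # intronic wins over everything else
                for j in range(len(m.junctions) or max(len(m.exons) - 1, 0)):
                    try:
                        istart, iend = m.junction_intron(j)
                    except IndexError:
                        continue
                    if s >= istart and e <= iend:
                        isl.context = "intronic"
                        isl.host_transcript = m.transcript_id
                        isl.host_intron_index = j
                        isl.boundary_tie = s == istart or e == iend
                        break
                if isl.context == "intronic":
                    break
                if any(s < ee and e > es for es, ee in m.exons):
                    isl.context = "exonic"
                    isl.host_transcript = m.transcript_id
            if isl.context in ("intronic", "exonic"):
                islands.append(isl)
                continue
            # flanking: island outside the model span, starting within
            # flank_distance of the model's 5' or 3' border
            for m in by_contig.get(contig, []):
                if s >= m.start and e <= m.end:
                    continue
                gap_up = m.start - e  # island fully upstream of the model
                gap_down = s - m.end  # island fully downstream of the model
                if 0 <= gap_up <= flank_distance or 0 <= gap_down <= flank_distance:
                    isl.context = "flanking"
                    isl.host_transcript = m.transcript_id
                    break
            islands.append(isl)
    return islands


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def load_transcript_models(gff_path: str, genome: GenomeAssembly) -> list[TranscriptModel]:
    """Parse a GFF3 annotation (gene/mRNA/exon) into TranscriptModels.

    External coordinates are 1-based inclusive; internal 0-based half-open.
    Spliced sequences are computed strand-aware from the genome.
    """
    import gffutils

    with tempfile.TemporaryDirectory() as tmp:
        db = gffutils.create_db(
            gff_path,
            dbfn=os.path.join(tmp, "gff.db"),
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        models = []
        for mrna in db.features_of_type("mRNA", order_by="start"):
            exons = [
                (ex.start - 1, ex.end)
                for ex in db.children(mrna, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise SequenceValidationError(f"mRNA {mrna.id} has zero exons")
            if mrna.seqid not in genome:
                raise SequenceValidationError(
                    f"mRNA {mrna.id}: unknown contig {mrna.seqid}"
                )
            if exons[-1][1] > len(genome.sequences[mrna.seqid]):
                raise SequenceValidationError(
                    f"mRNA {mrna.id}: exon outside contig bounds"
                )
            parents = list(db.parents(mrna, featuretype="gene"))
            model = TranscriptModel(
                transcript_id=mrna.id,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                gene_id=parents[0].id if parents else None,
            )
            model.compute_derived(genome)
            models.append(model)
    return models


def write_gff3(models: list[TranscriptModel], path: str, source: str = "exonpatch") -> None:
    """Write gene/mRNA/exon features in standard 1-based GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_id = m.gene_id or f"gene_{m.transcript_id}"
            fh.write(
                f"{m.contig}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={gene_id}\n"
            )
            fh.write(
                f"{m.contig}\t{source}\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.transcript_id};Parent={gene_id}\n"
            )
            for k, (s, e) in enumerate(m.exons):
                fh.write(
                    f"{m.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{k};Parent={m.transcript_id}\n"
                )
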