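"""Synthetic genomes, gapped assemblies, transcript objects and reads.

The generator emulates the study system: a GC-rich (65%) genome of
multi-exon genes whose splice sites follow a donor/acceptor consensus with
invariant GT...AG dinucleotides and informative flanking positions
(total specified information ~16 bits, maximum letter-height score ~15).
Selected introns are replaced in the "assembly" by runs of N whose length
only *estimates* the replaced length (x0.5..2), and may swallow zero or
more internal exons — the hidden-exon scenario.  Transcript objects are the
true spliced mRNAs (the de novo assembler sees RNA, not the gapped
assembly), optionally reverse-complemented, fragmented, or fused in pairs
to mimic track-crossing artifacts.  Reads are drawn uniformly from the true
genome (genomic) or the true mRNAs (RNA), from both strands, with
per-base substitution errors.

Every stage draws from an independent child stream of one global seed, so
any stage reproduces in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import GenomeAssembly, NIsland, ReadSet, TranscriptModel, find_n_islands, revcomp

_BASES = "ACGT"
_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _consensus_position(major: str, p_major: float, second: str, p_second: float) -> list[float]:
    rest = (1.0 - p_major - p_second) / 2.0
    p = {b: rest for b in _BASES}
    p[major] = p_major
    p[second] = p_second
    return [p[b] for b in _BASES]


def default_splice_consensus(
    gc: float = 0.65,
    intron_major: float = 0.56,
    intron_second: float = 0.275,
    exon_major: float = 0.65,
    donor_intronic: int = 10,
    acceptor_intronic: int = 12,
) -> dict[str, np.ndarray]:
    """Per-position nucleotide distributions for the splice windows.

    Donor: three moderately informative exonic positions, invariant GT, four
    informative intronic positions (an AT-rich donor box against the GC-rich
    background).  Acceptor: a T-rich intronic tract, invariant AG, three
    informative exonic positions.  Information is deliberately spread over
    many moderate positions rather than a few strong ones: that matches real
    splice logos and is what makes the 11-bit cutoff separate annotated
    junctions (~99% pass) from random GC-rich GT...AG sequences (a few
    percent pass), with a maximum letter-height score of ~15 bits.
    """

    def informative(major: str, second: str) -> list[float]:
        return _consensus_position(major, intron_major, second, intron_second)

    def exonic(major: str, second: str) -> list[float]:
        return _consensus_position(major, exon_major, second, (1 - exon_major) / 3)

    def invariant(b: str) -> list[float]:
        return [1.0 if x == b else 0.0 for x in _BASES]

    donor_info = [informative("A", "T"), informative("A", "T"), informative("A", "G"),
                  informative("T", "A"), informative("T", "A"), informative("T", "C"),
                  informative("A", "T"), informative("T", "A")][: donor_intronic - 2]
    acc_info = [informative("T", "A"), informative("T", "C"), informative("T", "A"),
                informative("T", "A"), informative("T", "C"), informative("T", "A"),
                informative("T", "A"), informative("T", "A")][: acceptor_intronic - 2]
    donor = np.array(
        [exonic("A", "T"), exonic("A", "T"), exonic("T", "A"),
         invariant("G"), invariant("T")] + donor_info
    )
    acceptor = np.array(
        acc_info + [invariant("A"), invariant("G"),
                    exonic("A", "T"), exonic("T", "A"), exonic("T", "A")]
    )
    return {"donor": donor, "acceptor": acceptor}


def default_island_plan(n_genes: int) -> dict[int, int]:
    """Which genes carry an N-island and how many exons it hides.

    Nine single-hidden-exon islands, four two-exon islands, one four-exon
    island (the multi-exon case-study shape), four purely intronic islands;
    remaining genes are island-free.
    """
    plan: dict[int, int] = {}
    g = 0
    for count, k in ((9, 1), (4, 2), (1, 4), (4, 0)):
        for _ in range(count):
            if g < n_genes:
                plan[g] = k
                g += 1
    return plan


@dataclass
class SimulationConfig:
    seed: int = 0
    gc: float = 0.65
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (7, 11)
    exon_len: tuple[int, int] = (120, 400)
    intron_len: tuple[int, int] = (150, 400)
    intergenic_len: tuple[int, int] = (2000, 5000)
    hidden_exon_len: tuple[int, int] = (120, 300)  # rounded to codon multiples
    hidden_intron_len: tuple[int, int] = (150, 300)
    island_len_factor: tuple[float, float] = (0.5, 2.0)
    island_margin: int = 25  # intron nt kept unmasked next to visible exons
    island_plan: dict[int, int] | None = None
    rna_read_len: int = 50
    genomic_read_len: int = 100
    rna_depth: float = 50.0
    genomic_depth: float = 30.0
    error_rate: float = 0.005
    fusion_rate: float = 0.15  # fused objects per gene
    n_fragment_objects: int = 0
    revcomp_prob: float = 0.3
    proteome_divergence: float = 0.25
    consensus: dict[str, np.ndarray] = field(default_factory=default_splice_consensus)

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0,1)")
        for name in ("exon_len", "intron_len", "intergenic_len",
                     "hidden_exon_len", "hidden_intron_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}")
        if self.intron_len[0] < 2 * self.island_margin + 20:
            raise ValueError("introns too short for island margins")
        for side, probs in self.consensus.items():
            probs = np.asarray(probs, dtype=float)
            if (probs.ndim != 2 or probs.shape[0] < 8 or probs.shape[1] != 4
                    or not np.allclose(probs.sum(axis=1), 1.0)):
                raise ValueError(f"{side} consensus is not a valid distribution")
        d, a = np.asarray(self.consensus["donor"]), np.asarray(self.consensus["acceptor"])
        if d[3, 2] != 1.0 or d[4, 3] != 1.0 or a[-5, 0] != 1.0 or a[-4, 2] != 1.0:
            raise ValueError("consensus must have invariant GT (donor) and AG (acceptor)")

    def plan(self) -> dict[int, int]:
        return self.island_plan if self.island_plan is not None else default_island_plan(self.n_genes)


@dataclass
class HiddenExonRecord:
    gene: int
    transcript_id: str
    seq: str
    mrna_interval: tuple[int, int]  # spliced coords in the true mRNA


@dataclass
class IslandRecord:
    gene: int
    transcript_id: str
    kind: str  # hidden | intronic
    n_hidden: int
    masked_interval: tuple[int, int]  # N-run on the masked assembly contig
    masked_junction_index: int | None  # junction of the masked model (hidden kind)
    hidden_exons: list[HiddenExonRecord] = field(default_factory=list)


@dataclass
class TruthSet:
    config: SimulationConfig
    genome: GenomeAssembly
    assembly: GenomeAssembly
    models_true: list[TranscriptModel]
    models_masked: list[TranscriptModel]
    islands: list[IslandRecord]
    n_islands: list[NIsland]
    mrnas: dict[str, str] = field(default_factory=dict)
    objects: dict[str, str] = field(default_factory=dict)
    object_registry: dict[str, dict] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    codes = rng.choice(4, size=n, p=_background_probs(gc))
    return _CODES[codes].tobytes().decode()


def _draw_window(rng: np.random.Generator, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, p=p)] for p in probs)


def _intron_seq(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    """Intron with consensus-drawn terminal windows (transcript sense).

    The consensus arrays cover 3 exonic + 6 intronic (donor) and 6 intronic
    + 3 exonic (acceptor) positions; the intron itself carries the intronic
    sides, the exon builder overwrites its terminal bases with the exonic
    sides.
    """
    dprobs = np.asarray(cfg.consensus["donor"])[3:]
    aprobs = np.asarray(cfg.consensus["acceptor"])[:-3]
    donor = _draw_window(rng, dprobs)
    acceptor = _draw_window(rng, aprobs)
    middle = _random_seq(rng, length - len(dprobs) - len(aprobs), cfg.gc)
    return donor + middle + acceptor


def _exon_seq(rng: np.random.Generator, length: int, cfg: SimulationConfig,
              has_acceptor: bool, has_donor: bool) -> str:
    """Exon sequence; terminal bases follow the exonic consensus sides."""
    seq = _random_seq(rng, length, cfg.gc)
    if has_acceptor:
        seq = _draw_window(rng, np.asarray(cfg.consensus["acceptor"])[-3:]) + seq[3:]
    if has_donor:
        seq = seq[:-3] + _draw_window(rng, np.asarray(cfg.consensus["donor"])[:3])
    return seq


def _even3(x: int) -> int:
    return max(3, x - x % 3)


@dataclass
class _GeneBuild:
    """One gene in transcript-oriented local coordinates."""
    true_seq: str
    masked_seq: str
    exons_true: list[tuple[int, int]]  # all exons incl. hidden (true coords)
    exons_masked: list[tuple[int, int]]  # visible exons (masked coords)
    hidden_local: list[tuple[int, int]]  # hidden exon intervals, true coords
    island_masked_local: tuple[int, int] | None
    island_kind: str | None
    visible_junction_index: int | None


def _build_gene(rng: np.random.Generator, cfg: SimulationConfig, k_hidden: int | None) -> _GeneBuild:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [int(rng.integers(*cfg.exon_len)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(*cfg.intron_len)) for _ in range(n_exons - 1)]
    # pick host intron for the island; k_hidden == -1 hides the terminal exon
    host = None
    if k_hidden is not None and k_hidden >= 0 and n_exons >= 3:
        host = int(rng.integers(1, n_exons - 1))  # intron index, away from ends

    pieces: list[str] = []
    exons_true: list[tuple[int, int]] = []
    hidden_local: list[tuple[int, int]] = []
    mask_true: tuple[int, int] | None = None  # region to replace with N (true coords)
    pos = 0

    def add(seq: str) -> tuple[int, int]:
        nonlocal pos
        pieces.append(seq)
        iv = (pos, pos + len(seq))
        pos += len(seq)
        return iv

    for i in range(n_exons):
        exons_true.append(add(_exon_seq(rng, exon_lens[i], cfg,
                                        has_acceptor=i > 0,
                                        has_donor=i < n_exons - 1)))
        if i == n_exons - 1:
            break
        if host == i and k_hidden is not None and k_hidden > 0:
            # intron, then k hidden exons separated by introns, then intron
            m = cfg.island_margin
            first_intron = add(_intron_seq(rng, int(rng.integers(*cfg.hidden_intron_len)), cfg))
            mask_start = first_intron[0] + m
            for _ in range(k_hidden):
                hx = add(_exon_seq(rng, _even3(int(rng.integers(*cfg.hidden_exon_len))), cfg,
                                   has_acceptor=True, has_donor=True))
                hidden_local.append(hx)
                exons_true.append(hx)
                add(_intron_seq(rng, int(rng.integers(*cfg.hidden_intron_len)), cfg))
            mask_end = pos - m
            mask_true = (mask_start, mask_end)
        elif host == i and k_hidden == 0:
            iv = add(_intron_seq(rng, intron_lens[i], cfg))
            m = cfg.island_margin
            mask_true = (iv[0] + m, iv[1] - m)
        else:
            add(_intron_seq(rng, intron_lens[i], cfg))

    true_seq = "".join(pieces)
    if k_hidden == -1:
        # flanking island: the terminal exon and most of its intron are masked,
        # leaving the N-run starting within the flank distance of the visible
        # gene end (transcript sense; mirrored genomically for '-')
        hidden_local = [exons_true[-1]]
        mask_true = (exons_true[-2][1] + cfg.island_margin, pos)
    visible = [e for e in exons_true if e not in hidden_local]

    if mask_true is None:
        return _GeneBuild(true_seq, true_seq, exons_true, list(visible),
                          [], None, None, None)
    a, b = mask_true
    n_len = max(1, int(round((b - a) * rng.uniform(*cfg.island_len_factor))))
    masked_seq = true_seq[:a] + "N" * n_len + true_seq[b:]
    shift = n_len - (b - a)

    def remap(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (s if s <= a else s + shift, e if e <= a else e + shift)

    exons_masked = [remap(e) for e in visible]
    if k_hidden == -1:
        kind, junction_idx = "flanking", None
    else:
        kind = "hidden" if hidden_local else "intronic"
        junction_idx = next(
            i for i, e in enumerate(visible[:-1]) if e[1] <= a and visible[i + 1][0] >= b
        )
    return _GeneBuild(
        true_seq, masked_seq, exons_true, exons_masked, hidden_local,
        (a, a + n_len), kind, junction_idx,
    )


def _orient(build: _GeneBuild, strand: str) -> _GeneBuild:
    """Flip a transcript-oriented gene block to genomic '-' orientation."""
    if strand == "+":
        return build
    Lt, Lm = len(build.true_seq), len(build.masked_seq)

    def flip(iv, L):
        return (L - iv[1], L - iv[0])

    return _GeneBuild(
        revcomp(build.true_seq),
        revcomp(build.masked_seq),
        sorted(flip(e, Lt) for e in build.exons_true),
        sorted(flip(e, Lm) for e in build.exons_masked),
        sorted(flip(e, Lt) for e in build.hidden_local),
        flip(build.island_masked_local, Lm) if build.island_masked_local else None,
        build.island_kind,
        build.visible_junction_index,
    )


def simulate_genome(config: SimulationConfig) -> TruthSet:
    """Generate the true genome, the N-masked assembly, models and truth."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng = np.random.default_rng(streams[0])
    plan = config.plan()

    true_parts: list[str] = []
    masked_parts: list[str] = []
    pos_t = pos_m = 0
    models_true: list[TranscriptModel] = []
    models_masked: list[TranscriptModel] = []
    islands: list[IslandRecord] = []
    contig = "chr1"

    for g in range(config.n_genes):
        gap = _random_seq(rng, int(rng.integers(*config.intergenic_len)), config.gc)
        true_parts.append(gap)
        masked_parts.append(gap)
        pos_t += len(gap)
        pos_m += len(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        build = _orient(_build_gene(rng, config, plan.get(g)), strand)
        tid = f"t{g}"
        mt = TranscriptModel(
            tid, contig, strand,
            [(s + pos_t, e + pos_t) for s, e in build.exons_true],
            gene_id=f"g{g}",
        )
        mm = TranscriptModel(
            tid, contig, strand,
            [(s + pos_m, e + pos_m) for s, e in build.exons_masked],
            gene_id=f"g{g}",
        )
        models_true.append(mt)
        models_masked.append(mm)
        if build.island_masked_local is not None:
            s, e = build.island_masked_local
            # hidden exon intervals in transcript (spliced mRNA) coordinates
            tex = build.exons_true if strand == "+" else list(reversed(build.exons_true))
            hidden_set = set(build.hidden_local)
            spliced_pos = 0
            hx: list[HiddenExonRecord] = []
            for ex in tex:
                elen = ex[1] - ex[0]
                if ex in hidden_set:
                    seq = build.true_seq[ex[0] : ex[1]]
                    if strand == "-":
                        seq = revcomp(seq)
                    hx.append(HiddenExonRecord(
                        g, tid, seq, (spliced_pos, spliced_pos + elen)
                    ))
                spliced_pos += elen
            # the gene was built in transcript orientation, so the junction
            # index is already a transcript-order index for either strand
            jidx = build.visible_junction_index
            islands.append(IslandRecord(
                g, tid, build.island_kind, len(hx), (s + pos_m, e + pos_m), jidx, hx
            ))
        true_parts.append(build.true_seq)
        masked_parts.append(build.masked_seq)
        pos_t += len(build.true_seq)
        pos_m += len(build.masked_seq)
    tail = _random_seq(rng, int(rng.integers(*config.intergenic_len)), config.gc)
    true_parts.append(tail)
    masked_parts.append(tail)

    genome = GenomeAssembly({contig: "".join(true_parts)})
    assembly = GenomeAssembly({contig: "".join(masked_parts)})
    for m in models_true:
        m.compute_derived(genome)
    for m in models_masked:
        m.compute_derived(assembly)
    n_islands = find_n_islands(assembly, models_masked)
    for m in models_masked:
        m.flag_n_islands(n_islands)

    truth = TruthSet(
        config, genome, assembly, models_true, models_masked, islands, n_islands
    )
    truth.mrnas = {m.transcript_id: m.spliced_sequence for m in models_true}
    make_transcript_objects(truth, config, np.random.default_rng(streams[1]))
    return truth


def make_transcript_objects(
    truth: TruthSet, config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Full-length objects for every gene plus fusion/fragment artifacts."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[1])
    objects: dict[str, str] = {}
    registry: dict[str, dict] = {}
    for m in truth.models_true:
        seq = m.spliced_sequence
        flipped = bool(rng.random() < config.revcomp_prob)
        objects[f"obj_{m.transcript_id}"] = revcomp(seq) if flipped else seq
        registry[f"obj_{m.transcript_id}"] = {
            "type": "full", "genes": [m.transcript_id], "flipped": flipped
        }
    n_fusions = int(round(config.fusion_rate * config.n_genes))
    ids = [m.transcript_id for m in truth.models_true]
    for f in range(n_fusions):
        a, b = rng.choice(len(ids), size=2, replace=False)
        flip = f == 0 or rng.random() < 0.5  # ensure >=1 strand-flip fusion
        sa = truth.mrnas[ids[a]]
        sb = truth.mrnas[ids[b]]
        seq = sa + (revcomp(sb) if flip else sb)
        objects[f"fusion_{f}"] = seq
        registry[f"fusion_{f}"] = {
            "type": "fusion", "genes": [ids[a], ids[b]], "strand_flip": bool(flip)
        }
    frag_candidates = [isl for isl in truth.islands if isl.kind == "hidden"]
    for i in range(min(config.n_fragment_objects, len(frag_candidates))):
        isl = frag_candidates[i]
        mrna = truth.mrnas[isl.transcript_id]
        p = isl.hidden_exons[0].mrna_interval[0]  # insert start in the mRNA
        left = min(p, 200)
        right = min(len(mrna) - p, 600)
        objects[f"frag_{i}"] = mrna[p - left : p + right]
        registry[f"frag_{i}"] = {
            "type": "fragment", "genes": [isl.transcript_id],
            "mrna_interval": (p - left, p + right),
        }
    truth.objects = objects
    truth.object_registry = registry
    return objects


def simulate_reads(truth: TruthSet, config: SimulationConfig) -> tuple[ReadSet, ReadSet]:
    """Uniform error-prone reads: RNA from true mRNAs, genomic from the genome."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rna = _sample_reads(
        np.random.default_rng(streams[2]),
        list(truth.mrnas.values()),
        config.rna_read_len, config.rna_depth, config.error_rate, "r",
    )
    genomic = _sample_reads(
        np.random.default_rng(streams[3]),
        list(truth.genome.sequences.values()),
        config.genomic_read_len, config.genomic_depth, config.error_rate, "g",
    )
    return rna, genomic


def _sample_reads(
    rng: np.random.Generator,
    sources: list[str],
    read_len: int,
    depth: float,
    error_rate: float,
    prefix: str,
) -> ReadSet:
    from .islands import encode

    reads: list[tuple[str, str, str | None]] = []
    counter = 0
    for si, seq in enumerate(sources):
        L = len(seq)
        if L < read_len:
            continue
        n = int(round(depth * L / read_len))
        starts = rng.integers(0, L - read_len + 1, size=n)
        codes = encode(seq)
        mat = codes[starts[:, None] + np.arange(read_len)[None, :]].astype(np.uint8)
        flip = rng.random(n) < 0.5
        mat[flip] = (3 - mat[flip])[:, ::-1]  # reverse complement
        if error_rate > 0:
            errs = rng.random(mat.shape) < error_rate
            bump = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
            mat = np.where(errs, (mat + bump) % 4, mat)
        basemap = np.frombuffer(b"ACGT", dtype=np.uint8)
        for row in mat:
            reads.append((f"{prefix}{counter}", basemap[row].tobytes().decode(), None))
            counter += 1
    return ReadSet(reads, read_length=read_len)


def make_proteome(truth: TruthSet, config: SimulationConfig) -> dict[str, str]:
    """Diverged homolog peptides, one per gene (the related-species proteome)."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[4])
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    proteome = {}
    for tid, mrna in truth.mrnas.items():
        trimmed = mrna[: len(mrna) - len(mrna) % 3]
        pep = list(str(Seq(trimmed).translate()))
        for i, r in enumerate(pep):
            if r == "*" or rng.random() < config.proteome_divergence:
                pep[i] = aas[rng.integers(len(aas))]
        proteome[f"pep_{tid}"] = "".join(pep)
    return proteome
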