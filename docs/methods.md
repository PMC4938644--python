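# Methods

This note documents the models and procedures implemented in `exonpatch`,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Problem setting

A draft assembly represents unresolved regions as runs of `N` whose length
is only an estimate of the missing sequence. Gene models annotated on such
an assembly can only splice *across* an N-island; if the island conceals
exons, the annotation is silently wrong there. The package decides, for
each intronic N-island, whether it is purely intronic or conceals exons,
and in the latter case reconstructs the exons, their splice junctions and
flanking intronic sequence from data that never depended on the assembly
at the gap: de novo transcript objects and raw genomic reads.

## Ungapped HSP search and the bridge test

The nucleotide aligner is a seeded ungapped local search: exact words
(default 11) shared between query and subject seed a two-sided extension
along the diagonal that stops once the running score falls more than
`x_drop` (default 10) below its best point and is trimmed back to that
point. Scores are match +1 / mismatch −2 and HSPs below 22 are discarded;
`N` always scores as a mismatch. Identical intervals are reported once and
overlapping candidates on one diagonal collapse to the best-scoring one
(ties to the tighter interval, which makes the seeded search agree exactly
with an exhaustive per-diagonal oracle). Both query strands are searched
because transcript objects carry no strand information.

Ungapped extension is the load-bearing choice: a gapped aligner would
absorb a hidden exon as an intron-sized gap inside one alignment, whereas
ungapped extension is forced to emit two separate HSPs with the hidden
sequence between them.

Junction classification per object:

* **covered** — one HSP spans the junction's spliced position with at
  least 4 aligned nt on each side. The spec of a single overhanging
  nucleotide is insufficient in practice: at 65 % GC a chance extension
  crosses the junction by ≥1 nt with probability ~0.27 per side, which
  would misread half-bridges as covered; four chance matches occur in
  <1 % of cases.
* **bridged** — two HSPs flanking the junction (each within 50 bp of it),
  non-overlapping in query and subject, with ≥1 nt of object sequence
  strictly between them. Chance extensions of up to 10 nt across the
  junction are clipped back to it before the test; overlap that survives
  clipping indicates a direct repeat and rejects the pair. Among candidate
  pairs the highest summed score wins, ties to the smaller insert.
* **half_bridged** (N-flagged junctions only) — a single HSP ending
  within 50 bp of the junction with an unaligned tail longer than 60 % of
  the object extending toward the island. The 50-bp distance is measured
  in subject (spliced transcript) coordinates from the junction, which is
  the natural reading of "within 50 bp of the island" on the transcript
  side.

Aggregation across objects takes the most informative status:
bridged > covered > half_bridged > no_information; among equals the object
with the highest summed HSP score supplies the call.

## Splice model

Donor and acceptor windows default to 3 exonic + 10 intronic and
12 intronic + 3 exonic positions respectively (the longer acceptor side
models the pyrimidine tract). Per position the model stores nucleotide
frequencies from training junctions (pseudocount 0 by default so invariant
columns score exactly 2 bits) and the information content `IC = 2 − H`
bits. A candidate scores the sum of `p(b)·IC` over observed nucleotides —
the letter-height convention, the only reading under which four invariant
dinucleotide positions contribute exactly 8 bits and a strong consensus
tops out near 15. `N` contributes 0 rather than failing the call. The
high-confidence call is two-step: literal `GT…AG` plus score ≥ 11 bits.

The window extents are wider than the minimal 3+6/6+3: with the cutoff
fixed at 11 and 8 bits free from the dinucleotides, separating annotated
junctions (~99 % should pass) from random GC-rich `GT…AG` carriers (a few
percent) requires the ~6 flank bits to be spread over many moderate
positions — few strong positions leave the random-score distribution with
a heavy right tail. The pipeline trains the model on the input
annotation's own non-N-flagged junctions; a pre-built `pwm.json` may be
supplied instead.

## Consensus islands

Reads are aligned to each object with the same word-seeded ungapped
machinery (minimum aligned length 20, mismatch fraction ≤ 5 %); each
read's best placement on either strand is kept. Start/finish pileups that
exceed 10× the interior mean (and at least 4 reads — a floor against
Poisson noise at thin depth) seed island growth; template termini act as
implicit seeds. Growth iterates: majority consensus over the recruited
reads (ties toward the template inside the core, alphabetical in tails);
membership re-evaluated for every aligned read by ≥20 nt of overlap with
the consensus at ≤5 % disagreement; stop at a fixed point (cycle-guarded,
≤50 rounds). Reads aligned only through an internal repeat disagree with
the consensus outside the repeat and are discarded — the same rule that
terminates growth.

Island cores are delimited by aligned coverage at ≥¼ of the island's
median depth (≥2 reads): error-free boundary reads share their genomic
continuation, so chance extensions move in lock-step, and a true k-nt
terminal direct repeat makes both neighboring cores genuinely cover the
repeat. Islands whose cores overlap by more than 10 nt are duplicates of
one segment and are merged (with one membership re-filter pass); small
overlaps are kept — they are the direct-repeat ambiguity itself.

Tails are bounded by read length minus the minimum local alignment
(100 − 20 = 80 nt by default); the observed mean tail settles slightly
below that bound because the extreme placement requires a read starting
exactly at the minimum overlap.

### The boundary-enrichment observable

At a segment boundary the idealized start-pileup enrichment equals the
read length (100× for 100-nt reads at the per-position start rate). Under
the package's own minimum aligned length of 20, however, only reads
overlapping the next segment by ≥20 can align, so the reachable pileup is
`read_len − min_len + 1 = 81×`, modulated a few percent either way by edge
effects on the interior mean (measured 74–96× across constructions). Because
error-free reads extend in lock-step, a chance terminal repeat shifts the
entire pileup by the repeat length; the enrichment is therefore measured
at the pileup peak within the ±3 nt repeat-ambiguity window of the
junction. The acceptance suite keeps the idealized 100× as its stated
expectation and the measured value honestly falls short of it; the detection
threshold (10×) is far below either value, so the discrepancy has no
effect on the method itself.

## Join constraint and splice test at island junctions

Adjacent islands must join at the position where their cores meet. The
candidate offsets are verified against sequence: offset `o` is valid only
if the left island's consensus reproduces the template up to `o` and the
right island's from `o` on — which yields exactly k+1 offsets under a
k-nt terminal direct repeat and one otherwise. For every offset and both
strands, donor/acceptor windows are assembled from the islands' cores and
tails (template bases for the exonic sides, island consensus for the
intronic sides; positions without coverage are N and score 0, so short
tails degrade gracefully). The best call per strand is kept (ties to the
smallest offset); under a repeat the offset with the best splice score
wins. A high-confidence call is never emitted without literal `GT…AG`.

Connected islands are maximal runs of islands whose consecutive junctions
carry same-strand high-confidence calls; a junction callable on both
strands is retained on both and flagged ambiguous. One run spanning the
object certifies it splice-consistent; several runs flag a suspected
fusion, with a strand flip between runs marking a strand-switching fusion.

A bridged junction resolves into hidden exons when the islands inside the
insert's query interval belong to one connected island that also contains
the flanking reference-matching islands. Exon boundaries are the chosen
join offsets, so every reported exon carries literal splice-site support
on both sides; bridges whose islands fail the test are reported as
unresolved, never as exons.

## Conservation test

The two HSP flanks are aligned separately to the subject peptide (six
reading frames, BLOSUM62, gap open 11 / extend 1, stop codons score the
matrix minimum); their summed scores are the baseline S2 — the two HSPs a
translated search reports for the flanks-only query. Charging the
baseline a deletion for the subject's inter-anchor segment would let any
junk insert "recover" tens of points of that penalty through a mismatch
diagonal, which is why S2 is anchor-summed instead. The insert's gain is
positionally constrained: its in-frame translation must explain the
subject segment *between* the anchors end-to-end (an affine-gap
end-anchored alignment with ~15-bit x-drop pruning, mirroring the gapped
x-dropoff of translated search tools); junk crossings dip below the
x-drop and contribute nothing. S1 adds the real insert's gain, each S3
replicate the gain of a control insert.

The control permutes the insert at nucleotide level (destroying frame and
codon structure — the null model for an untranslated in-silico artifact);
an amino-acid-level permutation is available but preserves composition
exactly and leaves a heavier-tailed null whose maximum over many
replicates exceeds the 10-unit threshold by construction. The verdict is
*conserved* iff the anchors hold (S2 ≥ 40), S1 − S2 > 10, and no
scrambled replicate gains more than 10.

## Synthetic data generator

The generator emulates: a 65 % GC genome of ~150–200 kb with 20 multi-exon
genes (7–11 exons of 120–400 nt, introns 150–400 nt, both strands);
splice sites drawn from the consensus described above (intronic majors
0.56 / seconds 0.275 on A/T, exonic majors 0.65 — calibrated so ~99 % of
annotated junctions pass the two-step test and ~3 % of random GC-rich
`GT…AG` carriers do, with a maximum score near 15 bits); N-islands that
replace 0–4 internal exons plus flanking intron interiors with an N-run
of 0.5–2× the true length (the island-as-estimate semantics), leaving
25 nt of intron next to visible exons; per-gene island plan 9×1, 4×2, 1×4
hidden exons plus 4 purely intronic islands by default; full-length
transcript objects (reverse-complemented with probability 0.3), fused
object pairs (one guaranteed strand flip), optional sub-fragments and a
truncated-terminal-exon "flanking island" gene; uniform error-prone reads
(RNA 50 nt at 50×, genomic 100 nt at 30×, substitutions at 0.5 %); and a
25 %-diverged homolog proteome. Hidden exon lengths are codon multiples
so conservation framing is clean. One global seed feeds independent
per-stage substreams.

Not emulated: repeat families, indels, quality-score structure,
expression variation, alternative splicing, non-canonical (GC–AG/AT–AC)
introns, and chance sequence reuse between genes. Passing tests therefore
demonstrate the machinery under substitution noise and honest splice-site
statistics, not robustness to repeat-rich or indel-rich data.

## Defaults and their reasons

| parameter | default | rationale |
| --- | --- | --- |
| match/mismatch, word, x-drop, min HSP | +1/−2, 11, 10, 22 | standard ungapped nucleotide-search settings; all CLI-tunable |
| min local read alignment | 20 nt | sets the 80-nt tails; the published minimum of the read aligner emulated |
| mismatch tolerance | 5 % | an order above the 0.5 % read error rate |
| seed enrichment threshold | 10× | detection needs far less than the ~85× signal of dense data |
| consensus majority / agree overlap | 0.75 / 20 nt | conservative majority; overlap matches the alignment minimum |
| splice cutoff | 11 bits | the two-step test's published cutoff |
| improvement threshold | 10 | the empirical bound of the scrambled control |
| scrambles | 20, seedable | enough replicates that the max is a stable statistic |
| flank distance | 100 bp | the flanking-island definition |

## Known limitations

* Hidden-exon calls are reported in object coordinates with the host
  island's interval on the assembly; exact genomic placement inside the
  island is impossible in principle (the island's length is an estimate).
* Very short exons (< word size) cannot seed an HSP or an island core and
  are invisible.
* A junction whose true splice windows score below 11 bits (the honest
  ~0.5–1 % tail of any consensus) breaks its connected island and its
  island's exons are reported unresolved rather than called.
* The conservation test assumes the insert is in-frame coding sequence;
  frame-shifting inserts score as not conserved.
* Iterative outward walking to reconstruct whole introns is out of scope.
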