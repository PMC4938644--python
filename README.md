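# exonpatch

Draft genome assemblies paper over unresolved regions with runs of `N`
("N-islands"), and gene annotations built on such assemblies splice right
across them — silently dropping any exons the gap conceals. `exonpatch`
recovers those hidden exons, their exact splice junctions, and flanking
intronic sequence **without trusting the assembly at the gap**, by
cross-examining three independent data sources:

1. **de novo assembled transcript objects** (from RNA-seq, which never saw
   the gap),
2. **the reference transcript models** (which splice across the gap), and
3. **raw genomic short reads** (which cover the missing sequence).

It is aimed at genome annotators and assembly curators working with
GC-rich, intron-dense genomes where gaps are common and tend to coincide
with hard-to-assemble exons.

## The method

**Bridges.** Each transcript object is aligned to each reference transcript
with an *ungapped* seeded local aligner (match +1, mismatch −2, word 11,
x-drop 10). Ungapped extension cannot absorb an inserted exon into a gap,
so at a junction that splices out an N-island concealing real exons the
alignment breaks into two HSPs with extra object sequence between them — a
**bridge**. One continuous HSP across the junction ("covered") instead
certifies the island as purely intronic. A single HSP ending within 50 bp
of the island with a long (>60 % of the object) unaligned tail pointing at
it is a **half-bridge**.

**Consensus islands.** Genomic reads are aligned locally to the object
(minimum aligned length 20). Alignment starts and finishes pile up exactly
where the object switches genomic segments; from those seeds an iterative
majority consensus recruits agreeing reads and discards poor fits,
rebuilding each genomic segment as an **island**: a core identical to the
object plus ~80 nt tails (read length 100 − minimum 20) of flanking
*intronic* sequence the object does not contain.

**The splicing test.** Adjacent islands share no sequence, so the position
where their cores meet constrains any splice to a single nucleotide (k+1
candidates under a k-nt terminal direct repeat). A donor/acceptor
position-weight model trained on the annotation's own junctions scores each
candidate in bits, with the letter-height convention

&nbsp;&nbsp;&nbsp;&nbsp;score = Σᵢ pᵢ(bᵢ)·ICᵢ,&nbsp;&nbsp;ICᵢ = 2 − Hᵢ,

so the invariant `GT…AG` dinucleotides alone contribute 8 bits and the
model maximum is ~15. A junction is **high confidence** iff the literal
dinucleotides are present *and* the score reaches 11 bits. Because the
consensus is mostly intronic, finding it in the island tails at the
constrained join is validation fully independent of the transcript data.
Chains of islands joined by same-strand high-confidence splices form
**connected islands**; an object that does not resolve into a single
connected island is flagged as an in-silico fusion (track-crossing)
artifact.

**The conservation test.** A bridge insert placed back between its two HSP
flanks must improve a translated (BLOSUM62, gap 11/1) alignment against a
pre-selected homologous peptide by more than 10 raw units, while
nucleotide-scrambled controls of the insert must not.

## Worked example

`examples/04_full_pipeline.py` simulates a 6-gene GC-rich genome whose
assembly hides exons in two N-islands and leaves one island purely
intronic, then runs the pipeline end to end:

```
junction summary:
 n_flag  status  count
  False covered     44
   True bridged      2
   True covered      1

N-island verdicts:
  t0 junction 1: bridged -> hidden_exons (1 hidden exons)
  t1 junction 1: covered -> purely_intronic (0 hidden exons)
  t2 junction 7: bridged -> hidden_exons (2 hidden exons)

hidden exon calls:
  t0 exon 0: object[1333:1624), splice score 12.4 bits, conserved
  t2 exon 0: object[1810:2086), splice score 13.1 bits, conserved
  t2 exon 1: object[2086:2218), splice score 12.8 bits, conserved

fusion diagnostics:
  fusion_0: 2 connected islands -> suspected fusion
```

All 44 ordinary junctions are covered; both hidden-exon islands are
bridged and resolve into exon calls with exact boundaries, high-confidence
splice scores above the 11-bit cutoff, and conserved translated alignments;
the purely intronic island is confirmed covered; the one deliberately fused
object fails to form a single connected island. The other examples isolate
each stage: `01` bridge detection, `02` the boundary signature and island
growth, `03` the scrambled-control conservation test.

## Command line

```
exonpatch simulate --seed 1 --outdir fixtures/
exonpatch run --genome assembly.fa --models models.gff3 \
              --objects objects.fa --greads genomic.fastq \
              --proteome homologs.faa --outdir out/ --seed 1
```

plus per-stage subcommands `bridge`, `pwm`, `islands`, `splicetest`,
`conserve`. Outputs: `junctions.tsv`, `report.json`, `hidden_exons.fa`,
`hidden_exons.gff3`, `conservation.tsv`.

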