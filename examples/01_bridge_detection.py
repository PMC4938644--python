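"""Separated-HSP bridge detection on a miniature case.

A reference transcript model splices two exons directly together because
its assembly hides an exon inside a run of N.  A de novo transcript object
built from RNA still contains the hidden sequence, so its ungapped
alignment to the reference transcript breaks into two HSPs with the extra
sequence in between: a "bridge".
"""

import numpy as np

from exonpatch.bridges import classify_junctions, ungapped_local_align
from exonpatch.seqio import GenomeAssembly, TranscriptModel

rng = np.random.default_rng(0)
bases = list("ACGT")
rand = lambda n: "".join(rng.choice(bases, p=[0.175, 0.325, 0.325, 0.175]) for _ in range(n))

# reference: two exons around an intron (the intron would contain the N-island)
e1, intron, e2 = rand(180), rand(300), rand(180)
genome = GenomeAssembly({"chr": e1 + intron + e2})
model = TranscriptModel("t1", "chr", "+", [(0, 180), (480, 660)])
model.compute_derived(genome)
model.n_island_flags = [True]  # the intron is annotated as spliced-out Ns

# the transcript object carries a 90-nt hidden exon between the two exons
hidden = rand(90)
obj = e1 + hidden + e2

hsps = ungapped_local_align(obj, model.spliced_sequence, query_id="obj", subject_id="t1")
print(f"{len(hsps)} HSPs:")
for h in hsps:
    print(f"  query[{h.q_start}:{h.q_end}) ~ subject[{h.s_start}:{h.s_end}) "
          f"strand {h.strand} score {h.score}")

calls = classify_junctions(hsps, model, {"obj": obj})
c = calls[0]
print(f"junction 0 status: {c.status}, insert length {c.insert_length}")
print(f"insert recovered exactly: {c.insert_sequence == hidden}")
# Two HSPs flanking the junction with ~90 nt of extra object sequence between
# them: the signature of an exon hidden in the assembly gap.
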