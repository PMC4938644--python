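import numpy as np
import pytest

from exonpatch.pipeline import RunParams, train_pwm
from exonpatch.seqio import find_n_islands
from exonpatch.simulate import SimulationConfig, simulate_genome, simulate_reads

BACKGROUND = {"A": 0.175, "C": 0.325, "G": 0.325, "T": 0.175}


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.65) -> str:
    return "".join(
        rng.choice(list("ACGT"), p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for _ in range(n)
    )


# deterministic one-codon-per-residue back-translation used by several tests
_BACKTABLE = {}


def backtranslate(pep: str) -> str:
    if not _BACKTABLE:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _BACKTABLE.setdefault(aa, codon)
    return "".join(_BACKTABLE[a] for a in pep)


@pytest.fixture(scope="session")
def small_config():
    # 7 genes: one 1-exon island, one purely intronic island, one 2-exon
    # island, one flanking (truncated terminal exon) island, plus clean genes
    return SimulationConfig(
        seed=11,
        n_genes=7,
        island_plan={0: 1, 1: 0, 2: 2, 3: -1},
        fusion_rate=2 / 7,
        n_fragment_objects=1,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_reads(small_truth, small_config):
    return simulate_reads(small_truth, small_config)


@pytest.fixture(scope="session")
def small_pwm(small_truth):
    params = RunParams()
    islands = find_n_islands(small_truth.assembly, small_truth.models_masked)
    for m in small_truth.models_masked:
        m.flag_n_islands(islands)
    return train_pwm(small_truth.models_masked, small_truth.assembly, params)


def planted_exon_intervals(truth):
    """Hidden-exon intervals in object coordinates, keyed by (tid, junction)."""
    out = {}
    for isl in truth.islands:
        if isl.kind != "hidden":
            continue
        obj_id = f"obj_{isl.transcript_id}"
        flip = truth.object_registry[obj_id]["flipped"]
        L = len(truth.objects[obj_id])
        ivs = [h.mrna_interval for h in isl.hidden_exons]
        if flip:
            ivs = sorted((L - b, L - a) for a, b in ivs)
        out[(isl.transcript_id, isl.masked_junction_index)] = ivs
    return out
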