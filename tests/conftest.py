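import numpy as np
import pytest

from museomito import (
    CircularSequence,
    DamageModel,
    FragmentModel,
    SimConfig,
    random_genome,
    simulate_readset,
)
from museomito.mapping import AlignedRead
from museomito.simulate import embed_homopolymer, plant_variants, table2_like_variants


@pytest.fixture(scope="session")
def toy_genome() -> CircularSequence:
    """2 kb random circular genome used by mapper oracle tests."""
    return random_genome(2000, seed=7, id="toy")


@pytest.fixture(scope="session")
def full_genome() -> CircularSequence:
    """Full-scale 17,408 bp random circular genome with an embedded 14-C run."""
    g = random_genome(17408, seed=11, id="mito")
    return embed_homopolymer(g, 15986, "C", 14)


@pytest.fixture(scope="session")
def planted(full_genome):
    """(variants, mutated genome) shaped like the published difference set:
    21 transitions, 5 transversions, one single-base deletion in the C run."""
    variants = table2_like_variants(full_genome, 23, homopolymer_site=15986)
    mutated, coord_map = plant_variants(full_genome, variants)
    return variants, mutated, coord_map


def make_alignments_from_truth(genome, readset):
    """Truth-placement alignments (no mapper), for damage-profile tests.

    Pairs are stored in reference orientation, as the mapper would produce.
    """
    from museomito import reverse_complement

    out = []
    for (rid, seq), t in zip(readset.reads, readset.truth):
        if t.origin != "endogenous":
            continue
        ref_sub = genome.fetch(t.start, len(seq))
        read_fwd = seq if t.strand == "+" else reverse_complement(seq)
        out.append(
            AlignedRead(
                read_id=rid,
                ref_start=t.start,
                strand=t.strand,
                matched=list(zip(ref_sub, read_fwd)),
                score=0,
            )
        )
    return out


@pytest.fixture(scope="session")
def damaged_alignments(full_genome):
    """20k single-stranded damaged reads placed at their true positions."""
    dm = DamageModel(p_max=0.3, p_base=0.01, decay=0.5, seq_error=0.001)
    fm = FragmentModel()
    n_for_depth = 20000 * fm.truncated_mean() / len(full_genome)
    cfg = SimConfig(target_depth=n_for_depth, seed=99)
    rs = simulate_readset(full_genome, fm, dm, cfg)
    return make_alignments_from_truth(full_genome, rs), dm
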