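import numpy as np
import pytest

from xprio import synthetic
from xprio.genome import Contig, Subgenome


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with one strongly planted disease motif."""
    cfg = synthetic.SimConfig(
        seed=101,
        chrom_length=400_000,
        n_disease=5,
        n_non_disease=8,
        planted_motifs=[("ACGGTCACGTTA", "disease", 5.0)],
    )
    return synthetic.simulate_dataset(cfg)


def make_subgenome(seqs, profile="disease", stratum="ALL", distance_kb=2):
    """Wrap bare sequences as a Subgenome with synthetic back-to-back contigs."""
    contigs = []
    offset = 0
    for i, s in enumerate(seqs):
        contigs.append(Contig("c", offset, offset + len(s), profile, [f"{profile}{i}"], stratum=stratum))
        offset += len(s)
    return Subgenome((profile, stratum, distance_kb), contigs, list(seqs))


def random_sequences(rng, n, length, gc=0.41):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [rng.choice(bases, size=length, p=p).tobytes().decode() for _ in range(n)]
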