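import numpy as np
import pytest

from lephox import synthetic


@pytest.fixture(scope="session")
def reference_panel():
    return synthetic.gen_reference_panel(seed=0)


@pytest.fixture(scope="session")
def planted_hox_genome(reference_panel):
    """Genome with one planted homeobox per class, alternating strands."""
    genes = []
    pos = 5000
    for i, (rid, cls, seq) in enumerate(reference_panel[::3]):
        genes.append((rid, seq, pos, "+-"[i % 2]))
        pos += 3000
    spec = synthetic.SyntheticGenomeSpec(length=100_000, seed=3, planted_genes=genes)
    contigs, truth = synthetic.gen_genome(spec)
    return contigs, truth


@pytest.fixture(scope="session")
def small_readset():
    """200 kb genome, 15x error-free paired reads."""
    spec = synthetic.SyntheticGenomeSpec(length=200_000, seed=11)
    contigs, _ = synthetic.gen_genome(spec)
    genome = contigs["synthetic_contig_1"]
    reads = synthetic.simulate_reads(
        genome, synthetic.ReadSimSpec(coverage=15.0, seed=11)
    )
    return genome, reads


def read_matrix(readset):
    return np.vstack([readset.r1, readset.r2])
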